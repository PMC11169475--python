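"""Vessel-to-drug distance pipeline: preprocessing, thresholding, distances."""

import numpy as np
import pytest
from scipy.ndimage import binary_erosion, generate_binary_structure
from skimage.draw import disk as draw_disk

from spimkit.errors import DegenerateInputError, ValidationError
from spimkit.stacks import ImageStack
from spimkit.vesseldist import (
    MaskSlicePair,
    classify_vessels,
    contour_points,
    drug_vessel_distances,
    grouped_mip,
    otsu_global_threshold,
    subtract_background,
    summarize_distances,
)


def otsu_by_exhaustive_search(image):
    """Independent oracle: maximize between-class variance over all cuts."""
    hist, edges = np.histogram(image.ravel(), bins=256)
    centers = (edges[:-1] + edges[1:]) / 2
    p = hist / hist.sum()
    best_t, best_v = None, -1.0
    for k in range(1, 256):
        if hist[k - 1] == 0:
            continue  # same partition as the previous populated cut
        w0, w1 = p[:k].sum(), p[k:].sum()
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (p[:k] * centers[:k]).sum() / w0
        mu1 = (p[k:] * centers[k:]).sum() / w1
        v = w0 * w1 * (mu0 - mu1) ** 2
        if v > best_v:
            best_v, best_t = v, centers[k - 1]
    return best_t


def all_pairs_nearest(drug_pts, vessel_pts):
    """Brute-force nearest vessel point per drug point, lowest index on ties."""
    out = []
    for p in drug_pts:
        d = np.linalg.norm(vessel_pts - p, axis=1)
        out.append((int(np.argmin(d)), float(d.min())))
    return out


class TestSubtractBackground:
    def test_constant_image_zeroed(self):
        assert np.allclose(subtract_background(np.full((30, 30), 80.0), 4), 0.0)

    def test_spike_preserved_background_removed(self):
        img = np.full((40, 40), 50.0)
        img[20, 20] = 250.0
        out = subtract_background(img, 4)
        assert out[20, 20] == pytest.approx(200.0, abs=5)
        assert np.median(out) < 1.0

    def test_broad_blob_flattened(self):
        img = np.zeros((60, 60))
        rr, cc = draw_disk((30, 30), 20)
        img[rr, cc] = 100.0
        out = subtract_background(img, 4)  # ball much smaller than blob
        assert out.max() < 100.0
        assert out[30, 30] < 10.0  # interior treated as background

    def test_invalid_radius(self):
        with pytest.raises(ValidationError):
            subtract_background(np.zeros((5, 5)), 0)


class TestGroupedMip:
    def test_thirty_slices_three_mips(self):
        stack = ImageStack(np.random.default_rng(0).integers(0, 255, (30, 8, 8)), (1, 1, 1))
        assert len(grouped_mip(stack, 10)) == 3

    def test_group_one_identity(self, random_stack):
        mips = grouped_mip(random_stack, 1)
        assert all(np.array_equal(m, s) for m, s in zip(mips, random_stack.voxels))

    def test_monotone_stack_takes_last_slice(self):
        vox = np.arange(12)[:, None, None] * np.ones((1, 4, 4))
        mips = grouped_mip(ImageStack(vox, (1, 1, 1)), 4)
        assert np.array_equal(mips[0], vox[3])
        assert np.array_equal(mips[2], vox[11])

    def test_trailing_partial_group_kept(self):
        vox = np.random.default_rng(1).integers(0, 255, (25, 4, 4))
        assert len(grouped_mip(ImageStack(vox, (1, 1, 1)), 10)) == 3


class TestOtsu:
    def test_two_level_threshold_separates(self):
        rng = np.random.default_rng(2)
        img = np.where(rng.random((64, 64)) < 0.4, 10, 200).astype(np.uint8)
        thr, masks = otsu_global_threshold([img], 0)
        assert 10 <= thr < 200
        # the strict > binarization separates the two populations exactly
        assert np.array_equal(masks[0], img == 200)

    def test_matches_exhaustive_search_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            img = np.concatenate([
                rng.normal(60, 12, size=500), rng.normal(180, 20, size=700)
            ]).clip(0, 255).astype(np.uint8).reshape(40, 30)
            thr, _ = otsu_global_threshold([img], 0)
            assert thr == pytest.approx(otsu_by_exhaustive_search(img), abs=1e-9)

    def test_agrees_with_skimage_within_one_bin(self):
        from skimage.filters import threshold_otsu

        rng = np.random.default_rng(7)
        img = np.concatenate([
            rng.normal(60, 12, size=500), rng.normal(180, 20, size=700)
        ]).clip(0, 255).astype(np.uint8).reshape(40, 30)
        thr, _ = otsu_global_threshold([img], 0)
        bin_width = np.ptp(img) / 256
        assert abs(thr - threshold_otsu(img, nbins=256)) <= bin_width + 1e-9

    def test_single_threshold_shared_by_all_slices(self):
        rng = np.random.default_rng(4)
        mips = [rng.integers(0, 255, (16, 16)).astype(np.uint8) for _ in range(5)]
        thr, masks = otsu_global_threshold(mips, 2)
        for mip, mask in zip(mips, masks):
            assert np.array_equal(mask, mip > thr)

    def test_constant_reference_rejected(self):
        with pytest.raises(DegenerateInputError):
            otsu_global_threshold([np.full((8, 8), 5, dtype=np.uint8)], 0)


class TestDistances:
    def _disk_pair(self, r=15):
        vessel = np.zeros((64, 64), dtype=bool)
        vessel[32, 32] = True
        drug = np.zeros((64, 64), dtype=bool)
        rr, cc = draw_disk((32, 32), r)
        drug[rr, cc] = True
        return MaskSlicePair(vessel, drug)

    def test_disk_distances_bounded_by_radius(self):
        pair = self._disk_pair(15)
        tbl = drug_vessel_distances(pair)
        d = tbl.valid_distances
        assert len(d) == 1  # single vessel point collects the whole contour
        assert d[0] <= 15.0
        assert d[0] == pytest.approx(14.0, abs=1.0)  # mean over the rim

    def test_matches_all_pairs_oracle(self, vessel_drug):
        vessel, drug, _ = vessel_drug
        pair = MaskSlicePair(vessel, drug)
        drug_pts = contour_points(drug)
        vessel_pts = contour_points(vessel)
        oracle = all_pairs_nearest(drug_pts, vessel_pts)
        tbl = drug_vessel_distances(pair, validate_lines=False)
        groups = {}
        for vi, d in oracle:
            groups.setdefault(vi, []).append(d)
        expected = {
            (int(vessel_pts[vi][0]), int(vessel_pts[vi][1])): float(np.mean(dl))
            for vi, dl in groups.items()
        }
        got = {
            (row.vessel_row, row.vessel_col): row.mean_distance_um
            for row in tbl.records.itertuples()
        }
        assert got.keys() == expected.keys()
        for k in expected:
            assert got[k] == pytest.approx(expected[k], abs=1e-9)

    def test_empty_drug_mask(self):
        tbl = drug_vessel_distances(MaskSlicePair(np.ones((8, 8), bool), np.zeros((8, 8), bool)))
        assert tbl.records.empty
        assert "empty drug mask" in tbl.notes

    def test_empty_vessel_mask_flagged(self):
        drug = np.zeros((16, 16), dtype=bool)
        drug[4:8, 4:8] = True
        tbl = drug_vessel_distances(MaskSlicePair(np.zeros((16, 16), bool), drug))
        assert tbl.records.empty
        assert any("vessel" in n for n in tbl.notes)

    def test_disconnected_lobe_lines_omitted(self):
        # vessel inside lobe A; lobe B's contour lines must cross background
        vessel = np.zeros((40, 80), dtype=bool)
        vessel[18:22, 18:22] = True
        drug = np.zeros((40, 80), dtype=bool)
        drug[14:26, 14:26] = True  # lobe A around the vessel
        drug[14:26, 60:72] = True  # lobe B, disconnected
        tbl = drug_vessel_distances(MaskSlicePair(vessel, drug))
        tbl_all = drug_vessel_distances(MaskSlicePair(vessel, drug), validate_lines=False)
        # the validity rule removed lobe-B pairings
        assert tbl.records["contributing_drug_points"].sum() < \
            tbl_all.records["contributing_drug_points"].sum()
        assert tbl.valid_distances.max() < 30.0

    def test_validity_filter_monotone(self, vessel_drug):
        vessel, drug, _ = vessel_drug
        with_rule = drug_vessel_distances(MaskSlicePair(vessel, drug))
        without = drug_vessel_distances(MaskSlicePair(vessel, drug), validate_lines=False)
        assert with_rule.records["contributing_drug_points"].sum() <= \
            without.records["contributing_drug_points"].sum()


class TestSummaries:
    def _table_of(self, distances, idx=0):
        import pandas as pd

        from spimkit.vesseldist import DistanceTable

        df = pd.DataFrame({
            "vessel_row": 0, "vessel_col": np.arange(len(distances)),
            "mean_distance_um": distances, "contributing_drug_points": 1, "valid": True,
        })
        return DistanceTable(df, idx)

    def test_constant_distances(self):
        s = summarize_distances([self._table_of([7.0] * 20)])
        box = s["per_slice"][0]
        assert box["q1"] == box["median"] == box["q3"] == 7.0
        assert s["percentile_95_um"] == 7.0

    def test_p95_linear_interpolation(self):
        s = summarize_distances([self._table_of(np.arange(1.0, 101.0))])
        assert s["percentile_95_um"] == pytest.approx(95.05)

    def test_empty_rejected(self):
        with pytest.raises(DegenerateInputError):
            summarize_distances([self._table_of([])])


class TestClassifyVessels:
    def test_vessel_inside_drug_is_associating(self):
        vessel = np.zeros((16, 16), bool)
        vessel[4:8, 4:8] = True
        drug = np.zeros((16, 16), bool)
        drug[2:10, 2:10] = True
        labels = classify_vessels(MaskSlicePair(vessel, drug))
        assert labels["label"].tolist() == ["drug-associating"]

    def test_disjoint_masks_non_associating(self):
        vessel = np.zeros((16, 16), bool)
        vessel[2:5, 2:5] = True
        drug = np.zeros((16, 16), bool)
        drug[10:14, 10:14] = True
        labels = classify_vessels(MaskSlicePair(vessel, drug))
        assert labels["label"].tolist() == ["non-associating"]

    def test_single_touching_pixel_associates(self):
        vessel = np.zeros((16, 16), bool)
        vessel[4:8, 4:8] = True
        drug = np.zeros((16, 16), bool)
        drug[7, 7] = True  # one overlapping pixel
        labels = classify_vessels(MaskSlicePair(vessel, drug))
        assert labels["label"].tolist() == ["drug-associating"]


class TestContours:
    def test_boundary_pixel_set(self):
        mask = np.zeros((10, 10), bool)
        mask[3:7, 3:7] = True
        pts = contour_points(mask)
        interior = binary_erosion(mask, generate_binary_structure(2, 2), border_value=0)
        assert len(pts) == mask.sum() - interior.sum()
        # all points are foreground with a background 8-neighbour
        assert all(mask[r, c] for r, c in pts)

    def test_empty_mask(self):
        assert contour_points(np.zeros((5, 5), bool)).size == 0
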