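"""Virtual H&E rendering of fluorescence volumes (Beer–Lambert scheme).

A nuclear stain (hematoxylin-like, purple) and a general-protein stain
(eosin-like, pink) are mapped to transmitted-light RGB by simulated
absorption: each normalized intensity attenuates a white background
exponentially with a per-channel RGB absorption triplet,

    RGB_c = background_c · exp(−k_nuc,c · g_n · I_nuc − k_cyt,c · g_p · I_prot).

The default absorption triplets are the standard hematoxylin and eosin
optical-density vectors from the virtual-staining / color-deconvolution
literature; both are plain config values a user can override with the
coefficients of any released renderer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import FormatError
from .stacks import ImageStack

__all__ = ["HEColorModel", "render_he"]


@dataclass
class HEColorModel:
    """Absorption triplets and gains for the two stains."""

    # classic hematoxylin / eosin optical-density RGB vectors
    k_nuclear: tuple[float, float, float] = (0.65, 0.70, 0.29)
    k_cytoplasm: tuple[float, float, float] = (0.07, 0.99, 0.11)
    background: tuple[float, float, float] = (1.0, 1.0, 1.0)
    gain_nuclear: float = 2.0
    gain_cytoplasm: float = 2.0

    def __post_init__(self) -> None:
        if min(*self.k_nuclear, *self.k_cytoplasm) < 0:
            raise ValueError("absorption coefficients must be non-negative")
        if self.gain_nuclear < 0 or self.gain_cytoplasm < 0:
            raise ValueError("gains must be non-negative")


def _normalized(arr: np.ndarray) -> np.ndarray:
    a = np.asarray(arr, dtype=np.float64)
    peak = a.max()
    return a / peak if peak > 0 else np.zeros_like(a)


def render_he(
    nuclear: ImageStack | np.ndarray,
    protein: ImageStack | np.ndarray,
    model: HEColorModel | None = None,
) -> np.ndarray:
    """Render two congruent channels as an RGB volume in [0, 1].

    Output shape is input shape + (3,).  Zero signal gives the pure
    background (white); output is monotone non-increasing in each input
    intensity, and the two stains combine multiplicatively (Beer–Lambert).
    """
    model = model or HEColorModel()
    nuc = nuclear.voxels if isinstance(nuclear, ImageStack) else np.asarray(nuclear)
    pro = protein.voxels if isinstance(protein, ImageStack) else np.asarray(protein)
    if nuc.shape != pro.shape:
        raise FormatError(f"channel shapes differ: {nuc.shape} vs {pro.shape}")
    i_n = _normalized(nuc)[..., None]
    i_p = _normalized(pro)[..., None]
    k_n = np.asarray(model.k_nuclear) * model.gain_nuclear
    k_p = np.asarray(model.k_cytoplasm) * model.gain_cytoplasm
    rgb = np.asarray(model.background) * np.exp(-k_n * i_n - k_p * i_p)
    return np.clip(rgb, 0.0, 1.0)
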