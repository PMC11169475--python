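"""Exception hierarchy shared across the toolkit.

All errors derive from :class:`SpimkitError` so callers (and the CLI) can
catch toolkit failures with a single except clause while tests can assert
the specific category.
"""


class SpimkitError(Exception):
    """Base class for all toolkit errors."""


class DomainError(SpimkitError, ValueError):
    """A physical parameter is outside its meaningful domain (e.g. n < 1)."""


class ValidationError(SpimkitError, ValueError):
    """Inputs are individually fine but mutually inconsistent."""


class FormatError(SpimkitError, ValueError):
    """Array shapes, bit depths or file layouts do not match."""


class FitError(SpimkitError, RuntimeError):
    """A model fit failed or produced a rejected solution."""


class NoInversionError(SpimkitError, RuntimeError):
    """Focus-contrast curves never cross: the two tiles are indistinguishable."""


class DegenerateInputError(SpimkitError, ValueError):
    """An operation received input it cannot meaningfully process
    (constant image, empty mask, zero-variance slice, ...)."""
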