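"""Exception hierarchy for the scoring pipeline."""


class IHCQuantError(Exception):
    """Base class for all pipeline errors."""


class ShapeError(IHCQuantError, ValueError):
    """Input array has the wrong shape (e.g. not H x W x 3)."""


class SingularBasisError(IHCQuantError, ValueError):
    """Stain matrix is singular or numerically non-invertible."""


class ValidationError(IHCQuantError, ValueError):
    """A domain object violates its invariants."""


class EmptyROIError(IHCQuantError, ValueError):
    """A region of interest selects no pixels."""
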