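"""Exception hierarchy shared across the pipeline stages."""


class PetprogError(Exception):
    """Base class for all pipeline errors."""


class ValidationError(PetprogError):
    """Input data violate a documented invariant (codes, ranges, signs)."""


class DimensionalityError(ValidationError):
    """Image does not have exactly three spatial dimensions."""


class GridMismatchError(ValidationError):
    """Mask and volume do not share shape/spacing/origin."""


class GeometryError(PetprogError):
    """A geometric construct (bounding box, tumour) does not fit the grid."""


class DegenerateInputError(PetprogError):
    """Input is degenerate for the requested operation (e.g. constant ROI)."""


class ConvergenceError(PetprogError):
    """An iterative algorithm failed to converge within its budget."""


class SeparationError(PetprogError):
    """Cox fit diverged (monotone likelihood / separated covariate)."""
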