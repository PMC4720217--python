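"""Exception hierarchy for the osteolysis pipeline.

Every stage raises a subclass of :class:`OsteolysisError` so callers (and the
CLI) can distinguish user/input problems from contract violations.
"""


class OsteolysisError(Exception):
    """Base class for all package errors."""


class InputError(OsteolysisError):
    """A path or argument does not exist or is malformed."""


class FormatError(OsteolysisError):
    """An on-disk dataset violates the expected format (e.g. ragged slices)."""


class EmptyInputError(OsteolysisError):
    """An operation received a volume/image with no usable content."""


class DataError(OsteolysisError):
    """Voxel data violates a precondition (e.g. NaN intensities)."""


class SeedError(OsteolysisError):
    """A seed point does not land on foreground."""


class ResolutionError(OsteolysisError):
    """The requested physical scale is below what the voxel grid resolves."""


class ResolutionWarning(UserWarning):
    """The maximum lesion diameter is marginal for this voxel size."""


class ContractViolationError(OsteolysisError):
    """An inter-stage contract (e.g. reconstructed ⊇ original) is broken."""


class ParameterError(OsteolysisError):
    """Reconstruction/analysis parameters are out of range."""


class IdError(OsteolysisError):
    """A lesion id does not exist in the report."""


class BoundsError(OsteolysisError):
    """A coordinate lies outside the voxel grid."""


class PhantomSpecError(OsteolysisError):
    """A phantom specification is geometrically inconsistent."""
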