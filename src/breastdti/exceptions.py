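"""Package-specific exception types.

All errors raised by breastdti derive from :class:`BreastDTIError` so callers
can catch pipeline failures with a single except clause.
"""


class BreastDTIError(Exception):
    """Base class for all breastdti errors."""


class DegenerateDesignError(BreastDTIError):
    """Gradient scheme cannot support a full-rank tensor fit."""


class InvalidTensorError(BreastDTIError):
    """Requested diffusion tensor is not positive definite / not sorted."""


class MissingShellError(BreastDTIError):
    """No acquisitions exist at the requested b-value."""


class EmptyROIError(BreastDTIError):
    """Lesion ROI contains no voxels."""


class MultiSliceROIError(BreastDTIError):
    """Seed region spans more than one slice; ROIs are single-slice."""


class UnenhancedVoxelError(BreastDTIError):
    """Initial post-contrast signal is non-positive; kinetics undefined."""


class TransformError(BreastDTIError):
    """A log-transformed feature contains non-positive values."""


class ConfigError(BreastDTIError):
    """Invalid simulation or pipeline configuration."""


class UndefinedAUCError(BreastDTIError):
    """AUC requested with only one outcome class present."""


class FormatError(BreastDTIError):
    """On-disk data does not match the expected layout."""
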