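"""Exception hierarchy for the petkeyhole package."""


class KeyholeError(Exception):
    """Base class for all package errors."""


class VolumeFormatError(KeyholeError):
    """A volume file violates the expected NIfTI contract (dimensionality,
    spacing, negative voxels)."""


class LesionTableError(KeyholeError):
    """A lesion table violates its schema (missing columns, duplicate keys)."""


class ROIError(KeyholeError):
    """A reference ROI is geometrically invalid for the given volume
    (outside the grid, or too few voxels for stable statistics)."""


class PhantomConfigError(KeyholeError):
    """A phantom configuration violates its invariants (overlapping regions,
    lesion outside the grid, non-positive radii)."""


class CouplingError(KeyholeError):
    """The requested PSA/tumor-volume rank coupling is unreachable."""


class UndefinedBaselineError(KeyholeError):
    """Relative change is undefined because the baseline sum is zero."""


class MetricFamilyError(KeyholeError):
    """Two response calls from different metric families were compared."""


class ConstantInputError(KeyholeError):
    """Spearman correlation is undefined for a constant vector."""


class EmptyCohortError(KeyholeError):
    """A cohort-level operation received no patients."""
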