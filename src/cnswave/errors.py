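"""Exception hierarchy shared across the pipeline."""


class CnswaveError(Exception):
    """Base class for all package-specific errors."""


class VolumeFormatError(CnswaveError):
    """File exists but does not declare a usable 3D+time layout."""


class DegenerateInputError(CnswaveError):
    """Input is structurally valid but empty/degenerate for the operation."""


class IntegrityError(CnswaveError):
    """Compressed container failed a checksum or header consistency check."""


class EmptyStatsError(CnswaveError):
    """No usable triggered events were accumulated."""


class UndefinedPeakError(CnswaveError):
    """A peak time was requested on a flat (constant) trace."""


class SchemaError(CnswaveError):
    """Required ROI labels or table columns are missing."""
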