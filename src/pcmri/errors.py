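"""Exception hierarchy for the pcmri package."""


class PCMRIError(Exception):
    """Base class for all pcmri errors."""


class DomainError(PCMRIError, ValueError):
    """An argument lies outside the physically meaningful domain."""


class ConfigurationError(PCMRIError, ValueError):
    """Inconsistent or invalid acquisition/analysis configuration."""


class FormatError(PCMRIError):
    """On-disk data violates the expected format."""


class MetadataError(FormatError):
    """Sidecar metadata is missing or invalid."""


class SegmentationError(PCMRIError):
    """Lumen segmentation could not produce a usable mask or contour."""


class FittingError(PCMRIError):
    """A least-squares fit failed or violated its quality contract."""


class WSSError(PCMRIError):
    """Wall shear stress estimation failed (too many rays dropped)."""


class StudyError(PCMRIError):
    """A simulated study had too many failed cells to be summarised."""
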