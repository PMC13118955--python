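"""Exception hierarchy for the mesofluor pipeline.

Every stage raises a subclass of :class:`MesofluorError` so callers can
distinguish pipeline failures from programming errors, and the orchestration
layer can attach stage/well context when propagating.
"""


class MesofluorError(Exception):
    """Base class for all pipeline errors."""


class DimensionError(MesofluorError):
    """Image grids are not conformable."""


class DegenerateCalibrationError(MesofluorError):
    """The ND calibration channel carries no signal (sum of ND**2 is zero)."""


class InsufficientDataError(MesofluorError):
    """Too few observations for the requested statistic."""


class DegenerateDesignError(MesofluorError):
    """All predictor values identical; a regression slope is undefined."""


class InsufficientBackgroundError(MesofluorError):
    """Fewer background pixels than required for a stable threshold."""


class EmptySegmentationError(MesofluorError):
    """No pixel exceeded the threshold; the well is below detection, not zero."""


class PairingError(MesofluorError):
    """Pre/post (or platform) measurements could not be matched."""


class ProvenanceError(MesofluorError):
    """Measurements that must share provenance (e.g. thresholds) do not."""


class UndefinedFoldChangeError(MesofluorError):
    """Fold change undefined: non-positive baseline signal."""


class UndefinedReleaseError(MesofluorError):
    """Release fraction undefined: lysed and initial fluorescence coincide."""


class ConfigValidationError(MesofluorError):
    """An experiment configuration failed schema or consistency checks."""
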