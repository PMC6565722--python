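"""Exception hierarchy for the PPG blood-pressure pipeline."""


class PPGError(Exception):
    """Base class for all pipeline errors."""


class NoPulsatileActivityError(PPGError):
    """Raised when fewer than two pulse onsets can be found in a record."""


class BaselineInvalidError(PPGError):
    """Raised when the DC level of a beat is non-positive (perfusion index undefined)."""


class InsufficientCyclesError(PPGError):
    """Raised when fewer good-quality cardiac cycles are available than required."""


class RankDeficiencyError(PPGError):
    """Raised when the training beat matrix has lower rank than the requested basis size."""


class FeatureAssemblyError(PPGError):
    """Raised when a beat's 19-element feature vector cannot be assembled."""


class PredictionError(PPGError):
    """Raised when a measurement cannot be predicted (e.g. wrong beat count)."""


class CalibrationError(PPGError):
    """Raised for calibration-factor misuse (no priors, subject mismatch)."""
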