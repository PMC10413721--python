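"""Exception hierarchy for longmatch."""


class LongmatchError(Exception):
    """Base class for all longmatch errors."""


class ConfigurationError(LongmatchError):
    """A scenario or model configuration is invalid."""


class DataError(LongmatchError):
    """Generated or supplied panel data violates a contract."""


class CalibrationError(LongmatchError):
    """Intercept calibration failed to converge or the target is degenerate."""


class EstimationError(LongmatchError):
    """A propensity or effect model could not be estimated."""


class MatchingError(LongmatchError):
    """A matched cohort could not be constructed."""
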