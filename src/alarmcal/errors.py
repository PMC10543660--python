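"""Exception types shared across the package."""


class AlarmcalError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(AlarmcalError, ValueError):
    """A configuration or transform parameter is outside its valid range."""


class InvalidInputError(AlarmcalError, ValueError):
    """Input data violate a precondition (wrong alphabet, mismatched lengths, ...)."""


class UndefinedMetricError(AlarmcalError, ValueError):
    """A metric has no defined value for these inputs (e.g. zero exposure)."""


class NoValidLambdaError(AlarmcalError, RuntimeError):
    """Calibration produced an empty validated set; the risk is not
    controllable at the requested level with this model and grid."""
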