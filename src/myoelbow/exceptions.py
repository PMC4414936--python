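"""Exception hierarchy for myoelbow."""


class MyoelbowError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(MyoelbowError, ValueError):
    """A configuration or call parameter is outside its valid range."""


class StabilityError(ParameterError):
    """Recursive-filter poles would make the activation dynamics unstable."""


class DegenerateMVCError(MyoelbowError, ValueError):
    """The MVC trials carry no signal, so no normalization scale exists."""


class CalibrationError(MyoelbowError, RuntimeError):
    """Calibration could not be performed on the supplied trial."""


class SignalFileError(MyoelbowError, ValueError):
    """A delimited signal file could not be parsed or is malformed."""
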