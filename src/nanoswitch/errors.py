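"""Exception types raised across the package."""


class NanoswitchError(Exception):
    """Base class for package errors."""


class InputError(NanoswitchError, ValueError):
    """Invalid argument or malformed input data."""


class CalibrationError(NanoswitchError):
    """Calibration cannot be performed with the supplied data."""


class FitConvergenceError(CalibrationError):
    """Nonlinear least squares failed to converge; carries context."""

    def __init__(self, message: str, p0=None, data_summary=None):
        super().__init__(message)
        self.p0 = p0
        self.data_summary = data_summary
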