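"""Exception hierarchy shared across the pipeline stages."""


class MotorPLSError(Exception):
    """Base class for all package errors."""


class InvalidModelError(MotorPLSError):
    """A physical or statistical model was constructed with invalid parameters."""


class InputError(MotorPLSError):
    """An input series or table violates a precondition (NaNs, too short, wrong shape)."""


class FitError(MotorPLSError):
    """A parameter fit could not be carried out (degenerate or under-determined data)."""


class DegenerateDataError(MotorPLSError):
    """Data with no usable variance (flat signal, zero-variance column, zero-RMS waveform)."""


class RankDeficiencyError(MotorPLSError):
    """A regression design matrix is rank deficient."""

    def __init__(self, message, columns=None):
        super().__init__(message)
        self.columns = tuple(columns) if columns is not None else ()
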