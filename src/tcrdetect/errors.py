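"""Exception hierarchy for tcrdetect."""


class TCRDetectError(Exception):
    """Base class for all tcrdetect errors."""


class ModelParameterError(TCRDetectError, ValueError):
    """Invalid model parameter or argument."""


class IdentifiabilityError(TCRDetectError):
    """Calibration data cannot identify the model parameters."""


class DegenerateDataError(TCRDetectError):
    """Calibration data carries no usable signal (e.g. all counts zero)."""


class ConvergenceError(TCRDetectError):
    """Optimizer failed to converge from every starting point.

    Carries the best parameters found so far in ``best_result``.
    """

    def __init__(self, message, best_result=None):
        super().__init__(message)
        self.best_result = best_result


class UnreachableTargetError(TCRDetectError):
    """A requested detection probability cannot be reached.

    ``max_achievable`` holds the largest attainable probability.
    """

    def __init__(self, message, max_achievable=None):
        super().__init__(message)
        self.max_achievable = max_achievable


class TableFormatError(TCRDetectError):
    """A clonotype or reference table does not match the expected format."""
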