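"""Exception hierarchy for the indicar package."""


class IndicarError(Exception):
    """Base class for all package-specific errors."""


class DataError(IndicarError):
    """Invalid or inconsistent input data (bad counts, unknown regions, ...)."""


class AdjacencyError(IndicarError):
    """Invalid neighbourhood structure (asymmetry, self-loops, bad labels)."""


class SingularityError(IndicarError):
    """A matrix that must be invertible is singular (e.g. lambda = 1)."""


class ConvergenceError(IndicarError):
    """An iterative fit failed to converge; carries the last iterate."""

    def __init__(self, message, last_iterate=None, trace=None):
        super().__init__(message)
        self.last_iterate = last_iterate
        self.trace = trace
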