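"""Exception hierarchy shared across the package."""


class HistgpError(Exception):
    """Base class for package errors."""


class ConfigurationError(HistgpError, ValueError):
    """Invalid simulation or model configuration."""


class DesignError(HistgpError, ValueError):
    """Field design arithmetic does not close (e.g. cohort not partitionable)."""


class DataError(HistgpError, ValueError):
    """Input data violate a precondition (missing ids, zero variance, ...)."""


class ConvergenceError(HistgpError, RuntimeError):
    """Iterative fit failed to converge; carries the iteration trace."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace if trace is not None else []
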