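"""Exception hierarchy shared across the pipeline stages."""


class CofracError(Exception):
    """Base class for all package errors."""


class TraceParseError(CofracError):
    """A trace file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(message if line is None else f"line {line}: {message}")


class InputError(CofracError):
    """Invalid or missing input data (exit code 3 at the CLI)."""


class StageError(CofracError):
    """A pipeline stage failed (exit code 4 at the CLI)."""


class PeakFitError(CofracError):
    """Nonlinear peak fit failed to converge; carries the best attempt."""

    def __init__(self, message: str, best_model=None):
        self.best_model = best_model
        super().__init__(message)
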