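"""Exception hierarchy shared across the package."""


class TepqualError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(TepqualError):
    """Invalid model or run configuration (e.g. mis-ordered cardinal temperatures)."""


class InputError(TepqualError, ValueError):
    """Invalid user-supplied data (negative PAR, unsorted series, bad CSV rows...)."""


class FittingError(TepqualError, RuntimeError):
    """Nonlinear least squares failed to converge after the documented restarts."""


class PipelineStageError(TepqualError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
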