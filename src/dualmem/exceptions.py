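"""Exception hierarchy shared across the package."""


class DualMemError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(DualMemError):
    """Invalid cohort or analysis configuration."""


class DataError(DualMemError):
    """Malformed, incomplete, or degenerate input data."""


class EstimationError(DualMemError):
    """Estimation cannot proceed (e.g. degenerate restudy proportions)."""


class StatsError(DualMemError):
    """Invalid input to a statistical test."""


class PipelineError(DualMemError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")
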