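"""Exception hierarchy shared across the package."""


class PPXError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(PPXError, ValueError):
    """Invalid configuration; the message names the offending field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class ClaimsValidationError(PPXError, ValueError):
    """A claims record failed validation; carries the 0-based row index."""

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")


class EstimationError(PPXError, RuntimeError):
    """The conditional likelihood has no usable information (no discordant sets)."""


class DegenerateEstimateError(EstimationError):
    """The conditional MLE lies on the boundary (OR -> 0 or infinity).

    ``kind`` is ``"infinite"`` when exposure occurs only in case periods
    among the informative sets and ``"zero"`` when it occurs only in
    control periods.
    """

    def __init__(self, kind: str, message: str = ""):
        self.kind = kind
        super().__init__(message or f"degenerate estimate: {kind} odds ratio")


class PipelineError(PPXError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
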