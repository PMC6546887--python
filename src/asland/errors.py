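"""Exception hierarchy shared across the package."""


class AslandError(Exception):
    """Base class for all package-specific errors."""


class ParseError(AslandError):
    """A standard-format input file could not be parsed."""


class StructuralViolation(AslandError):
    """A transcript or interval violates a structural invariant."""


class ConfigError(AslandError):
    """A simulation or pipeline configuration is invalid or infeasible."""


class StageError(AslandError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
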