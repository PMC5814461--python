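"""Exception hierarchy shared across the package."""


class HerbnetError(Exception):
    """Base class for all package errors."""


class FormatError(HerbnetError):
    """A chemical or tabular file violates its format contract."""


class SchemaError(HerbnetError):
    """A table is missing required columns."""


class IntegrityError(HerbnetError):
    """Cross-file referential integrity is violated."""


class ValidationError(HerbnetError):
    """An argument is outside its documented domain."""


class GenerationError(HerbnetError):
    """The synthetic-data generator could not satisfy its geometric constraints."""


class StageError(HerbnetError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
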