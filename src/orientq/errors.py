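"""Exception hierarchy shared across the pipeline stages."""


class OrientQError(Exception):
    """Base class for all package errors."""


class SchemaError(OrientQError, ValueError):
    """An input file or record violates the expected schema."""


class EmptyCorpusError(OrientQError, ValueError):
    """A corpus has no records (or an institution has none)."""


class ConfigError(OrientQError, ValueError):
    """An invalid configuration value or unknown backend/plugin name."""


class EmbeddingError(OrientQError, ValueError):
    """Texts could not be embedded (e.g. empty after normalization)."""


class StatementError(OrientQError, ValueError):
    """Statement extraction could not satisfy its contract."""


class FactorError(OrientQError, ValueError):
    """A factor-analysis precondition is violated."""


class PipelineError(OrientQError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
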