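"""Exception hierarchy shared by all txmap modules."""


class TxmapError(Exception):
    """Base class for all txmap errors."""


class ParseError(TxmapError):
    """A file could not be parsed (malformed row, non-numeric field, ...)."""


class ValidationError(TxmapError):
    """Parsed data violates an invariant (duplicate key, bad coordinates, ...)."""


class ConfigError(TxmapError):
    """A run configuration is missing fields or references unknown entities."""


class PipelineError(TxmapError):
    """A pipeline stage failed; the message is prefixed with the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
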