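"""Exception types shared across the pipeline."""


class TregpipeError(Exception):
    """Base class for all pipeline errors."""


class FormatError(TregpipeError):
    """An input file or table does not match the expected format."""


class EmptyRepertoireError(TregpipeError):
    """An operation that requires clones was given an empty repertoire."""


class EmptyInputError(TregpipeError):
    """An operation was given an empty input it cannot handle."""


class ConfigError(TregpipeError):
    """A run configuration failed validation."""
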