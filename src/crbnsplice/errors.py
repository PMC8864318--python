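"""Exception hierarchy shared across the pipeline."""


class CrbnSpliceError(Exception):
    """Base class for all pipeline errors."""


class ParseError(CrbnSpliceError):
    """A file could not be parsed (malformed line, missing cell, ...)."""


class SchemaError(CrbnSpliceError):
    """A tabular input is missing required columns or has invalid values."""


class ValidationError(CrbnSpliceError):
    """A domain-type invariant was violated."""


class ConfigurationError(CrbnSpliceError):
    """A configuration references unknown entities or is inconsistent."""
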