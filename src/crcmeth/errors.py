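"""Exception hierarchy shared across the pipeline.

The CLI maps these onto exit codes (config -> 2, data -> 3, degenerate -> 4).
"""


class CrcMethError(Exception):
    """Base class for all package errors."""


class ConfigError(CrcMethError):
    """Invalid configuration or parameter value."""


class DataError(CrcMethError):
    """Input data violates a structural requirement."""


class DegenerateInputError(CrcMethError):
    """Input is structurally valid but degenerate (e.g. an empty group)."""
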