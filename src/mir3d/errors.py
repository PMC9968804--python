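"""Exception types shared across the package."""


class Mir3dError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(Mir3dError, ValueError):
    """A configuration value is outside its valid range."""


class DataError(Mir3dError, ValueError):
    """Input data violates a structural invariant (shape, sign, ids)."""


class ParseError(Mir3dError, ValueError):
    """An on-disk file could not be parsed; message carries the line number."""


class PipelineError(Mir3dError, RuntimeError):
    """A pipeline stage failed; message names the stage."""
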