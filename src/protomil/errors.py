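"""Exception hierarchy.

Every error raised by the public API derives from :class:`ProtomilError`
so callers can catch one type at tool boundaries.
"""


class ProtomilError(Exception):
    """Base class for all package errors."""


class ParameterError(ProtomilError, ValueError):
    """An argument violates a documented precondition."""


class DataError(ProtomilError, ValueError):
    """Input data violate an invariant (non-finite values, bad shapes...)."""


class DimensionError(ProtomilError, ValueError):
    """Feature width does not match the consuming component."""


class FormatError(ProtomilError, ValueError):
    """An on-disk artifact is malformed; the message names the field."""


class CheckpointError(ProtomilError, ValueError):
    """A model checkpoint cannot be loaded (truncated, wrong version...)."""


class ConfigError(ProtomilError, ValueError):
    """A model/training configuration is internally inconsistent."""


class UnsupportedHeadError(ProtomilError, ValueError):
    """The requested operation is defined only for specific classifier heads."""
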