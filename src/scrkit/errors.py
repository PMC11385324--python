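"""Exception hierarchy shared across scrkit modules."""


class ScrkitError(Exception):
    """Base class for all scrkit errors."""


class AlphabetError(ScrkitError, ValueError):
    """A sequence contains characters outside the nucleotide alphabet."""


class StructureError(ScrkitError, ValueError):
    """A transcript violates a structural invariant (frame, terminal stop)."""


class FrameError(ScrkitError, ValueError):
    """A sequence length is incompatible with the reading frame."""


class PolicyError(ScrkitError, ValueError):
    """An invalid stop-decoding policy was requested."""


class ConfigError(ScrkitError, ValueError):
    """Invalid simulation or analysis configuration."""


class DataError(ScrkitError, ValueError):
    """Measured values violate a precondition (e.g. non-positive denominator)."""


class ShapeError(ScrkitError, ValueError):
    """Array-like inputs have incompatible shapes or lengths."""
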