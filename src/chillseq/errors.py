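"""Exception types shared across the package."""


class ChillseqError(ValueError):
    """Base class for all chillseq errors."""


class InvalidConfigError(ChillseqError):
    """A simulation or pipeline configuration violates its invariants."""


class DimensionError(ChillseqError):
    """Inputs whose shapes or index sets do not line up."""


class InvalidIntervalError(ChillseqError):
    """A genomic interval with start >= end or out of chromosome bounds."""
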