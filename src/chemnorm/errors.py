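class ChemnormError(Exception):
    """Base class for all package errors."""


class ParseError(ChemnormError):
    """A record in an input file could not be parsed; the message names the offending line or stanza."""


class ValidationError(ChemnormError):
    """An internal invariant was violated (cycle in the is_a graph, inconsistent index, ...)."""
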