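"""Exception hierarchy shared across the package."""


class ConbindError(Exception):
    """Base class for all conbind errors."""


class MotifConfigError(ConbindError, ValueError):
    """Invalid motif-family configuration (bad IUPAC code, empty family list, ...)."""


class EncodingError(ConbindError, ValueError):
    """Invalid symbol-encoding request (occurrence out of bounds, unknown symbol, ...)."""


class AlignmentError(ConbindError, ValueError):
    """Invalid alignment request (empty sequence, fewer than two sequences, ...)."""


class EvaluationError(ConbindError, ValueError):
    """Invalid evaluation request (no validated sites, mismatched sequence sets, ...)."""


class SimulationError(ConbindError, ValueError):
    """Invalid simulation parameters (motifs do not fit, probabilities out of range)."""


class ConfigError(ConbindError, ValueError):
    """Invalid run configuration or malformed input file."""
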