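"""Exception hierarchy for sstagg."""


class SSTError(Exception):
    """Base class for all sstagg errors."""


class GraphParseError(SSTError, ValueError):
    """An edge-list file could not be parsed (bad relation token, malformed line)."""


class ConfigurationError(SSTError, ValueError):
    """Missing or inconsistent configuration (e.g. no reference node given)."""


class DisconnectedGraphError(SSTError, ValueError):
    """The operation requires a connected graph but the input is disconnected."""


class UnbalancedGraphError(SSTError, ValueError):
    """A balanced-only operation was called on a causally inconsistent graph."""


class EnumerationCapError(SSTError, ValueError):
    """The number of spanning trees (or deletion subsets) exceeds the exact-engine cap."""


class CoverTimeError(SSTError, RuntimeError):
    """A random walker exceeded its step budget before covering the graph."""


class MissingScoreError(SSTError, KeyError):
    """A node of the graph has no score and zero-imputation was not requested."""
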