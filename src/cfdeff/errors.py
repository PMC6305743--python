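"""Exception hierarchy.

Each error class carries a distinct process exit code so that shell
pipelines can tell schema problems apart from statistical degeneracy.
"""


class CfdeffError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class SchemaError(CfdeffError):
    """Malformed input table: missing column, bad value, duplicate key."""

    exit_code = 2


class ArgumentError(CfdeffError):
    """A precondition on arguments or configuration was violated."""

    exit_code = 3


class ProtocolError(ArgumentError):
    """The drug-addition event sequence does not match the assay protocol."""

    exit_code = 3


class DegenerateDataError(CfdeffError):
    """Data with zero variance (or similar) where a statistic is undefined."""

    exit_code = 4


class InsufficientDataError(CfdeffError):
    """Too few observations (or histogram bins) for the requested statistic."""

    exit_code = 5
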