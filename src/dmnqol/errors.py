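"""Exception hierarchy shared across the package."""


class DmnQolError(Exception):
    """Base class for all package-specific errors."""


class ParseError(DmnQolError):
    """A delimited file contained a cell that could not be interpreted."""


class LengthError(DmnQolError):
    """A time series is too short for the requested operation."""


class SchemaError(DmnQolError):
    """A table is missing required columns or contains unknown names."""


class ParameterError(DmnQolError):
    """A configuration value is outside its valid domain."""


class DegenerateSignalError(DmnQolError):
    """An ROI signal has zero variance and cannot be correlated."""


class DegenerateGraphError(DmnQolError):
    """A graph has no edges (or no nodes) where structure is required."""


class PartitionError(DmnQolError):
    """A module partition does not cover the node set exactly once."""


class UndefinedRatioError(DmnQolError):
    """A ratio statistic has a zero denominator (e.g. C_rand = 0)."""


class ConsistencyError(DmnQolError):
    """Summary statistics are mutually inconsistent (e.g. mean ranks)."""


class CapacityError(DmnQolError):
    """An exact enumeration was requested beyond the supported size."""


class JoinError(DmnQolError):
    """Two subject-level tables could not be aligned on subject ids."""
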