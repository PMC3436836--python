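"""Shared exception types."""


class MTDMinerError(Exception):
    """Base class for all package errors."""


class FormatError(MTDMinerError):
    """Unreadable or malformed input file."""


class EmptyStructureError(MTDMinerError):
    """Structure contains no usable atoms."""


class UnsupportedGridError(MTDMinerError):
    """Scalar grid is missing metadata or is non-axis-aligned."""


class DegenerateGeometryError(MTDMinerError):
    """Geometry collapses to a point or otherwise cannot be meshed."""


class MappingError(MTDMinerError):
    """Grid and mesh do not overlap in space."""


class DataError(MTDMinerError):
    """Inconsistent or degenerate input data."""
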