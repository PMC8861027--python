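"""Typed exceptions shared across the package."""


class FluxdryError(Exception):
    """Base class for all package errors."""


class ParameterError(FluxdryError, ValueError):
    """An invalid parameter value; message names the offending field."""


class SchemaError(FluxdryError, ValueError):
    """A table is missing mandatory columns or has an unusable layout."""


class FormatError(FluxdryError, ValueError):
    """A cell could not be parsed; message carries the row number."""


class ContractError(FluxdryError, ValueError):
    """A precondition between pipeline stages was violated."""


class DegenerateVariableError(FluxdryError, ValueError):
    """A variable has zero variance and cannot be standardized."""


class BinningError(FluxdryError, ValueError):
    """Too few days (or degenerate values) to form percentile bins."""


class CollinearityError(FluxdryError, ValueError):
    """Rank-deficient regression design."""


class InsufficientReplicationError(FluxdryError, ValueError):
    """Fewer sites than the cross-site summary requires."""


class GeometryError(FluxdryError, ValueError):
    """Unphysical tower/canopy geometry or wind input."""


class UsageError(FluxdryError, ValueError):
    """Unknown mode, variable or option name."""


class ConfigError(FluxdryError, ValueError):
    """Run configuration failed schema validation."""
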