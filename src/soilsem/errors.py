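"""Exception hierarchy.

All package errors derive from :class:`SoilSemError` so callers can catch
everything with one clause; subclasses mirror the failure modes of the
pipeline stages (invalid designs, bad configuration, schema violations,
numerical domain errors, convergence bookkeeping).
"""


class SoilSemError(Exception):
    """Base class for all soilsem errors."""


class InvalidDesignError(SoilSemError, ValueError):
    """A study design violates its invariants (e.g. non-monotone depths)."""


class ConfigurationError(SoilSemError, ValueError):
    """A generator/model/MCMC configuration is inconsistent."""


class DomainError(SoilSemError, ValueError):
    """A numeric input is outside the mathematical domain of an operation."""


class SchemaError(SoilSemError, ValueError):
    """A table does not match its registered schema."""


class ShapeError(SoilSemError, ValueError):
    """Array dimensions do not match the model specification."""


class DegenerateColumnError(SoilSemError, ValueError):
    """A manifest column is constant and cannot be standardized."""


class InsufficientDataError(SoilSemError, ValueError):
    """Too few observations/draws for the requested statistic."""


class NegativeFlushError(DomainError):
    """Fumigated extract below unfumigated control in a CFE measurement."""


class IncompleteCombustionError(DomainError):
    """A thermogram never reaches the 50% evolved-CO2 crossing."""
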