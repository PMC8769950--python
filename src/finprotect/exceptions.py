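"""Exception hierarchy for finprotect.

All package errors derive from :class:`FinprotectError` so callers can catch
one base class; subclasses mark which pipeline stage the problem belongs to.
"""


class FinprotectError(Exception):
    """Base class for all finprotect errors."""


class ConfigurationError(FinprotectError):
    """Invalid generator or pipeline configuration; message names the field."""


class SchemaError(FinprotectError):
    """Household table violates the expected schema (message carries column
    name and, where applicable, the offending row index)."""


class DomainError(FinprotectError):
    """Inputs outside the mathematical domain of an operation
    (negative expenditure, nonpositive poverty line, ...)."""


class DesignError(FinprotectError):
    """Survey design unusable for variance estimation (e.g. a stratum with a
    single PSU and no fallback enabled)."""


class PovertyLineError(FinprotectError):
    """Poverty-line construction failed (missing price, empty band window)."""


class AssetIndexError(FinprotectError):
    """Asset matrix degenerate (no variation) or otherwise unusable for PCA."""


class SeparationError(FinprotectError):
    """(Quasi-)complete separation detected while fitting a logistic model;
    message names the diverging term."""


class ModelError(FinprotectError):
    """Logistic model cannot be fitted (e.g. single-class outcome)."""
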