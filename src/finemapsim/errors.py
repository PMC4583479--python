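"""Exception hierarchy.

``ConfigError`` maps to CLI exit code 2, ``DataError`` (and subclasses) to 3.
"""


class FinemapSimError(Exception):
    """Base class for all package errors."""


class ConfigError(FinemapSimError):
    """Invalid configuration or parameter values."""


class DataError(FinemapSimError):
    """Invalid, inconsistent, or infeasible data."""


class PanelError(DataError):
    """Haplotype panel construction or I/O failure."""


class MonomorphicVariantError(DataError):
    """An operation that requires a polymorphic variant hit a monomorphic one.

    Raised instead of silently returning 0 so callers can distinguish
    "no correlation" from "correlation undefined".
    """


class SimulationError(DataError):
    """Case-control simulation could not satisfy its constraints
    (e.g. an empty required causal-allele haplotype class)."""
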