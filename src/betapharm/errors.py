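"""Exception hierarchy for betapharm.

All package errors derive from :class:`BetapharmError` so callers can
catch the whole family; batch drivers catch it per group and record a
failure status instead of aborting the run.
"""


class BetapharmError(Exception):
    """Base class for all betapharm errors."""


class SchemaError(BetapharmError):
    """A tabular input is missing a required column or has a bad header."""


class ValidationError(BetapharmError):
    """A parsed value violates a dataset invariant (row-level)."""


class UnitError(BetapharmError):
    """An unrecognized or unresolvable concentration/time unit."""


class NormalizationError(BetapharmError):
    """A (receptor, pathway) group lacks basal or reference wells."""


class InsufficientDataError(BetapharmError):
    """Too few points/doses/traces for the requested fit."""


class IdentifiabilityError(BetapharmError):
    """The experimental design cannot separate the requested parameters.

    Raised e.g. for competition-kinetics datasets containing only
    competitor-free traces, where k3 and k4 do not enter the model.
    """


class WindowError(BetapharmError):
    """A time window excludes every data point."""


class SelectionError(BetapharmError):
    """An atom/residue selector resolved to zero or multiple atoms."""


class MatchingError(BetapharmError):
    """Two structures/profiles share too few residues to compare."""


class DomainError(BetapharmError):
    """A numeric argument is outside the mathematical domain."""


class SpecError(BetapharmError):
    """A synthetic-data spec or run configuration is invalid."""
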