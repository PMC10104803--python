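"""Unit handling.

Internal convention: concentrations in molar, time in seconds, rates in
s^-1 and M^-1 s^-1.  All conversion happens at the I/O boundary; nothing
downstream of the readers ever sees nM or minutes.
"""

from __future__ import annotations

from betapharm.errors import UnitError

#: multiplicative factors to molar
CONCENTRATION_UNITS: dict[str, float] = {
    "M": 1.0,
    "mM": 1e-3,
    "uM": 1e-6,
    "µM": 1e-6,  # µM
    "nM": 1e-9,
    "pM": 1e-12,
    "fM": 1e-15,
}

#: multiplicative factors to seconds
TIME_UNITS: dict[str, float] = {
    "s": 1.0,
    "sec": 1.0,
    "ms": 1e-3,
    "min": 60.0,
    "h": 3600.0,
    "hr": 3600.0,
}


def to_molar(value: float, unit: str) -> float:
    """Convert a concentration in *unit* to molar."""
    try:
        return value * CONCENTRATION_UNITS[unit]
    except KeyError:
        raise UnitError(f"unknown concentration unit {unit!r}; "
                        f"known: {sorted(CONCENTRATION_UNITS)}") from None


def from_molar(value: float, unit: str) -> float:
    """Convert a molar concentration to *unit* (exact inverse of to_molar)."""
    try:
        return value / CONCENTRATION_UNITS[unit]
    except KeyError:
        raise UnitError(f"unknown concentration unit {unit!r}") from None


def to_seconds(value: float, unit: str) -> float:
    """Convert a time in *unit* to seconds."""
    try:
        return value * TIME_UNITS[unit]
    except KeyError:
        raise UnitError(f"unknown time unit {unit!r}; "
                        f"known: {sorted(TIME_UNITS)}") from None


def from_seconds(value: float, unit: str) -> float:
    try:
        return value / TIME_UNITS[unit]
    except KeyError:
        raise UnitError(f"unknown time unit {unit!r}") from None
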