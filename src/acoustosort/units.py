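"""Unit parsing and conversion.

Every function in the library computes in SI (metres, seconds, cubic
metres, pascals, particles per cubic metre).  Configuration files and the
command line, however, speak the units natural to the instrument — ``um``,
``ul/s``, ``ms``, ``MHz``, ``nl``, ``cells/ml`` — so silent unit mistakes
are the dominant implementation risk.  This module is the single place
where those strings are converted, via a small grammar:

    quantity  := number [whitespace] unit
    unit      := product [ "/" product ]
    product   := token { whitespace token }

e.g. ``"0.08 ul/s"`` -> 8e-11 m^3/s, ``"25 mPa s"`` -> 0.025 Pa s.
"""

from __future__ import annotations

import re

__all__ = ["si_factor", "parse_quantity", "to_si", "from_si", "UnitError"]


class UnitError(ValueError):
    """Raised for an unrecognised unit token or malformed quantity."""


#: multiplicative factor taking one of <token> to its SI equivalent
_FACTORS: dict[str, float] = {
    "": 1.0,
    "1": 1.0,
    # length
    "m": 1.0, "cm": 1e-2, "mm": 1e-3, "um": 1e-6, "nm": 1e-9,
    # area / volume
    "m^2": 1.0, "mm^2": 1e-6, "um^2": 1e-12,
    "m^3": 1.0, "l": 1e-3, "L": 1e-3, "ml": 1e-6, "ul": 1e-9,
    "nl": 1e-12, "pl": 1e-15,
    # time
    "s": 1.0, "ms": 1e-3, "us": 1e-6, "ns": 1e-9, "min": 60.0, "h": 3600.0,
    # frequency
    "Hz": 1.0, "kHz": 1e3, "MHz": 1e6, "GHz": 1e9,
    # pressure / stress
    "Pa": 1.0, "mPa": 1e-3, "kPa": 1e3, "MPa": 1e6,
    # force / energy / power
    "N": 1.0, "mN": 1e-3, "uN": 1e-6, "nN": 1e-9, "pN": 1e-12,
    "J": 1.0, "mJ": 1e-3, "W": 1.0, "mW": 1e-3,
    # mass
    "kg": 1.0, "g": 1e-3, "mg": 1e-6,
    # counts (dimensionless tallies used in concentrations)
    "cells": 1.0, "beads": 1.0, "events": 1.0, "particles": 1.0,
}

_QUANTITY_RE = re.compile(
    r"^\s*([+-]?(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?)\s*(.*?)\s*$"
)


def _normalise(unit: str) -> str:
    return (
        unit.replace("μ", "u")  # μ
        .replace("µ", "u")      # µ
        .replace("³", "^3")
        .replace("²", "^2")
        .replace("**", "^")
        .strip()
    )


def _product_factor(expr: str) -> float:
    factor = 1.0
    for token in expr.split():
        try:
            factor *= _FACTORS[token]
        except KeyError:
            raise UnitError(f"unknown unit token {token!r} in {expr!r}") from None
    return factor


def si_factor(unit: str) -> float:
    """Multiplicative factor converting a value in *unit* to SI.

    Supports a single division, products separated by spaces and the
    exponents ^2 / ^3 on the base tokens present in the table.
    """
    unit = _normalise(unit)
    if unit in _FACTORS:
        return _FACTORS[unit]
    if unit.count("/") > 1:
        raise UnitError(f"at most one '/' supported, got {unit!r}")
    if "/" in unit:
        num, den = unit.split("/")
        den_factor = _product_factor(den)
        if den_factor == 0:
            raise UnitError(f"zero denominator factor in {unit!r}")
        return _product_factor(num) / den_factor
    return _product_factor(unit)


def to_si(value: float, unit: str) -> float:
    return float(value) * si_factor(unit)


def from_si(value: float, unit: str) -> float:
    return float(value) / si_factor(unit)


def parse_quantity(text, unit: str | None = None) -> float:
    """Parse ``"0.08 ul/s"`` (or a bare number) into an SI float.

    Parameters
    ----------
    text:
        A string ``"<number> <unit>"``, or a bare number.  Bare numbers
        are interpreted in *unit* when given, otherwise as already-SI.
    unit:
        Default unit applied to bare numbers.
    """
    if isinstance(text, (int, float)):
        return to_si(text, unit) if unit else float(text)
    m = _QUANTITY_RE.match(str(text))
    if m is None:
        raise UnitError(f"cannot parse quantity {text!r}")
    value, parsed_unit = float(m.group(1)), m.group(2)
    if not parsed_unit:
        return to_si(value, unit) if unit else value
    return to_si(value, parsed_unit)
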