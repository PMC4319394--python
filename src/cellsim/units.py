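"""Dimensional analysis over the seven SI base dimensions.

A :class:`Dimension` is a vector of rational exponents over
(metre, kilogram, second, ampere, kelvin, mole, candela), together with a
multiplicative factor relative to the coherent SI unit of that dimension and
an additive offset (only Celsius-style units use it).  Booleans — the results
of relational and logical operators — are modelled as a pseudo-dimension that
is incompatible with every physical dimension.

The full CellML built-in units table is provided, and user units definitions
are expanded recursively with cycle detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

from .errors import CircularUnitsError

BASE_DIMENSIONS = ("metre", "kilogram", "second", "ampere", "kelvin",
                   "mole", "candela")

_ZERO = (Fraction(0),) * 7


def _exp(**kw) -> tuple:
    v = [Fraction(0)] * 7
    for name, e in kw.items():
        v[BASE_DIMENSIONS.index(name)] = Fraction(e)
    return tuple(v)


@dataclass(frozen=True)
class Dimension:
    """Exponent vector + scale factor (+ optional offset) of a unit."""

    exponents: tuple = _ZERO
    multiplier: float = 1.0
    offset: float = 0.0
    boolean: bool = False

    @property
    def dimensionless(self) -> bool:
        return not self.boolean and all(e == 0 for e in self.exponents)

    def same_dimension(self, other: "Dimension") -> bool:
        """Exponent vectors (and booleanness) agree; scale may differ."""
        return (self.boolean == other.boolean
                and self.exponents == other.exponents)

    def same_scale(self, other: "Dimension", rtol: float = 1e-9) -> bool:
        a, b = self.multiplier, other.multiplier
        return abs(a - b) <= rtol * max(abs(a), abs(b))

    def __mul__(self, other: "Dimension") -> "Dimension":
        return Dimension(
            tuple(a + b for a, b in zip(self.exponents, other.exponents)),
            self.multiplier * other.multiplier)

    def __truediv__(self, other: "Dimension") -> "Dimension":
        return Dimension(
            tuple(a - b for a, b in zip(self.exponents, other.exponents)),
            self.multiplier / other.multiplier)

    def __pow__(self, k) -> "Dimension":
        q = Fraction(k).limit_denominator(10**6)
        return Dimension(tuple(e * q for e in self.exponents),
                         self.multiplier ** float(q))

    def describe(self) -> str:
        if self.boolean:
            return "boolean"
        parts = [f"{n}^{e}" for n, e in zip(BASE_DIMENSIONS, self.exponents)
                 if e != 0]
        body = "*".join(parts) if parts else "dimensionless"
        if self.multiplier != 1.0:
            body += f" x{self.multiplier:g}"
        return body


DIMENSIONLESS = Dimension()
BOOLEAN = Dimension(boolean=True)

# The CellML built-in units table.  Multipliers are relative to the coherent
# SI unit of each dimension (gram = 1e-3 kg, litre = 1e-3 m^3, ...).
BUILTIN_UNITS: dict = {
    "ampere": Dimension(_exp(ampere=1)),
    "becquerel": Dimension(_exp(second=-1)),
    "candela": Dimension(_exp(candela=1)),
    "celsius": Dimension(_exp(kelvin=1), offset=273.15),
    "coulomb": Dimension(_exp(second=1, ampere=1)),
    "dimensionless": DIMENSIONLESS,
    "farad": Dimension(_exp(metre=-2, kilogram=-1, second=4, ampere=2)),
    "gram": Dimension(_exp(kilogram=1), 1e-3),
    "gray": Dimension(_exp(metre=2, second=-2)),
    "henry": Dimension(_exp(metre=2, kilogram=1, second=-2, ampere=-2)),
    "hertz": Dimension(_exp(second=-1)),
    "joule": Dimension(_exp(metre=2, kilogram=1, second=-2)),
    "katal": Dimension(_exp(second=-1, mole=1)),
    "kelvin": Dimension(_exp(kelvin=1)),
    "kilogram": Dimension(_exp(kilogram=1)),
    "liter": Dimension(_exp(metre=3), 1e-3),
    "litre": Dimension(_exp(metre=3), 1e-3),
    "lumen": Dimension(_exp(candela=1)),
    "lux": Dimension(_exp(metre=-2, candela=1)),
    "meter": Dimension(_exp(metre=1)),
    "metre": Dimension(_exp(metre=1)),
    "mole": Dimension(_exp(mole=1)),
    "newton": Dimension(_exp(metre=1, kilogram=1, second=-2)),
    "ohm": Dimension(_exp(metre=2, kilogram=1, second=-3, ampere=-2)),
    "pascal": Dimension(_exp(metre=-1, kilogram=1, second=-2)),
    "radian": DIMENSIONLESS,
    "second": Dimension(_exp(second=1)),
    "siemens": Dimension(_exp(metre=-2, kilogram=-1, second=3, ampere=2)),
    "sievert": Dimension(_exp(metre=2, second=-2)),
    "steradian": DIMENSIONLESS,
    "tesla": Dimension(_exp(kilogram=1, second=-2, ampere=-1)),
    "volt": Dimension(_exp(metre=2, kilogram=1, second=-3, ampere=-1)),
    "watt": Dimension(_exp(metre=2, kilogram=1, second=-3)),
    "weber": Dimension(_exp(metre=2, kilogram=1, second=-2, ampere=-1)),
}

SI_PREFIXES: dict = {
    "yotta": 24, "zetta": 21, "exa": 18, "peta": 15, "tera": 12,
    "giga": 9, "mega": 6, "kilo": 3, "hecto": 2, "deka": 1, "deca": 1,
    "deci": -1, "centi": -2, "milli": -3, "micro": -6, "nano": -9,
    "pico": -12, "femto": -15, "atto": -18, "zepto": -21, "yocto": -24,
}


def prefix_exponent(prefix) -> int:
    """Turn a CellML prefix attribute (name or integer string) into an int."""
    if prefix is None or prefix == "":
        return 0
    if isinstance(prefix, int):
        return prefix
    p = str(prefix).strip()
    if p in SI_PREFIXES:
        return SI_PREFIXES[p]
    return int(p)


class UnitsEnvironment:
    """Resolves units names to :class:`Dimension`, expanding user definitions.

    ``definitions`` maps a units name to a list of part tuples
    ``(units, prefix_exponent, exponent, multiplier, offset)`` or to the
    empty list for ``base_units="yes"`` definitions (treated as fresh,
    mutually incomparable base dimensions are out of scope — a user base unit
    is mapped to dimensionless with multiplier 1 and flagged).
    """

    def __init__(self, definitions=None):
        self.definitions = dict(definitions or {})
        self._cache: dict = {}

    def knows(self, name: str) -> bool:
        return name in BUILTIN_UNITS or name in self.definitions

    def resolve(self, name: str) -> Dimension:
        return self._resolve(name, ())

    def _resolve(self, name: str, stack: tuple) -> Dimension:
        if name in self._cache:
            return self._cache[name]
        if name in stack:
            chain = stack[stack.index(name):] + (name,)
            raise CircularUnitsError(
                "circular units definition: " + " -> ".join(chain))
        # User definitions shadow nothing: shadowing is rejected at
        # validation time, so lookup order is irrelevant for valid models.
        if name in self.definitions:
            parts = self.definitions[name]
            if not parts:          # base_units="yes"
                dim = DIMENSIONLESS
            else:
                dim = Dimension()
                for (units, pfx, expo, mult, offs) in parts:
                    child = self._resolve(units, stack + (name,))
                    factor = mult * (10.0 ** pfx * child.multiplier) ** expo
                    contrib = Dimension(
                        tuple(e * Fraction(expo).limit_denominator(10**6)
                              for e in child.exponents),
                        factor, offs if offs else 0.0)
                    dim = Dimension(
                        tuple(a + b for a, b in
                              zip(dim.exponents, contrib.exponents)),
                        dim.multiplier * contrib.multiplier,
                        dim.offset or contrib.offset)
        elif name in BUILTIN_UNITS:
            dim = BUILTIN_UNITS[name]
        else:
            raise KeyError(f"unknown units name: {name!r}")
        self._cache[name] = dim
        return dim
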