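"""Exact elemental-formula arithmetic and monoisotopic mass computation.

Every mass, m/z and biotransformation mass shift in the pipeline is derived
from the fixed monoisotopic isotope table below, so results do not depend on
any external library's constants.

Two protonation conventions are supported for [M+H]+ m/z:

* ``hydrogen-atom`` (default): neutral mass + mass of a hydrogen *atom*
  (1.0078250319 Da).  High-resolution screening software frequently reports
  protonated masses this way (the electron mass is not subtracted), and it is
  the convention under which sibiriline's [M+H]+ prints as 211.0871.
* ``proton``: neutral mass + mass of a bare proton (1.00727646688 Da), the
  physically exact convention for a singly protonated cation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Mapping

__all__ = [
    "MONOISOTOPIC_MASSES",
    "HYDROGEN_ATOM_MASS",
    "PROTON_MASS",
    "FormulaError",
    "InfeasibleTransformation",
    "ElementalFormula",
    "MassConventions",
    "parse_formula",
    "format_formula",
    "monoisotopic_mass",
    "protonated_mz",
    "combine",
]

#: Monoisotopic masses (Da) of the most abundant isotope of each element.
MONOISOTOPIC_MASSES: Dict[str, float] = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
    "P": 30.97376151,
    "F": 18.9984032,
    "Cl": 34.96885271,
    "Br": 78.9183376,
    "I": 126.904468,
    "Na": 22.98976928,
    "K": 38.9637069,
}

HYDROGEN_ATOM_MASS = 1.0078250319
PROTON_MASS = 1.00727646688

# Hill ordering: C, H first, remaining elements alphabetical.
_HILL_HEAD = ("C", "H")

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for unparseable or chemically invalid formula input."""


class InfeasibleTransformation(ValueError):
    """Raised when applying an elemental delta would drive a count below zero.

    Signals that a biotransformation rule is not applicable to a formula.
    """


@dataclass(frozen=True)
class ElementalFormula:
    """An element -> count mapping with exact monoisotopic mass arithmetic."""

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for elem, n in dict(self.counts).items():
            if elem not in MONOISOTOPIC_MASSES:
                raise FormulaError(f"unknown element symbol: {elem!r}")
            if not isinstance(n, int):
                raise FormulaError(f"non-integer count for {elem}: {n!r}")
            if n < 0:
                raise FormulaError(f"negative count for {elem}: {n}")
            if n > 0:
                clean[elem] = n
        object.__setattr__(self, "counts", clean)

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self)

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        return combine(self, other.counts)

    def __str__(self) -> str:
        return format_formula(self)

    def __hash__(self) -> int:
        return hash(frozenset(self.counts.items()))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ElementalFormula):
            return NotImplemented
        return dict(self.counts) == dict(other.counts)


@dataclass(frozen=True)
class MassConventions:
    """Mass constants and [M+H]+ convention used to turn formulas into m/z."""

    isotope_masses: Mapping[str, float] = field(
        default_factory=lambda: dict(MONOISOTOPIC_MASSES)
    )
    protonation_mode: str = "hydrogen-atom"
    hydrogen_atom_mass: float = HYDROGEN_ATOM_MASS
    proton_mass: float = PROTON_MASS

    def __post_init__(self) -> None:
        if self.protonation_mode not in ("hydrogen-atom", "proton"):
            raise ValueError(
                f"protonation_mode must be 'hydrogen-atom' or 'proton', "
                f"got {self.protonation_mode!r}"
            )
        if not self.hydrogen_atom_mass > self.proton_mass:
            raise ValueError("hydrogen-atom mass must exceed proton mass")
        for name, m in (
            ("hydrogen_atom_mass", self.hydrogen_atom_mass),
            ("proton_mass", self.proton_mass),
        ):
            if not 1.0072 <= m <= 1.0079:
                raise ValueError(f"{name} {m} outside 1.0072-1.0079 Da")

    @property
    def proton_adduct_mass(self) -> float:
        if self.protonation_mode == "hydrogen-atom":
            return self.hydrogen_atom_mass
        return self.proton_mass


DEFAULT_CONVENTIONS = MassConventions()


def parse_formula(text: str) -> ElementalFormula:
    """Parse ``"C13H10N2O"`` or underscore-style ``"C_13_H_10_N_2_O"``.

    Raises :class:`FormulaError` on empty input, unknown element symbols or
    explicit zero counts.
    """
    if not isinstance(text, str):
        raise FormulaError(f"formula must be a string, got {type(text).__name__}")
    compact = text.replace("_", "").strip()
    if not compact:
        raise FormulaError("empty formula string")
    counts: Dict[str, int] = {}
    pos = 0
    while pos < len(compact):
        m = _TOKEN.match(compact, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise FormulaError(f"cannot parse formula {text!r} at position {pos}")
        elem, digits = m.group(1), m.group(2)
        if elem not in MONOISOTOPIC_MASSES:
            raise FormulaError(f"unknown element symbol {elem!r} in {text!r}")
        n = int(digits) if digits else 1
        if n <= 0:
            raise FormulaError(f"zero count for {elem} in {text!r}")
        counts[elem] = counts.get(elem, 0) + n
        pos = m.end()
    return ElementalFormula(counts)


def format_formula(f: ElementalFormula) -> str:
    """Format in Hill order (C, H, then alphabetical); empty formula -> ''."""
    parts = []
    rest = sorted(e for e in f.counts if e not in _HILL_HEAD)
    for elem in (*_HILL_HEAD, *rest):
        n = f.counts.get(elem, 0)
        if n == 0:
            continue
        parts.append(elem if n == 1 else f"{elem}{n}")
    return "".join(parts)


def monoisotopic_mass(
    f: ElementalFormula, conv: MassConventions = DEFAULT_CONVENTIONS
) -> float:
    """Neutral monoisotopic mass in Da; additive over formula sums."""
    total = 0.0
    for elem, n in f.counts.items():
        try:
            total += n * conv.isotope_masses[elem]
        except KeyError:
            raise FormulaError(f"element {elem!r} absent from isotope table")
    return total


def protonated_mz(
    f: ElementalFormula, conv: MassConventions = DEFAULT_CONVENTIONS
) -> float:
    """[M+H]+ m/z under the convention selected in ``conv``."""
    return monoisotopic_mass(f, conv) + conv.proton_adduct_mass


def combine(f: ElementalFormula, delta: Mapping[str, int]) -> ElementalFormula:
    """Apply a signed elemental delta; negative resulting counts are infeasible."""
    counts = dict(f.counts)
    for elem, d in delta.items():
        if elem not in MONOISOTOPIC_MASSES:
            raise FormulaError(f"unknown element symbol in delta: {elem!r}")
        new = counts.get(elem, 0) + d
        if new < 0:
            raise InfeasibleTransformation(
                f"delta {dict(delta)} drives {elem} below zero in {format_formula(f)}"
            )
        counts[elem] = new
    return ElementalFormula(counts)


def delta_mass(delta: Mapping[str, int], conv: MassConventions = DEFAULT_CONVENTIONS) -> float:
    """Signed monoisotopic mass of an elemental delta (may be negative)."""
    total = 0.0
    for elem, d in delta.items():
        try:
            total += d * conv.isotope_masses[elem]
        except KeyError:
            raise FormulaError(f"element {elem!r} absent from isotope table")
    return total
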