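"""Molecular formulas, monoisotopic masses and ionization adducts.

A :class:`MolecularFormula` is an element -> count mapping with strictly
non-negative counts.  Deuterium is tracked as its own symbol ``D`` so that
isotope-labeled standards keep their label through all arithmetic; its mass
is that of :sup:`2`\\ H.  Arithmetic helpers additionally accept *signed*
element deltas (plain dicts), which is how adduct gains/losses and OzID
neutral losses are expressed.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass, field

__all__ = [
    "MolecularFormula",
    "Adduct",
    "ADDUCTS",
    "MONOISOTOPIC_MASS",
    "ELECTRON_MASS",
    "PROTON_MASS",
    "FormulaError",
]

# Principal-isotope masses (Da), IUPAC 2021, truncated to 6 decimals for
# bit-reproducibility across platforms.
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.007825,
    "D": 2.014102,
    "N": 14.003074,
    "O": 15.994915,
    "P": 30.973762,
    "S": 31.972071,
    "Na": 22.989769,
    "K": 38.963706,
    "Cl": 34.968853,
}

ELECTRON_MASS = 0.000549
PROTON_MASS = MONOISOTOPIC_MASS["H"] - ELECTRON_MASS  # 1.007276


class FormulaError(ValueError):
    """Raised when formula arithmetic would produce a negative count."""


@dataclass(frozen=True)
class MolecularFormula:
    """Immutable element->count map with monoisotopic-mass semantics."""

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for el, n in dict(self.counts).items():
            if el not in MONOISOTOPIC_MASS:
                raise FormulaError(f"unknown element symbol: {el!r}")
            n = int(n)
            if n < 0:
                raise FormulaError(f"negative count for {el}: {n}")
            if n > 0:
                clean[el] = n
        object.__setattr__(self, "counts", clean)

    def __getitem__(self, el: str) -> int:
        return self.counts.get(el, 0)

    def __bool__(self) -> bool:
        return bool(self.counts)

    def __add__(self, other: "MolecularFormula | Mapping[str, int]") -> "MolecularFormula":
        return self.shift(other, sign=+1)

    def __sub__(self, other: "MolecularFormula | Mapping[str, int]") -> "MolecularFormula":
        return self.shift(other, sign=-1)

    def shift(self, delta: "MolecularFormula | Mapping[str, int]", sign: int = +1) -> "MolecularFormula":
        """Apply a signed element delta; raise :class:`FormulaError` on underflow."""
        other = delta.counts if isinstance(delta, MolecularFormula) else delta
        out = dict(self.counts)
        for el, n in other.items():
            new = out.get(el, 0) + sign * int(n)
            if new < 0:
                raise FormulaError(
                    f"element {el} would drop below zero ({out.get(el, 0)} {'+' if sign > 0 else '-'} {n})"
                )
            out[el] = new
        return MolecularFormula(out)

    def substitute_h_with_d(self, n: int) -> "MolecularFormula":
        """Replace ``n`` hydrogens with deuterium (isotope labeling)."""
        if n == 0:
            return self
        if self["H"] < n:
            raise FormulaError(f"cannot label {n} H as D: only {self['H']} H present")
        out = dict(self.counts)
        out["H"] -= n
        out["D"] = out.get("D", 0) + n
        return MolecularFormula(out)

    @property
    def monoisotopic_mass(self) -> float:
        return sum(MONOISOTOPIC_MASS[el] * n for el, n in self.counts.items())

    def hill(self) -> str:
        """Hill-order string (C, H, then alphabetical; D folded after H)."""
        order = ["C", "H", "D"] + sorted(set(self.counts) - {"C", "H", "D"})
        parts = []
        for el in order:
            n = self[el]
            if n == 1:
                parts.append(el)
            elif n > 1:
                parts.append(f"{el}{n}")
        return "".join(parts)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.hill()


def delta_mass(delta: Mapping[str, int]) -> float:
    """Monoisotopic mass of a signed element delta."""
    return sum(MONOISOTOPIC_MASS[el] * n for el, n in delta.items())


@dataclass(frozen=True)
class Adduct:
    """An ionization adduct: a signed formula delta plus a charge.

    m/z of an ion is ``(neutral mass + delta mass - charge * m_e) / |charge|``;
    the electron-mass term matters at QTOF mass accuracy (sub-mDa).
    """

    name: str
    formula_delta: Mapping[str, int]
    charge: int

    def __post_init__(self) -> None:
        if self.charge == 0:
            raise ValueError("adduct charge must be nonzero")

    def mz(self, neutral: MolecularFormula) -> float:
        m = neutral.monoisotopic_mass + delta_mass(self.formula_delta)
        return (m - self.charge * ELECTRON_MASS) / abs(self.charge)

    def ion_formula(self, neutral: MolecularFormula) -> MolecularFormula:
        """Element composition of the intact ion (charge carried implicitly)."""
        return neutral.shift(self.formula_delta)


ADDUCTS: dict[str, Adduct] = {
    a.name: a
    for a in [
        Adduct("[M+H]+", {"H": 1}, +1),
        Adduct("[M+Na]+", {"Na": 1}, +1),
        Adduct("[M+K]+", {"K": 1}, +1),
        Adduct("[M+NH4]+", {"N": 1, "H": 4}, +1),
        Adduct("[M-H]-", {"H": -1}, -1),
        Adduct("[M+HCOO]-", {"H": 1, "C": 1, "O": 2}, -1),
        Adduct("[M+CH3COO]-", {"H": 3, "C": 2, "O": 2}, -1),
        Adduct("[M+Cl]-", {"Cl": 1}, -1),
    ]
}


def get_adduct(name: str) -> Adduct:
    try:
        return ADDUCTS[name]
    except KeyError:
        raise KeyError(
            f"unknown adduct {name!r}; supported: {', '.join(sorted(ADDUCTS))}"
        ) from None
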