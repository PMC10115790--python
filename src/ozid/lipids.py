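"""Lipid shorthand parsing, class registry and formula assembly.

Shorthand follows the community convention: ``CLASS(c1:d1/c2:d2)`` with an
optional deuterium-label prefix ``D<y>-`` (the label count of an isotope
standard) and sphingoid-base notation (``d18:1`` = dihydroxy base) for the
first chain of ceramides and sphingomyelins.  Double-bond positions are
expressed either carboxyl-referenced (delta) or methyl-referenced (n-x);
the two are related by ``x = carbons - delta``.

Formula assembly for glycerolipids and glycerophospholipids follows ester
arithmetic: the class core is the free head-group alcohol and each acyl
chain contributes a fatty acid minus one water.  Sphingolipids condense a
sphingoid base with one N-acyl (amide, minus one water) plus a head-group
extra for SM.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .formula import FormulaError, MolecularFormula

__all__ = [
    "AcylChain",
    "LipidSpecies",
    "LipidClass",
    "LIPID_CLASSES",
    "parse_target_name",
    "format_name",
    "species_formula",
    "delta_to_n",
    "n_to_delta",
    "LipidParseError",
]

WATER = MolecularFormula({"H": 2, "O": 1})


class LipidParseError(ValueError):
    """A lipid name that does not follow the supported shorthand grammar."""


def delta_to_n(carbons: int, delta: int) -> int:
    """Convert a carboxyl-referenced double-bond position to methyl-referenced n-x.

    For an 18-carbon chain, delta-12 is n-6 and delta-9 is n-9.
    """
    if not 2 <= delta <= carbons - 1:
        raise ValueError(f"delta position {delta} out of range [2, {carbons - 1}]")
    return carbons - delta


def n_to_delta(carbons: int, x: int) -> int:
    """Inverse of :func:`delta_to_n`: methyl-referenced n-x back to delta."""
    if not 1 <= x <= carbons - 2:
        raise ValueError(f"n-position {x} out of range [1, {carbons - 2}]")
    return carbons - x


@dataclass(frozen=True)
class AcylChain:
    """A fatty acyl (or sphingoid base) as carbons:double_bonds.

    ``hydroxyls`` > 0 marks a sphingoid base (``d`` = 2, ``t`` = 3).
    ``carboxyl_positions`` optionally carries known delta positions,
    strictly increasing, each in ``[2, carbons - 1]``.
    """

    carbons: int
    double_bonds: int
    hydroxyls: int = 0
    carboxyl_positions: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.carbons < 2:
            raise ValueError(f"chain needs >= 2 carbons, got {self.carbons}")
        if self.double_bonds < 0:
            raise ValueError("double_bonds must be >= 0")
        if self.double_bonds > (self.carbons - 2) // 2:
            raise ValueError(
                f"{self.carbons}:{self.double_bonds} exceeds the maximum "
                f"unsaturation {(self.carbons - 2) // 2} for this chain length"
            )
        if self.carboxyl_positions is not None:
            pos = tuple(self.carboxyl_positions)
            if len(pos) != self.double_bonds:
                raise ValueError("carboxyl_positions length must equal double_bonds")
            if list(pos) != sorted(set(pos)):
                raise ValueError("carboxyl_positions must be strictly increasing")
            for p in pos:
                if not 2 <= p <= self.carbons - 1:
                    raise ValueError(f"delta position {p} out of range")
            object.__setattr__(self, "carboxyl_positions", pos)

    @property
    def is_sphingoid(self) -> bool:
        return self.hydroxyls > 0

    def n_positions(self) -> tuple[int, ...] | None:
        """Known methyl-referenced positions, sorted ascending (index order)."""
        if self.carboxyl_positions is None:
            return None
        return tuple(sorted(delta_to_n(self.carbons, d) for d in self.carboxyl_positions))

    def fatty_acid_formula(self) -> MolecularFormula:
        """Free fatty acid CcH(2c-2d)O2 (plain acyl chains only)."""
        if self.is_sphingoid:
            raise FormulaError("sphingoid base is not an esterifiable fatty acid")
        return MolecularFormula(
            {"C": self.carbons, "H": 2 * self.carbons - 2 * self.double_bonds, "O": 2}
        )

    def sphingoid_formula(self) -> MolecularFormula:
        """Free sphingoid base CcH(2c+3-2d)N O_h (e.g. d18:1 -> C18H37NO2)."""
        if not self.is_sphingoid:
            raise FormulaError("not a sphingoid base")
        return MolecularFormula(
            {
                "C": self.carbons,
                "H": 2 * self.carbons + 3 - 2 * self.double_bonds,
                "N": 1,
                "O": self.hydroxyls,
            }
        )

    def __str__(self) -> str:
        prefix = {0: "", 2: "d", 3: "t"}.get(self.hydroxyls, f"{self.hydroxyls}OH-")
        return f"{prefix}{self.carbons}:{self.double_bonds}"


@dataclass(frozen=True)
class LipidClass:
    """Registry entry: head-group core formula and chain-count contract."""

    name: str
    core: MolecularFormula
    n_chains: int
    sphingoid: bool = False
    # added after amide condensation (SM: phosphocholine minus water)
    extra: MolecularFormula = field(default_factory=MolecularFormula)


def _f(**counts: int) -> MolecularFormula:
    return MolecularFormula(counts)


_GLYCEROL = _f(C=3, H=8, O=3)

LIPID_CLASSES: dict[str, LipidClass] = {
    c.name: c
    for c in [
        LipidClass("PC", _f(C=8, H=20, N=1, O=6, P=1), 2),
        LipidClass("PE", _f(C=5, H=14, N=1, O=6, P=1), 2),
        LipidClass("PG", _f(C=6, H=15, O=8, P=1), 2),
        LipidClass("PI", _f(C=9, H=19, O=11, P=1), 2),
        LipidClass("PS", _f(C=6, H=14, N=1, O=8, P=1), 2),
        LipidClass("PA", _f(C=3, H=9, O=6, P=1), 2),
        LipidClass("DG", _GLYCEROL, 2),
        LipidClass("TG", _GLYCEROL, 3),
        LipidClass("LPC", _f(C=8, H=20, N=1, O=6, P=1), 1),
        LipidClass("LPE", _f(C=5, H=14, N=1, O=6, P=1), 1),
        LipidClass("Cer", MolecularFormula(), 2, sphingoid=True),
        LipidClass("SM", MolecularFormula(), 2, sphingoid=True, extra=_f(C=5, H=12, N=1, O=3, P=1)),
    ]
}


@dataclass(frozen=True)
class LipidSpecies:
    """A lipid at fatty-acyl resolution plus an optional deuterium label count."""

    lipid_class: str
    chains: tuple[AcylChain, ...]
    deuterium_label: int = 0

    def __post_init__(self) -> None:
        if self.lipid_class not in LIPID_CLASSES:
            raise LipidParseError(f"unknown lipid class {self.lipid_class!r}")
        if not self.chains:
            raise ValueError("a lipid species needs at least one chain")
        object.__setattr__(self, "chains", tuple(self.chains))
        if self.deuterium_label < 0:
            raise ValueError("deuterium_label must be >= 0")

    def __str__(self) -> str:
        return format_name(self)


_NAME_RE = re.compile(
    r"^(?:D(?P<label>\d+)-)?(?P<cls>[A-Za-z][A-Za-z0-9]*)\((?P<chains>[^)]+)\)$"
)
_CHAIN_RE = re.compile(r"^(?P<hydroxy>[dt])?(?P<c>\d+):(?P<d>\d+)$")


def parse_target_name(name: str) -> LipidSpecies:
    """Parse shorthand like ``PC(16:0/18:1)`` or ``D5-PG(17:0/20:3)``.

    Chain separators ``/`` (known sn order) and ``_`` (unknown) are both
    accepted; chains are kept in written order either way.
    """
    m = _NAME_RE.match(name.strip())
    if m is None:
        raise LipidParseError(f"cannot parse lipid name {name!r}")
    cls = m.group("cls")
    if cls not in LIPID_CLASSES:
        raise LipidParseError(f"unknown lipid class {cls!r} in {name!r}")
    spec = LIPID_CLASSES[cls]
    chains = []
    for tok in re.split(r"[/_]", m.group("chains")):
        cm = _CHAIN_RE.match(tok.strip())
        if cm is None:
            raise LipidParseError(f"cannot parse chain token {tok!r} in {name!r}")
        hydroxyls = {None: 0, "d": 2, "t": 3}[cm.group("hydroxy")]
        if hydroxyls and not (spec.sphingoid and not chains):
            raise LipidParseError(
                f"sphingoid chain token {tok!r} only allowed first in Cer/SM"
            )
        chains.append(AcylChain(int(cm.group("c")), int(cm.group("d")), hydroxyls))
    if spec.sphingoid and not chains[0].is_sphingoid:
        raise LipidParseError(
            f"{cls} requires a sphingoid first chain (e.g. d18:1) in {name!r}"
        )
    label = int(m.group("label") or 0)
    species = LipidSpecies(cls, tuple(chains), label)
    _check_chain_count(species)
    return species


def format_name(species: LipidSpecies) -> str:
    prefix = f"D{species.deuterium_label}-" if species.deuterium_label else ""
    body = "/".join(str(ch) for ch in species.chains)
    return f"{prefix}{species.lipid_class}({body})"


def _check_chain_count(species: LipidSpecies) -> None:
    spec = LIPID_CLASSES[species.lipid_class]
    if len(species.chains) != spec.n_chains:
        raise LipidParseError(
            f"{species.lipid_class} takes {spec.n_chains} chain(s), "
            f"got {len(species.chains)}"
        )


def species_formula(species: LipidSpecies) -> MolecularFormula:
    """Neutral molecular formula of a lipid species.

    Deterministic for a given (class, chains, label); the deuterium label is
    applied as an H->D substitution of the assembled formula (positions are
    not tracked — labeled standards carry the label on head group/backbone,
    outside the acyl chains that OzID cleaves).
    """
    _check_chain_count(species)
    spec = LIPID_CLASSES[species.lipid_class]
    if spec.sphingoid:
        base, acyl = species.chains
        total = base.sphingoid_formula() + acyl.fatty_acid_formula() - WATER + spec.extra
    else:
        total = spec.core
        for ch in species.chains:
            if ch.is_sphingoid:
                raise FormulaError(f"sphingoid chain invalid for class {spec.name}")
            total = total + ch.fatty_acid_formula() - WATER
    return total.substitute_h_with_d(species.deuterium_label)
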