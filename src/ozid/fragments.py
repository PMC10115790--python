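"""Enumeration of candidate double-bond sites and OzID fragment prediction.

Ozone cleaves a C=C bond and yields two diagnostic product ions: the
*aldehyde* and the *criegee* (carbonyl oxide), the latter one oxygen
(15.9949 Da) heavier.  Both appear as neutral losses from the intact
precursor ion, and the loss mass encodes the bond's methyl-referenced
position ``n-x`` and its index ``i`` (ordinal from the methyl end):

    aldehyde neutral loss = C(x-1) H(2x-4-2(i-1))
    criegee  neutral loss = aldehyde loss - O   (the fragment gains the O)

The criegee loss is represented as a *signed* element delta (O: -1); the
fragment formulas themselves are always valid non-negative formulas.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .formula import Adduct, ELECTRON_MASS, FormulaError, MolecularFormula, delta_mass
from .lipids import AcylChain, LipidSpecies, species_formula

__all__ = [
    "DoubleBondSite",
    "OzidFragmentPair",
    "EnumerationRules",
    "enumerate_sites",
    "neutral_loss_delta",
    "fragment_pair",
    "predict_fragments",
]

OXYGEN_MASS = 15.994915


@dataclass(frozen=True)
class DoubleBondSite:
    """One putative C=C bond: chain reference, index i and position n-x.

    Index and position are both counted from the methyl (omega) end; for a
    chain with d double bonds the index runs 1..d and positions increase
    with index.
    """

    chain: int
    index: int
    position: int

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError("double-bond index starts at 1")
        if self.position < 1:
            raise ValueError("n-position starts at 1")


@dataclass(frozen=True)
class OzidFragmentPair:
    """Aldehyde/criegee ion formulas and m/z for one candidate site."""

    site: DoubleBondSite
    aldehyde_formula: MolecularFormula
    criegee_formula: MolecularFormula
    aldehyde_mz: float
    criegee_mz: float
    charge: int


@dataclass(frozen=True)
class EnumerationRules:
    """Bounds for candidate-site enumeration.

    ``min_spacing`` is the carbon spacing between successive double bonds
    (3 = methylene-interrupted, the dominant biological pattern; 2 admits
    conjugated systems).  ``x_min`` is the shallowest position considered
    for the first (methyl-most) bond; the deepest position is
    ``carbons - 2``.
    """

    x_min: int = 2
    min_spacing: int = 3

    def __post_init__(self) -> None:
        if self.x_min < 1 or self.min_spacing < 1:
            raise ValueError("x_min and min_spacing must be >= 1")


def enumerate_sites(
    chain: AcylChain, chain_ref: int = 0, rules: EnumerationRules = EnumerationRules()
) -> list[DoubleBondSite]:
    """All plausible (index, position) sites for one chain, sorted.

    For index i of d total bonds, positions run from
    ``x_min + spacing*(i-1)`` (room for the shallower bonds) to
    ``carbons - 2 - spacing*(d-i)`` (room for the deeper ones).
    A saturated chain yields an empty list.
    """
    d = chain.double_bonds
    sites = []
    for i in range(1, d + 1):
        lo = rules.x_min + rules.min_spacing * (i - 1)
        hi = chain.carbons - 2 - rules.min_spacing * (d - i)
        for x in range(lo, hi + 1):
            sites.append(DoubleBondSite(chain_ref, i, x))
    return sites


def neutral_loss_delta(site: DoubleBondSite, fragment_kind: str) -> dict[str, int]:
    """Signed element delta lost from the precursor ion for one fragment.

    ``fragment_kind`` is ``"aldehyde"`` or ``"criegee"``; the criegee delta
    carries O: -1 because the fragment retains the cleaved bond's carbon
    plus one oxygen from ozone.
    """
    x, i = site.position, site.index
    h = 2 * x - 4 - 2 * (i - 1)
    if x < 2 or h < 0:
        raise ValueError(
            f"site (index {i}, n-{x}) is chemically impossible: "
            f"lost fragment would be C{x - 1}H{h}"
        )
    delta = {"C": x - 1, "H": h}
    if fragment_kind == "criegee":
        delta["O"] = -1
    elif fragment_kind != "aldehyde":
        raise ValueError(f"unknown fragment kind {fragment_kind!r}")
    return delta


def fragment_pair(
    precursor_formula: MolecularFormula, adduct: Adduct, site: DoubleBondSite
) -> OzidFragmentPair:
    """Aldehyde/criegee ion formulas and m/z for one site.

    The fragment ions retain the full adduct; no adduct-loss channels are
    modeled.  Raises :class:`~ozid.formula.FormulaError` if the neutral
    loss is not subtractable from the precursor ion (impossible site).
    """
    ion = adduct.ion_formula(precursor_formula)
    ald_delta = neutral_loss_delta(site, "aldehyde")
    cri_delta = neutral_loss_delta(site, "criegee")
    ald = ion.shift(ald_delta, sign=-1)
    cri = ion.shift(cri_delta, sign=-1)
    z = adduct.charge
    ald_mz = (ald.monoisotopic_mass - z * ELECTRON_MASS) / abs(z)
    cri_mz = (cri.monoisotopic_mass - z * ELECTRON_MASS) / abs(z)
    return OzidFragmentPair(site, ald, cri, ald_mz, cri_mz, z)


def predict_fragments(
    species: LipidSpecies,
    adduct: Adduct,
    rules: EnumerationRules = EnumerationRules(),
    mz_collision_tol: float = 0.01,
) -> tuple[list[OzidFragmentPair], set[int]]:
    """Fragment pairs for every enumerated site of every unsaturated chain.

    Returns the pairs plus the set of list indices whose aldehyde m/z
    collides (within ``mz_collision_tol``) with a pair from a *different*
    chain — those assignments are chain-ambiguous and flagged rather than
    merged.  Impossible sites (neutral-loss underflow) are dropped with a
    warning.
    """
    neutral = species_formula(species)
    pairs: list[OzidFragmentPair] = []
    for ci, chain in enumerate(species.chains):
        if chain.double_bonds == 0:
            continue
        for site in enumerate_sites(chain, chain_ref=ci, rules=rules):
            try:
                pairs.append(fragment_pair(neutral, adduct, site))
            except FormulaError as exc:  # pragma: no cover - lipid formulas are large
                warnings.warn(f"dropping impossible site {site}: {exc}")
    ambiguous: set[int] = set()
    for a in range(len(pairs)):
        for b in range(a + 1, len(pairs)):
            if pairs[a].site.chain != pairs[b].site.chain and (
                abs(pairs[a].aldehyde_mz - pairs[b].aldehyde_mz) <= mz_collision_tol
            ):
                ambiguous.update((a, b))
    return pairs, ambiguous


def neutral_loss_mass(site: DoubleBondSite, fragment_kind: str) -> float:
    """Monoisotopic mass of the neutral loss (criegee loss is one O lighter)."""
    return delta_mass(neutral_loss_delta(site, fragment_kind))
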