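"""Constrained M/M+1/M+2 theoretical isotope distributions.

Abundances follow a multinomial expansion over per-atom isotope choices,
restricted to the five heavy isotopes 13C, 15N, 18O, 33S and 34S (2H/17O
and anything beyond a nominal +2 shift are excluded, and deuterium atoms
introduced by labeling are fixed, not subject to natural abundance).  Only
the M, M+1 and M+2 nominal isotopes are computed, normalized to the most
abundant of the three.  M+1/M+2 m/z values are abundance-weighted
centroids of the contributing isotopologues, which is what a centroiding
QTOF reports.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .formula import ELECTRON_MASS, MolecularFormula

__all__ = ["IsotopeTriplet", "isotope_triplet", "theoretical_spectrum", "HEAVY_ISOTOPES"]

# (element, nominal shift, natural abundance, exact mass shift vs principal)
HEAVY_ISOTOPES: list[tuple[str, int, float, float]] = [
    ("C", 1, 0.0107, 1.003355),   # 13C
    ("N", 1, 0.00364, 0.997035),  # 15N
    ("O", 2, 0.00205, 2.004246),  # 18O
    ("S", 1, 0.0075, 0.999388),   # 33S
    ("S", 2, 0.0425, 1.995796),   # 34S
]


@dataclass(frozen=True)
class IsotopeTriplet:
    """M/M+1/M+2 m/z values and relative abundances (max = 1)."""

    mz: tuple[float, float, float]
    abundance: tuple[float, float, float]
    origin: str = "theoretical"

    def __post_init__(self) -> None:
        if any(not 0.0 <= a <= 1.0 + 1e-12 for a in self.abundance):
            raise ValueError("abundances must lie in [0, 1]")
        if max(self.abundance) > 0 and abs(max(self.abundance) - 1.0) > 1e-9:
            raise ValueError("abundances must be normalized to the maximum")
        if not (self.mz[0] < self.mz[1] < self.mz[2]):
            raise ValueError("m/z values must be strictly increasing")


def _element_distribution(n: int, options: list[tuple[int, float, float]]):
    """(prob, mass-moment) arrays over nominal shifts 0..2 for n atoms.

    ``options`` lists the heavy choices (shift, per-atom prob, mass shift)
    of one element.  Atoms are folded in one at a time; the mass moment of
    shift s accumulates prob * summed-mass-shift so centroids come out as
    moment / prob.  Truncation at shift 2 is exact for the reported triplet.
    """
    light = 1.0 - sum(p for _, p, _ in options)
    per_atom = [(0, light, 0.0)] + [(s, p, dm) for s, p, dm in options]
    prob = np.array([1.0, 0.0, 0.0])
    mom = np.zeros(3)
    for _ in range(n):
        new_p = np.zeros(3)
        new_m = np.zeros(3)
        for s_old in range(3):
            if prob[s_old] == 0.0 and mom[s_old] == 0.0:
                continue
            for s_add, p_add, dm_add in per_atom:
                s = s_old + s_add
                if s > 2:
                    continue
                new_p[s] += prob[s_old] * p_add
                new_m[s] += mom[s_old] * p_add + prob[s_old] * p_add * dm_add
        prob, mom = new_p, new_m
    return prob, mom


def isotope_triplet(formula: MolecularFormula, charge: int) -> IsotopeTriplet:
    """Theoretical M/M+1/M+2 triplet for an ion of the given composition.

    ``formula`` is the intact-ion composition; ``charge`` its signed charge.
    """
    if not formula:
        raise ValueError("empty formula")
    if charge == 0:
        raise ValueError("charge must be nonzero")
    by_element: dict[str, list[tuple[int, float, float]]] = {}
    for el, shift, p, dm in HEAVY_ISOTOPES:
        by_element.setdefault(el, []).append((shift, p, dm))

    prob = np.array([1.0, 0.0, 0.0])
    mom = np.zeros(3)
    for el, options in by_element.items():
        n = formula[el]
        if n == 0:
            continue
        ep, em = _element_distribution(n, options)
        new_p = np.zeros(3)
        new_m = np.zeros(3)
        for a in range(3):
            for b in range(3 - a):
                new_p[a + b] += prob[a] * ep[b]
                new_m[a + b] += mom[a] * ep[b] + prob[a] * em[b]
        prob, mom = new_p, new_m

    z = abs(charge)
    base = (formula.monoisotopic_mass - charge * ELECTRON_MASS) / z
    nominal = (1.003355, 2.003355)  # carbon-dominated fallback spacings
    mz = [base]
    for s in (1, 2):
        dm = mom[s] / prob[s] if prob[s] > 0 else nominal[s - 1]
        mz.append(base + dm / z)
    top = prob.max()
    abund = tuple(float(p / top) for p in prob)
    return IsotopeTriplet((mz[0], mz[1], mz[2]), abund, origin="theoretical")


def theoretical_spectrum(
    triplet: IsotopeTriplet, grid: np.ndarray, peak_fwhm: float
) -> np.ndarray:
    """Render a triplet as three Gaussian peaks on an m/z grid, max = 1.

    The grid must cover all three centroids (the scoring window is
    M-1.5 .. M+2.5); heights equal the triplet abundances.
    """
    grid = np.asarray(grid, dtype=float)
    if peak_fwhm <= 0:
        raise ValueError("peak_fwhm must be > 0")
    if grid[0] > triplet.mz[0] or grid[-1] < triplet.mz[2]:
        raise ValueError("m/z grid does not cover the isotope triplet")
    sigma = peak_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    out = np.zeros_like(grid)
    for center, height in zip(triplet.mz, triplet.abundance):
        out += height * np.exp(-0.5 * ((grid - center) / sigma) ** 2)
    top = out.max()
    if top > 0:
        out /= top
    return out
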