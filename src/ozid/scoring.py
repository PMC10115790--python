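"""Dual cosine-distance scoring of putative OzID fragments and assignment.

Each candidate fragment is scored on two orthogonal axes:

* ``rt_cosine`` — cosine distance between the fragment XIC and the
  precursor XIC over a shared RT grid spanning the fitted peak (a real
  fragment co-elutes with its precursor);
* ``mz_cosine`` — cosine distance between the observed MS1 spectrum around
  the fragment (M-1.5 .. M+2.5) and a spectrum constructed from the
  theoretical isotope distribution.

A distance of 0 means perfectly overlapping signals, 1 means no overlap.
A site is *accepted* when all four components (both axes for aldehyde and
criegee) fall at or below the cutoff (default 0.25), *partial* when
exactly one fragment of the pair passes both axes (e.g. sphingolipid
backbone bonds where the criegee is consistently absent), and *rejected*
otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .fragments import OzidFragmentPair
from .isotopes import IsotopeTriplet, theoretical_spectrum
from .peaks import PeakFit, fit_isotope_peaks
from .rawdata import Chromatogram

__all__ = [
    "FragmentScores",
    "Assignment",
    "cosine_distance",
    "score_fragment",
    "composite_score",
    "assign",
    "export_results",
    "RESULT_COLUMNS",
]

MISSING_PENALTY = 0.5  # added to the composite when a fragment is wholly absent


def cosine_distance(a: np.ndarray, b: np.ndarray) -> float:
    """1 - cos(a, b) for non-negative vectors; 1.0 if either is all-zero.

    Symmetric and invariant to positive rescaling of either argument.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return 1.0
    return float(np.clip(1.0 - float(a @ b) / (na * nb), 0.0, 1.0))


def _resample(chrom: Chromatogram, grid: np.ndarray) -> np.ndarray:
    return np.interp(grid, chrom.rt, chrom.intensity, left=0.0, right=0.0)


def interpolate_spectrum(
    spectrum: tuple[np.ndarray, np.ndarray], grid: np.ndarray, gap: float = 0.02
) -> np.ndarray:
    """Linearly resample a sparse spectrum onto a grid, zeroing data gaps.

    Grid points farther than ``gap`` from any observed point are set to 0
    so that linear interpolation never bridges empty m/z regions.
    """
    mz, inten = (np.asarray(a, dtype=float) for a in spectrum)
    if mz.size == 0:
        return np.zeros_like(grid)
    out = np.interp(grid, mz, inten, left=0.0, right=0.0)
    pos = np.searchsorted(mz, grid)
    left = np.abs(grid - mz[np.clip(pos - 1, 0, mz.size - 1)])
    right = np.abs(mz[np.clip(pos, 0, mz.size - 1)] - grid)
    out[np.minimum(left, right) > gap] = 0.0
    return out


def spectral_cosine(
    spectrum: tuple[np.ndarray, np.ndarray],
    theoretical: IsotopeTriplet,
    peak_fwhm: float = 0.05,
    step: float = 0.01,
) -> float:
    """Cosine distance between a raw M-1.5..M+2.5 spectrum and the theory.

    The observed spectrum is compared as-is (interpolated onto the grid),
    so interfering peaks inside the window — e.g. isotopes of a different
    fragment — count against the match instead of being fitted away.
    """
    mz_lo, mz_hi = theoretical.mz[0] - 1.5, theoretical.mz[0] + 2.5
    grid = np.arange(mz_lo, mz_hi + step, step)
    fwhm = peak_fwhm if math.isfinite(peak_fwhm) and peak_fwhm > 0 else 0.05
    theo_vec = theoretical_spectrum(theoretical, grid, fwhm)
    obs_vec = interpolate_spectrum(spectrum, grid)
    return cosine_distance(obs_vec, theo_vec)


def score_fragment(
    precursor_xic: Chromatogram,
    fragment_xic: Chromatogram,
    fragment_spectrum: tuple[np.ndarray, np.ndarray],
    theoretical: IsotopeTriplet,
    precursor_fit: PeakFit,
    mz_tol_fit: float = 0.05,
    mz_grid_step: float = 0.01,
    fallback_fwhm: float = 0.05,
) -> tuple[float, float]:
    """(rt_cosine, mz_cosine) for one putative fragment.

    XICs are linearly resampled to a shared grid over the precursor peak
    (fit mean +/- 3 sigma).  The observed spectrum is compared against a
    theoretical spectrum rendered on a 0.01 Da grid whose peak width is
    taken from the observed M peak fit (``fallback_fwhm`` when missing).
    An absent fragment scores (1, 1) on both axes.
    """
    if not precursor_fit.ok:
        raise ValueError("precursor peak fit required for scoring")
    lo = precursor_fit.mean - 3.0 * precursor_fit.sigma
    hi = precursor_fit.mean + 3.0 * precursor_fit.sigma
    grid = np.union1d(
        precursor_xic.rt[(precursor_xic.rt >= lo) & (precursor_xic.rt <= hi)],
        fragment_xic.rt[(fragment_xic.rt >= lo) & (fragment_xic.rt <= hi)],
    )
    if grid.size == 0:
        return 1.0, 1.0
    rt_cos = cosine_distance(_resample(precursor_xic, grid), _resample(fragment_xic, grid))

    # peak width for the constructed theoretical spectrum comes from the
    # observed M peak where one can be fitted
    obs = fit_isotope_peaks(fragment_spectrum, theoretical, mz_tol=mz_tol_fit)
    fwhm = obs.fwhm_m if math.isfinite(obs.fwhm_m) and obs.fwhm_m > 0 else fallback_fwhm
    mz_cos = spectral_cosine(fragment_spectrum, theoretical, fwhm, mz_grid_step)
    return rt_cos, mz_cos


@dataclass(frozen=True)
class FragmentScores:
    """Cosine-distance components for an aldehyde/criegee pair (NaN = missing)."""

    rt_cosine_aldehyde: float = float("nan")
    mz_cosine_aldehyde: float = float("nan")
    rt_cosine_criegee: float = float("nan")
    mz_cosine_criegee: float = float("nan")

    def components(self) -> tuple[float, float, float, float]:
        return (
            self.rt_cosine_aldehyde,
            self.mz_cosine_aldehyde,
            self.rt_cosine_criegee,
            self.mz_cosine_criegee,
        )

    def fragment_missing(self, kind: str) -> bool:
        if kind == "aldehyde":
            return math.isnan(self.rt_cosine_aldehyde) and math.isnan(self.mz_cosine_aldehyde)
        return math.isnan(self.rt_cosine_criegee) and math.isnan(self.mz_cosine_criegee)

    @property
    def composite(self) -> float:
        return composite_score(self)


def composite_score(scores: FragmentScores) -> float:
    """Mean of available components, +0.5 per wholly missing fragment."""
    comps = [c for c in scores.components() if not math.isnan(c)]
    base = float(np.mean(comps)) if comps else 1.0
    penalty = MISSING_PENALTY * (
        scores.fragment_missing("aldehyde") + scores.fragment_missing("criegee")
    )
    return base + penalty


@dataclass(frozen=True)
class Assignment:
    """Decision for one candidate double-bond site of one target."""

    lipid: str
    adduct: str
    chain: int
    index: int
    position: int
    scores: FragmentScores
    decision: str  # accepted | partial | rejected
    flags: tuple[str, ...] = ()

    @property
    def accepted(self) -> bool:
        return self.decision == "accepted"


def _fragment_passes(rt: float, mz: float, cutoff: float) -> bool:
    return (not math.isnan(rt)) and (not math.isnan(mz)) and rt <= cutoff and mz <= cutoff


def assign(
    lipid: str,
    adduct: str,
    candidates: list[tuple[OzidFragmentPair, FragmentScores]],
    cutoff: float = 0.25,
    extra_flags: dict[int, tuple[str, ...]] | None = None,
) -> list[Assignment]:
    """Apply the cutoff heuristic to scored candidates and rank them.

    Accepted: all four components <= cutoff.  Partial: exactly one of the
    two fragments passes both of its components (the absent/failing mate
    is flagged).  Output is sorted per double-bond index by ascending
    composite score (most confident first), ties broken by ascending
    n-position.
    """
    out: list[Assignment] = []
    for k, (pair, scores) in enumerate(candidates):
        ald_ok = _fragment_passes(scores.rt_cosine_aldehyde, scores.mz_cosine_aldehyde, cutoff)
        cri_ok = _fragment_passes(scores.rt_cosine_criegee, scores.mz_cosine_criegee, cutoff)
        flags = list((extra_flags or {}).get(k, ()))
        if ald_ok and cri_ok:
            decision = "accepted"
        elif ald_ok or cri_ok:
            decision = "partial"
            flags.append("criegee-missing" if ald_ok else "aldehyde-missing")
        else:
            decision = "rejected"
        out.append(
            Assignment(
                lipid,
                adduct,
                pair.site.chain,
                pair.site.index,
                pair.site.position,
                scores,
                decision,
                tuple(flags),
            )
        )
    out.sort(key=lambda a: (a.chain, a.index, round(a.scores.composite, 12), a.position))
    return out


RESULT_COLUMNS = [
    "lipid",
    "adduct",
    "chain",
    "index",
    "n_position",
    "rt_cosine_aldehyde",
    "mz_cosine_aldehyde",
    "rt_cosine_criegee",
    "mz_cosine_criegee",
    "composite",
    "decision",
    "flags",
]


def assignments_frame(assignments: list[Assignment]) -> pd.DataFrame:
    rows = [
        {
            "lipid": a.lipid,
            "adduct": a.adduct,
            "chain": a.chain,
            "index": a.index,
            "n_position": a.position,
            "rt_cosine_aldehyde": a.scores.rt_cosine_aldehyde,
            "mz_cosine_aldehyde": a.scores.mz_cosine_aldehyde,
            "rt_cosine_criegee": a.scores.rt_cosine_criegee,
            "mz_cosine_criegee": a.scores.mz_cosine_criegee,
            "composite": a.scores.composite,
            "decision": a.decision,
            "flags": ";".join(a.flags),
        }
        for a in assignments
    ]
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def export_results(
    assignments: list[Assignment], path: str | Path, xlsx: bool = False
) -> pd.DataFrame:
    """Write one row per candidate site as CSV (optionally also .xlsx)."""
    df = assignments_frame(assignments)
    path = Path(path)
    df.to_csv(path, index=False, float_format="%.6f")
    if xlsx:
        df.to_excel(path.with_suffix(".xlsx"), index=False)
    return df
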