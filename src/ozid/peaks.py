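"""Gaussian peak fitting for XICs and RT-selected MS1 isotope peaks.

Chromatographic and spectral peaks are both modeled as single Gaussians
(height, mean, FWHM) fitted by least squares.  Detector saturation is
detected by an intensity threshold; saturated precursors get their MS1
window moved to the leading edge of the fitted peak, where the detector
still responds linearly, so isotope ratios are not biased by clipping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .isotopes import IsotopeTriplet
from .rawdata import Chromatogram

__all__ = [
    "PeakFit",
    "ObservedIsotopes",
    "gaussian",
    "fit_chrom_peak",
    "select_ms1_rt_window",
    "fit_isotope_peaks",
]

_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))  # sigma -> FWHM factor


def gaussian(x: np.ndarray, height: float, mean: float, sigma: float) -> np.ndarray:
    return height * np.exp(-0.5 * ((x - mean) / sigma) ** 2)


@dataclass(frozen=True)
class PeakFit:
    """One fitted Gaussian peak; ``status`` is ok | no-peak | fail."""

    mean: float = np.nan
    height: float = np.nan
    fwhm: float = np.nan
    r2: float = np.nan
    saturated: bool = False
    status: str = "ok"
    seed: tuple[float, float, float] | None = None  # (height, mean, sigma) used to start

    @property
    def ok(self) -> bool:
        return self.status == "ok"

    @property
    def sigma(self) -> float:
        return self.fwhm / _FWHM


def _pick_seed(x: np.ndarray, y: np.ndarray, expected: float) -> tuple[float, float, float]:
    """Seed at the local maximum nearest ``expected``; ties go to the higher."""
    if y.size >= 3:
        interior = (y[1:-1] >= y[:-2]) & (y[1:-1] >= y[2:]) & (y[1:-1] > 0)
        locs = np.where(interior)[0] + 1
    else:
        locs = np.array([], dtype=int)
    if locs.size == 0:
        locs = np.array([int(np.argmax(y))])
    dist = np.abs(x[locs] - expected)
    best = np.lexsort((-y[locs], np.round(dist, 9)))[0]
    i = locs[best]
    height = float(y[i])
    # crude width from half-maximum crossing around the seed
    half = height / 2.0
    left = i
    while left > 0 and y[left] > half:
        left -= 1
    right = i
    while right < y.size - 1 and y[right] > half:
        right += 1
    width = max(x[right] - x[left], np.median(np.diff(x)) if x.size > 1 else 0.01)
    return height, float(x[i]), max(width / _FWHM, 1e-4)


def _r2(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else 0.0
    return float(np.clip(1.0 - ss_res / ss_tot, 0.0, 1.0))


def fit_gaussian_peak(
    x: np.ndarray, y: np.ndarray, expected: float, saturation_threshold: float = np.inf
) -> PeakFit:
    """Least-squares single-Gaussian fit seeded near ``expected``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or not np.any(y > 0):
        return PeakFit(status="no-peak")
    seed = _pick_seed(x, y, expected)
    saturated = bool(y.max() >= saturation_threshold)
    if x.size < 4:
        # not enough points for least squares; report the seed directly
        h, mu, sig = seed
        return PeakFit(mu, h, sig * _FWHM, 0.0, saturated, "ok", seed)
    try:
        popt, _ = curve_fit(
            gaussian,
            x,
            y,
            p0=seed,
            bounds=([0.0, x[0] - (x[-1] - x[0]), 1e-6], [np.inf, x[-1] + (x[-1] - x[0]), np.inf]),
            maxfev=2000,
        )
    except (RuntimeError, ValueError):
        return PeakFit(status="fail", saturated=saturated, seed=seed)
    h, mu, sig = (float(v) for v in popt)
    return PeakFit(mu, h, abs(sig) * _FWHM, _r2(y, gaussian(x, *popt)), saturated, "ok", seed)


def fit_chrom_peak(
    xic: Chromatogram, expected_rt: float, saturation_threshold: float = 1e6
) -> PeakFit:
    """Fit the chromatographic peak nearest ``expected_rt`` in an XIC."""
    return fit_gaussian_peak(xic.rt, xic.intensity, expected_rt, saturation_threshold)


def select_ms1_rt_window(
    fit: PeakFit,
    rt_lo: float = -np.inf,
    rt_hi: float = np.inf,
    leading_edge_k: float = 1.0,
) -> tuple[float, float]:
    """RT window for MS1 extraction from a fitted XIC peak.

    Unsaturated peaks use ``mean +/- k*sigma``; saturated peaks use the
    leading edge ``[mean - 2*sigma, mean - sigma]`` to avoid clipped scans.
    Bounds are clipped to the extracted RT range.
    """
    if not fit.ok:
        raise ValueError("cannot select an MS1 window from a failed/no-peak fit")
    s = fit.sigma
    if fit.saturated:
        lo, hi = fit.mean - 2.0 * s, fit.mean - s
    else:
        lo, hi = fit.mean - leading_edge_k * s, fit.mean + leading_edge_k * s
    return max(lo, rt_lo), min(hi, rt_hi)


@dataclass(frozen=True)
class ObservedIsotopes:
    """Fitted M/M+1/M+2 peaks from an RT-selected MS1 spectrum.

    Unfitted isotopes are ``missing`` with abundance 0; ``ppm_error`` is
    observed-vs-theoretical mass error for fitted peaks (NaN otherwise).
    """

    triplet: IsotopeTriplet
    fits: tuple[PeakFit, PeakFit, PeakFit]
    ppm_error: tuple[float, float, float]
    missing: tuple[bool, bool, bool]
    fwhm_m: float = np.nan  # fitted width of the M peak (Da), NaN if missing

    @property
    def all_missing(self) -> bool:
        return all(self.missing)


def fit_isotope_peaks(
    spectrum: tuple[np.ndarray, np.ndarray],
    theoretical: IsotopeTriplet,
    mz_tol: float = 0.05,
) -> ObservedIsotopes:
    """Fit each nominal isotope near its theoretical centroid.

    A peak counts as found when the fit converges, its height is positive
    and its fitted centroid lies within ``mz_tol`` of the theoretical m/z.
    Abundances are fitted heights normalized to the largest found peak.
    """
    mz, inten = (np.asarray(a, dtype=float) for a in spectrum)
    fits: list[PeakFit] = []
    for center in theoretical.mz:
        sel = (mz >= center - 0.3) & (mz <= center + 0.3)
        if not np.any(sel) or not np.any(inten[sel] > 0):
            fits.append(PeakFit(status="no-peak"))
            continue
        fit = fit_gaussian_peak(mz[sel], inten[sel], center)
        if fit.ok and (abs(fit.mean - center) > mz_tol or fit.height <= 0):
            fit = PeakFit(status="no-peak")
        fits.append(fit)
    heights = np.array([f.height if f.ok else 0.0 for f in fits])
    missing = tuple(not f.ok for f in fits)
    top = heights.max()
    abund = tuple(float(h / top) if top > 0 else 0.0 for h in heights)
    obs_mz = tuple(
        float(f.mean) if f.ok else float(c) for f, c in zip(fits, theoretical.mz)
    )
    ppm = tuple(
        float((f.mean - c) / c * 1e6) if f.ok else float("nan")
        for f, c in zip(fits, theoretical.mz)
    )
    triplet = IsotopeTriplet(obs_mz, abund, origin="observed")
    return ObservedIsotopes(
        triplet,
        tuple(fits),
        ppm,
        missing,
        fwhm_m=fits[0].fwhm if fits[0].ok else float("nan"),
    )
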