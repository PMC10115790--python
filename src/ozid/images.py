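"""3-channel LC-MS profile images for classifier input.

Each training/inference example is a pseudo-RGB image: channel 0 holds the
precursor's LC-MS profile, channels 1 and 2 the aldehyde and criegee
profiles, each extracted over its own M-1.5 .. M+2.5 m/z window (x axis)
and a shared RT window of fit RT +/- 2.5 min (y axis).  Sparse scan data
is resampled to a uniform H x W grid by 2D linear interpolation and each
channel is max-normalized to [0, 1] (an all-zero channel stays zero).
Augmentation resamples the RT dimension to emulate shifted, narrower and
broader chromatographic peaks; a default recipe yields 9 variants so one
source example becomes 10 images.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import map_coordinates

from .fragments import OzidFragmentPair
from .rawdata import RawRun

__all__ = [
    "ProfileImage",
    "AugmentStep",
    "DEFAULT_RECIPE",
    "build_image",
    "augment",
    "split_train_val",
]

RT_HALF_WINDOW = 2.5  # minutes either side of the fitted RT
MZ_LO, MZ_HI = -1.5, 2.5  # m/z window relative to each ion's monoisotopic peak


@dataclass(frozen=True)
class ProfileImage:
    """(3, H, W) tensor in [0, 1]; axis 1 = RT, axis 2 = m/z."""

    tensor: np.ndarray
    label: bool | None = None
    source_id: str = ""
    variant: str = "original"
    rt_center: float = float("nan")

    def __post_init__(self) -> None:
        t = np.asarray(self.tensor, dtype=np.float32)
        if t.ndim != 3 or t.shape[0] != 3:
            raise ValueError(f"expected (3, H, W) tensor, got {t.shape}")
        if t.size and (t.min() < 0 or t.max() > 1.0 + 1e-6):
            raise ValueError("tensor values must lie in [0, 1]")
        object.__setattr__(self, "tensor", t)


def _channel_profile(
    run: RawRun, mz_lo: float, mz_hi: float, rt_lo: float, rt_hi: float, h: int, w: int
) -> np.ndarray:
    idx = run.scan_indices_in(rt_lo, rt_hi)
    if idx.size == 0:
        raise ValueError(f"RT window [{rt_lo}, {rt_hi}) lies outside the run")
    mz_grid = np.linspace(mz_lo, mz_hi, w)
    rows = np.zeros((idx.size, w), dtype=np.float64)
    scan_rts = np.empty(idx.size)
    for k, i in enumerate(idx):
        rt, scan_mz, scan_in = run.scans[i]
        scan_rts[k] = rt
        lo = np.searchsorted(scan_mz, mz_lo, side="left")
        hi = np.searchsorted(scan_mz, mz_hi, side="right")
        if hi > lo:
            rows[k] = np.interp(mz_grid, scan_mz[lo:hi], scan_in[lo:hi], left=0.0, right=0.0)
    rt_grid = np.linspace(rt_lo, rt_hi, h)
    out = np.empty((h, w), dtype=np.float64)
    for j in range(w):
        out[:, j] = np.interp(rt_grid, scan_rts, rows[:, j], left=0.0, right=0.0)
    return out


def build_image(
    run: RawRun,
    precursor_mz: float,
    pair: OzidFragmentPair,
    rt_center: float,
    size: int = 32,
    label: bool | None = None,
    source_id: str = "",
) -> ProfileImage:
    """Extract the 3-channel profile image for one candidate site."""
    rt_lo, rt_hi = rt_center - RT_HALF_WINDOW, rt_center + RT_HALF_WINDOW
    channels = []
    for base_mz in (precursor_mz, pair.aldehyde_mz, pair.criegee_mz):
        ch = _channel_profile(run, base_mz + MZ_LO, base_mz + MZ_HI, rt_lo, rt_hi, size, size)
        top = ch.max()
        if top > 0:
            ch = ch / top
        channels.append(ch)
    return ProfileImage(
        np.stack(channels).astype(np.float32),
        label=label,
        source_id=source_id,
        rt_center=rt_center,
    )


@dataclass(frozen=True)
class AugmentStep:
    """One RT-resampling variant: shift in minutes, width scale factor."""

    shift_min: float = 0.0
    scale: float = 1.0

    @property
    def tag(self) -> str:
        return f"shift{self.shift_min:+.2f}_scale{self.scale:.2f}"


DEFAULT_RECIPE: tuple[AugmentStep, ...] = (
    AugmentStep(shift_min=+0.25),
    AugmentStep(shift_min=-0.25),
    AugmentStep(shift_min=+0.5),
    AugmentStep(shift_min=-0.5),
    AugmentStep(scale=0.7),
    AugmentStep(scale=0.85),
    AugmentStep(scale=1.15),
    AugmentStep(scale=1.3),
    AugmentStep(shift_min=+0.25, scale=1.15),
)


def _resample_rt(tensor: np.ndarray, step: AugmentStep) -> np.ndarray:
    """Resample the RT axis: rows move by the shift, widths scale about center."""
    _, h, w = tensor.shape
    px_per_min = h / (2.0 * RT_HALF_WINDOW)
    center = (h - 1) / 2.0
    y = np.arange(h, dtype=float)
    src_y = center + (y - center) / step.scale - step.shift_min * px_per_min
    out = np.empty_like(tensor)
    for c in range(tensor.shape[0]):
        coords = np.stack(np.meshgrid(src_y, np.arange(w, dtype=float), indexing="ij"))
        out[c] = map_coordinates(tensor[c], coords, order=1, mode="constant", cval=0.0)
    return np.clip(out, 0.0, 1.0)


def augment(
    image: ProfileImage, recipe: tuple[AugmentStep, ...] = DEFAULT_RECIPE
) -> list[ProfileImage]:
    """Label-preserving RT-resampled variants (default: 9, so 10 with the source)."""
    if image.label is None:
        raise ValueError("augmentation requires a labeled image")
    out = []
    for step in recipe:
        if step.shift_min == 0.0 and step.scale == 1.0:
            out.append(replace(image, variant="identity"))
            continue
        out.append(
            ProfileImage(
                _resample_rt(image.tensor, step),
                label=image.label,
                source_id=image.source_id,
                variant=step.tag,
                rt_center=image.rt_center,
            )
        )
    return out


def split_train_val(
    images: list[ProfileImage], seed: int, val_fraction: float = 0.2
) -> tuple[list[ProfileImage], list[ProfileImage]]:
    """Stratified 4:1 split at the *source* level (no variant leakage).

    All augmented variants of one source example land on the same side.
    The True/False proportion of sources is preserved (to rounding).
    Raises if either class has fewer than 2 source examples.
    """
    by_source: dict[str, bool] = {}
    for im in images:
        if im.label is None:
            raise ValueError("split requires labeled images")
        if im.source_id in by_source and by_source[im.source_id] != im.label:
            raise ValueError(f"source {im.source_id!r} carries conflicting labels")
        by_source[im.source_id] = im.label
    rng = np.random.default_rng(seed)
    val_sources: set[str] = set()
    for lbl in (True, False):
        sources = sorted(s for s, v in by_source.items() if v is lbl)
        if len(sources) < 2:
            raise ValueError(f"label {lbl}: need >= 2 source examples to stratify")
        n_val = max(1, round(val_fraction * len(sources)))
        picked = rng.permutation(len(sources))[:n_val]
        val_sources.update(sources[i] for i in picked)
    train = [im for im in images if im.source_id not in val_sources]
    val = [im for im in images if im.source_id in val_sources]
    return train, val
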