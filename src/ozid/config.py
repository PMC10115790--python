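"""Extraction/processing parameters and a flat key=value config reader."""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from pathlib import Path

__all__ = ["AnalysisConfig", "load_config", "DEFAULT_CONFIG"]


@dataclass(frozen=True)
class AnalysisConfig:
    """All tunable extraction/scoring parameters with their defaults.

    Units: m/z tolerances in Da, RT windows in minutes, saturation in
    detector counts.
    """

    mz_tol_xic: float = 0.02          # half-width for XIC extraction
    mz_tol_fit: float = 0.05          # isotope-peak centroid acceptance window
    rt_window_broad: float = 2.0      # +/- around the target RT for precursor XIC
    saturation_threshold: float = 1e6  # counts above which a peak is saturated
    leading_edge_k: float = 1.0       # unsaturated MS1 window = mean +/- k*sigma
    score_cutoff: float = 0.25        # accept when all cosine distances <= this
    precursor_cutoff: float | None = None  # isotope-validation cutoff (None -> score_cutoff)
    min_spacing: int = 3              # carbons between successive double bonds
    x_min: int = 2                    # shallowest candidate n-position

    @property
    def effective_precursor_cutoff(self) -> float:
        return self.score_cutoff if self.precursor_cutoff is None else self.precursor_cutoff


DEFAULT_CONFIG = AnalysisConfig()

_FIELD_TYPES = {f.name: f for f in fields(AnalysisConfig)}


def load_config(path: str | Path | None, base: AnalysisConfig = DEFAULT_CONFIG) -> AnalysisConfig:
    """Read ``key = value`` lines (TOML-style scalars, # comments) over ``base``.

    Unknown keys are rejected so typos cannot silently fall back to
    defaults.
    """
    if path is None:
        return base
    updates = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected key = value, got {raw!r}")
        key, value = (s.strip() for s in line.split("=", 1))
        if key not in _FIELD_TYPES:
            raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
        if key in ("min_spacing", "x_min"):
            updates[key] = int(value)
        elif key == "precursor_cutoff" and value.lower() in ("none", ""):
            updates[key] = None
        else:
            updates[key] = float(value)
    return replace(base, **updates)
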