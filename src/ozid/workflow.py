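"""Target-list-driven OzID analysis: extract, validate, score, assign.

For each target (lipid name, adduct, expected RT) the workflow

1. extracts the precursor XIC in a broad RT window and fits it,
2. selects an MS1 RT window (leading edge when saturated) and fits the
   observed M/M+1/M+2 isotopes,
3. validates the precursor identity by the spectral cosine distance
   between observed and theoretical isotope envelopes,
4. enumerates candidate double-bond sites from the fatty-acyl
   composition, scores each aldehyde/criegee pair on the dual cosine
   axes, and applies the cutoff heuristic,
5. optionally runs the CNN classifier on the 3-channel profile image of
   every candidate (modes ``dl`` and ``both``).

Per-target failures are recorded as skip reasons and never abort the
batch.  Given identical inputs, config and seed the exported results CSV
is byte-identical.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cnn import TrainedModel, predict_proba
from .config import AnalysisConfig, DEFAULT_CONFIG
from .formula import Adduct, get_adduct
from .fragments import EnumerationRules, OzidFragmentPair, predict_fragments
from .images import build_image
from .isotopes import isotope_triplet
from .lipids import LipidParseError, LipidSpecies, parse_target_name, species_formula
from .peaks import fit_chrom_peak, fit_isotope_peaks, select_ms1_rt_window
from .rawdata import EmptyWindowError, RawRun, extract_ms1, extract_xic
from .scoring import (
    Assignment,
    FragmentScores,
    assign,
    assignments_frame,
    score_fragment,
    spectral_cosine,
)

__all__ = ["Target", "WorkflowResult", "parse_target_list", "run_workflow"]

log = logging.getLogger("ozid")

REQUIRED_COLUMNS = ("lipid", "adduct", "retention_time_min")


@dataclass(frozen=True)
class Target:
    lipid: str
    adduct: str
    retention_time_min: float
    species: LipidSpecies
    adduct_obj: Adduct


def parse_target_list(path: str | Path) -> tuple[list[Target], pd.DataFrame]:
    """Read a delimited target list; malformed rows become a rejects table.

    The header must contain ``lipid``, ``adduct`` and
    ``retention_time_min``; unknown columns are ignored and exact
    duplicate targets are dropped with a warning.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"target list {path} is missing required column(s): {missing}")
    targets: list[Target] = []
    rejects: list[dict] = []
    seen: set[tuple] = set()
    for _, row in df.iterrows():
        key = (row["lipid"], row["adduct"], row["retention_time_min"])
        if key in seen:
            warnings.warn(f"duplicate target {key} dropped")
            continue
        try:
            species = parse_target_name(str(row["lipid"]))
            adduct = get_adduct(str(row["adduct"]))
            rt = float(row["retention_time_min"])
            if not math.isfinite(rt):
                raise ValueError("retention_time_min is not finite")
        except (LipidParseError, KeyError, ValueError) as exc:
            rejects.append({**{c: row[c] for c in REQUIRED_COLUMNS}, "reason": str(exc)})
            continue
        seen.add(key)
        targets.append(Target(str(row["lipid"]), str(row["adduct"]), rt, species, adduct))
    return targets, pd.DataFrame(rejects, columns=[*REQUIRED_COLUMNS, "reason"])


@dataclass
class TargetDiagnostics:
    target: Target
    status: str  # analyzed | skipped
    reason: str = ""
    precursor_rt: float = float("nan")
    precursor_saturated: bool = False
    precursor_isotope_cosine: float = float("nan")
    n_candidates: int = 0
    n_accepted: int = 0


@dataclass
class WorkflowResult:
    results: pd.DataFrame
    assignments: list[Assignment]
    diagnostics: list[TargetDiagnostics]
    rejects: pd.DataFrame = field(default_factory=pd.DataFrame)

    def accepted(self) -> pd.DataFrame:
        return self.results[self.results["decision"] == "accepted"]


def run_workflow(
    targets: list[Target],
    run: RawRun,
    config: AnalysisConfig = DEFAULT_CONFIG,
    mode: str = "heuristic",
    model: TrainedModel | None = None,
) -> WorkflowResult:
    """Analyze every target against a raw run; see the module docstring."""
    if mode not in {"heuristic", "dl", "both"}:
        raise ValueError(f"unknown mode {mode!r}")
    if mode in {"dl", "both"} and model is None:
        raise ValueError(f"mode {mode!r} requires a trained model")
    rules = EnumerationRules(x_min=config.x_min, min_spacing=config.min_spacing)
    all_assignments: list[Assignment] = []
    frames: list[pd.DataFrame] = []
    diags: list[TargetDiagnostics] = []
    for target in targets:
        diag = TargetDiagnostics(target, "skipped")
        try:
            frame = _analyze_one(target, run, config, rules, mode, model, diag)
        except Exception as exc:  # per-target failures never abort the batch
            diag.reason = f"error: {exc}"
            log.error("target %s %s: %s", target.lipid, target.adduct, exc)
            frame = None
        diags.append(diag)
        if frame is not None:
            frames.append(frame)
    if frames:
        results = pd.concat(frames, ignore_index=True)
    else:
        results = assignments_frame([])
        if mode in {"dl", "both"}:
            results["dl_p_true"] = []
            results["dl_label"] = []
    for d in diags:
        if d.status == "analyzed":
            all_assignments.extend(d._assignments)  # type: ignore[attr-defined]
    return WorkflowResult(results, all_assignments, diags)


def _analyze_one(
    target: Target,
    run: RawRun,
    config: AnalysisConfig,
    rules: EnumerationRules,
    mode: str,
    model: TrainedModel | None,
    diag: TargetDiagnostics,
) -> pd.DataFrame | None:
    neutral = species_formula(target.species)
    ion = target.adduct_obj.ion_formula(neutral)
    prec_mz = target.adduct_obj.mz(neutral)
    rt_lo = target.retention_time_min - config.rt_window_broad
    rt_hi = target.retention_time_min + config.rt_window_broad
    log.info("target %s %s: XIC at m/z %.4f", target.lipid, target.adduct, prec_mz)

    xic = extract_xic(run, prec_mz, config.mz_tol_xic, rt_lo, rt_hi)
    fit = fit_chrom_peak(xic, target.retention_time_min, config.saturation_threshold)
    if not fit.ok:
        diag.reason = "precursor not detected"
        log.info("target %s: %s", target.lipid, diag.reason)
        return None
    diag.precursor_rt = fit.mean
    diag.precursor_saturated = fit.saturated

    win = select_ms1_rt_window(fit, xic.rt[0], xic.rt[-1] + 1e-9, config.leading_edge_k)
    prec_triplet = isotope_triplet(ion, target.adduct_obj.charge)
    try:
        spectrum = extract_ms1(run, win[0], win[1], prec_triplet.mz[0] - 1.5, prec_triplet.mz[0] + 2.5)
    except EmptyWindowError:
        diag.reason = "precursor MS1 window empty"
        return None
    obs = fit_isotope_peaks(spectrum, prec_triplet, config.mz_tol_fit)
    if obs.all_missing:
        diag.reason = "precursor isotopes not found"
        return None
    iso_cos = spectral_cosine(spectrum, prec_triplet, obs.fwhm_m)
    diag.precursor_isotope_cosine = iso_cos
    if iso_cos > config.effective_precursor_cutoff:
        diag.reason = f"precursor isotope mismatch (cosine {iso_cos:.3f})"
        log.info("target %s: %s", target.lipid, diag.reason)
        return None

    pairs, ambiguous = predict_fragments(target.species, target.adduct_obj, rules=rules)
    candidates: list[tuple[OzidFragmentPair, FragmentScores]] = []
    extra_flags: dict[int, tuple[str, ...]] = {}
    for k, pair in enumerate(pairs):
        comps = {}
        for kind, frag_mz, frag_formula in (
            ("aldehyde", pair.aldehyde_mz, pair.aldehyde_formula),
            ("criegee", pair.criegee_mz, pair.criegee_formula),
        ):
            frag_xic = extract_xic(run, frag_mz, config.mz_tol_xic, rt_lo, rt_hi)
            frag_triplet = isotope_triplet(frag_formula, pair.charge)
            try:
                frag_spec = extract_ms1(
                    run, win[0], win[1], frag_triplet.mz[0] - 1.5, frag_triplet.mz[0] + 2.5
                )
            except EmptyWindowError:
                frag_spec = (np.empty(0), np.empty(0))
            if not np.any(frag_xic.intensity > 0) and frag_spec[0].size == 0:
                comps[kind] = (float("nan"), float("nan"))  # wholly missing fragment
                continue
            comps[kind] = score_fragment(
                xic, frag_xic, frag_spec, frag_triplet, fit, config.mz_tol_fit
            )
        scores = FragmentScores(
            rt_cosine_aldehyde=comps["aldehyde"][0],
            mz_cosine_aldehyde=comps["aldehyde"][1],
            rt_cosine_criegee=comps["criegee"][0],
            mz_cosine_criegee=comps["criegee"][1],
        )
        candidates.append((pair, scores))
        if k in ambiguous:
            extra_flags[k] = ("chain-ambiguous",)

    assignments = assign(
        target.lipid, target.adduct, candidates, cutoff=config.score_cutoff, extra_flags=extra_flags
    )
    frame = assignments_frame(assignments)
    frame.insert(2, "target_rt", target.retention_time_min)
    frame.insert(3, "observed_rt", round(fit.mean, 6))

    if mode in {"dl", "both"}:
        images = [
            build_image(run, prec_mz, pair, fit.mean, size=model.image_size)
            for pair, _ in candidates
        ]
        # candidates order matches `pairs`; re-rank to match `assignments`
        by_site = {
            (p.site.chain, p.site.index, p.site.position): i
            for i, (p, _) in enumerate(candidates)
        }
        p_true = predict_proba(model, images) if images else np.empty(0)
        ordered = [
            p_true[by_site[(a.chain, a.index, a.position)]] for a in assignments
        ]
        frame["dl_p_true"] = [round(float(p), 6) for p in ordered]
        frame["dl_label"] = [bool(p >= 0.5) for p in ordered]
        if mode == "dl":
            frame["decision"] = ["accepted" if p >= 0.5 else "rejected" for p in ordered]

    diag.status = "analyzed"
    diag.n_candidates = len(candidates)
    diag.n_accepted = int((frame["decision"] == "accepted").sum())
    diag._assignments = assignments  # type: ignore[attr-defined]
    log.info(
        "target %s %s: %d candidates, %d accepted",
        target.lipid,
        target.adduct,
        diag.n_candidates,
        diag.n_accepted,
    )
    return frame
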