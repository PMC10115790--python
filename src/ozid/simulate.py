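"""Synthetic LC-OzID-MS runs with planted double-bond ground truth.

The simulator emulates what the analysis sees in a real run of labeled
lipid standards: each target elutes as a Gaussian chromatographic peak,
every ion carries its theoretical M/M+1/M+2 envelope rendered as Gaussian
profile peaks, and each *true* double-bond site contributes co-eluting
aldehyde/criegee fragment signals at the exact m/z values predicted by
the fragment chemistry (shared code path with :mod:`ozid.fragments`).
Decoy sites are silent unless an interference preset plants confounders:

* ``rt-shift-decoys`` — fragment-pair signals with correct isotope ratios
  but shifted retention time (fails the chromatographic score);
* ``isotope-decoys`` — co-eluting signals with scrambled isotope ratios
  (fails the spectral score);
* ``realistic`` — a seeded mixture of both on a fraction of decoy sites,
  plus Poisson counting noise and uniform chemical-noise spikes.

Optional detector saturation clips intensities at a configured level.
A fixed seed fully determines the run, down to the bytes of the written
run-store file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .formula import get_adduct
from .fragments import EnumerationRules, predict_fragments
from .images import ProfileImage, build_image
from .isotopes import IsotopeTriplet, isotope_triplet
from .lipids import parse_target_name, species_formula
from .rawdata import RawRun

__all__ = ["SimulatedLipid", "SimulationSpec", "simulate_run", "make_training_corpus"]

_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # FWHM -> sigma divisor


@dataclass(frozen=True)
class SimulatedLipid:
    """One planted target: species, adduct, elution and true sites."""

    name: str
    adduct: str
    rt: float
    abundance: float = 1e5
    # chain index -> methyl-referenced positions in index order, e.g. {1: (6, 9, 12)}
    true_positions: dict = field(default_factory=dict)
    # (chain, position) sites whose criegee fragment is suppressed
    criegee_suppressed: tuple = ()


@dataclass(frozen=True)
class SimulationSpec:
    """Full description of a synthetic run; the seed determines everything."""

    lipids: tuple
    noise_level: float = 0.0  # 0 = noise-free; 1 = nominal Poisson counting noise
    interference: str = "none"  # none | rt-shift-decoys | isotope-decoys | realistic
    saturation_level: float | None = None
    rt_start: float = 0.0
    rt_end: float = 16.0
    scan_rate_hz: float = 2.0
    mz_step: float = 0.005
    peak_fwhm_mz: float = 0.03
    peak_fwhm_rt: float = 0.25
    fragment_yield: float = 0.05  # fragment apex as a fraction of precursor apex
    seed: int = 0
    rules: EnumerationRules = EnumerationRules()

    def __post_init__(self) -> None:
        problems = []
        if not self.lipids:
            problems.append("lipids: at least one entry required")
        if self.interference not in {"none", "rt-shift-decoys", "isotope-decoys", "realistic"}:
            problems.append(f"interference: unknown preset {self.interference!r}")
        if self.rt_end <= self.rt_start:
            problems.append("rt_end must exceed rt_start")
        if self.scan_rate_hz <= 0 or self.mz_step <= 0 or self.peak_fwhm_mz <= 0:
            problems.append("scan_rate_hz, mz_step, peak_fwhm_mz must be > 0")
        for lip in self.lipids:
            if not self.rt_start < lip.rt < self.rt_end:
                problems.append(f"{lip.name}: rt {lip.rt} outside the run span")
        if problems:
            raise ValueError("invalid simulation spec: " + "; ".join(problems))
        object.__setattr__(self, "lipids", tuple(self.lipids))

    def to_json(self, path: str | Path) -> None:
        doc = asdict(self)
        doc["lipids"] = [asdict(l) for l in self.lipids]
        doc["rules"] = asdict(self.rules)
        Path(path).write_text(json.dumps(doc, indent=2, default=list))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationSpec":
        doc = json.loads(Path(path).read_text())
        lipids = tuple(
            SimulatedLipid(
                name=l["name"],
                adduct=l["adduct"],
                rt=l["rt"],
                abundance=l.get("abundance", 1e5),
                true_positions={int(k): tuple(v) for k, v in l.get("true_positions", {}).items()},
                criegee_suppressed=tuple(tuple(s) for s in l.get("criegee_suppressed", [])),
            )
            for l in doc["lipids"]
        )
        rules = EnumerationRules(**doc.get("rules", {}))
        kwargs = {
            k: v
            for k, v in doc.items()
            if k not in ("lipids", "rules")
        }
        return cls(lipids=lipids, rules=rules, **kwargs)


@dataclass
class _Signal:
    centers: np.ndarray  # isotope m/z values
    heights: np.ndarray  # relative isotope abundances
    rt: float
    apex: float


# fraction of decoy sites that receive an interfering signal per preset
_DECOY_FRACTION = {"rt-shift-decoys": 1.0, "isotope-decoys": 1.0, "realistic": 0.25}


def _scramble_ratios(rng: np.random.Generator) -> np.ndarray:
    """Isotope ratios far from any lipid-scale envelope (M+1 comparable to M)."""
    return np.array([1.0, rng.uniform(0.7, 1.0), rng.uniform(0.5, 0.9)])


def _isotope_interferer(
    triplet: IsotopeTriplet, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """A co-eluting compound whose envelope is offset by one nominal mass.

    Its monoisotope sits ~1.003 Da below the candidate fragment m/z, so the
    interferer's M+1 feeds the fragment XIC (which therefore co-elutes with
    the precursor) while the MS1 window shows a dominant peak one mass unit
    low — the spectral cosine fails even though the chromatographic one
    passes.
    """
    centers = np.array(triplet.mz) - 1.003355
    heights = np.array([1.0, rng.uniform(0.35, 0.55), rng.uniform(0.08, 0.2)])
    return centers, heights


def simulate_run(spec: SimulationSpec) -> tuple[RawRun, pd.DataFrame]:
    """Render the run and return it with a ground-truth site table.

    The table has one row per enumerated candidate site of every lipid:
    columns lipid, adduct, chain, index, n_position, rt, is_true,
    interference (none/rt-shift/isotope), criegee_suppressed,
    aldehyde_mz, criegee_mz, precursor_mz.
    """
    rng = np.random.default_rng(spec.seed)
    dt = 1.0 / (spec.scan_rate_hz * 60.0)
    scan_rts = np.arange(spec.rt_start, spec.rt_end, dt)
    rt_sigma = spec.peak_fwhm_rt / _SIGMA

    signals: list[_Signal] = []
    truth_rows: list[dict] = []

    for lip in spec.lipids:
        species = parse_target_name(lip.name)
        adduct = get_adduct(lip.adduct)
        neutral = species_formula(species)
        ion = adduct.ion_formula(neutral)
        prec_triplet = isotope_triplet(ion, adduct.charge)
        prec_mz = adduct.mz(neutral)
        signals.append(
            _Signal(
                np.array(prec_triplet.mz),
                np.array(prec_triplet.abundance),
                lip.rt,
                lip.abundance,
            )
        )
        pairs, _ambig = predict_fragments(species, adduct, rules=spec.rules)
        for pair in pairs:
            site = pair.site
            truths = lip.true_positions.get(site.chain, ())
            # a site is true when its position matches the planted bond of its index
            is_true = (
                len(truths) >= site.index and truths[site.index - 1] == site.position
            )
            interference = "none"
            suppressed = (site.chain, site.position) in {
                tuple(s) for s in lip.criegee_suppressed
            }
            ald_triplet = isotope_triplet(pair.aldehyde_formula, pair.charge)
            cri_triplet = isotope_triplet(pair.criegee_formula, pair.charge)
            if is_true:
                apex = spec.fragment_yield * lip.abundance
                signals.append(
                    _Signal(np.array(ald_triplet.mz), np.array(ald_triplet.abundance), lip.rt, apex)
                )
                if not suppressed:
                    signals.append(
                        _Signal(
                            np.array(cri_triplet.mz),
                            np.array(cri_triplet.abundance),
                            lip.rt,
                            0.8 * apex,
                        )
                    )
            else:
                frac = _DECOY_FRACTION.get(spec.interference, 0.0)
                if frac > 0.0 and rng.random() < frac:
                    if spec.interference == "rt-shift-decoys":
                        kind = "rt-shift"
                    elif spec.interference == "isotope-decoys":
                        kind = "isotope"
                    else:
                        kind = ["rt-shift", "isotope", "ratio-scramble"][int(rng.integers(3))]
                    interference = kind
                    apex = spec.fragment_yield * lip.abundance * rng.uniform(0.4, 1.2)
                    if kind == "rt-shift":
                        shift = rng.uniform(3.0, 6.0) * rt_sigma * rng.choice([-1.0, 1.0])
                        rt = float(np.clip(lip.rt + shift, spec.rt_start + 0.2, spec.rt_end - 0.2))
                        for trip in (ald_triplet, cri_triplet):
                            signals.append(
                                _Signal(np.array(trip.mz), np.array(trip.abundance), rt, apex)
                            )
                    elif kind == "isotope":
                        for trip in (ald_triplet, cri_triplet):
                            centers, heights = _isotope_interferer(trip, rng)
                            signals.append(_Signal(centers, heights, lip.rt, apex))
                    else:
                        # near-miss: correct m/z but wrong isotope ratios
                        for trip in (ald_triplet, cri_triplet):
                            signals.append(
                                _Signal(np.array(trip.mz), _scramble_ratios(rng), lip.rt, apex)
                            )
            truth_rows.append(
                {
                    "lipid": lip.name,
                    "adduct": lip.adduct,
                    "chain": site.chain,
                    "index": site.index,
                    "n_position": site.position,
                    "rt": lip.rt,
                    "is_true": is_true,
                    "interference": interference,
                    "criegee_suppressed": bool(is_true and suppressed),
                    "aldehyde_mz": pair.aldehyde_mz,
                    "criegee_mz": pair.criegee_mz,
                    "precursor_mz": prec_mz,
                }
            )

    mz_sigma = spec.peak_fwhm_mz / _SIGMA
    half = 5.0 * mz_sigma
    scans: list[tuple[float, np.ndarray, np.ndarray]] = []
    # accumulate on an integer m/z grid so coincident points merge exactly
    def grid(m: float) -> int:
        return int(round(m / spec.mz_step))

    acc: list[dict[int, float]] = [dict() for _ in range(scan_rts.size)]
    for sig in signals:
        lo_scan = np.searchsorted(scan_rts, sig.rt - 4.5 * rt_sigma)
        hi_scan = np.searchsorted(scan_rts, sig.rt + 4.5 * rt_sigma)
        if hi_scan <= lo_scan:
            continue
        point_keys: list[int] = []
        point_amp: list[float] = []
        for center, height in zip(sig.centers, sig.heights):
            if height <= 0:
                continue
            ks = np.arange(grid(center - half), grid(center + half) + 1)
            mzs = ks * spec.mz_step
            amps = height * np.exp(-0.5 * ((mzs - center) / mz_sigma) ** 2)
            point_keys.extend(int(k) for k in ks)
            point_amp.extend(amps)
        amp_arr = np.array(point_amp)
        for s in range(lo_scan, hi_scan):
            elut = np.exp(-0.5 * ((scan_rts[s] - sig.rt) / rt_sigma) ** 2)
            vals = sig.apex * elut * amp_arr
            bucket = acc[s]
            for k, v in zip(point_keys, vals):
                bucket[k] = bucket.get(k, 0.0) + v

    noisy = spec.noise_level > 0.0
    spike_range = None
    if noisy and signals:
        all_centers = np.concatenate([s.centers for s in signals])
        spike_range = (all_centers.min() - 2.0, all_centers.max() + 2.0)

    for s, rt in enumerate(scan_rts):
        bucket = acc[s]
        if noisy and bucket:
            keys = np.array(sorted(bucket))
            vals = np.array([bucket[k] for k in keys])
            scaled = rng.poisson(np.maximum(vals / spec.noise_level, 0.0)) * spec.noise_level
            bucket = dict(zip((int(k) for k in keys), scaled))
            # uniform chemical-noise spikes
            for _ in range(rng.poisson(2.0)):
                k = grid(rng.uniform(*spike_range))
                bucket[k] = bucket.get(k, 0.0) + rng.uniform(
                    0.001, 0.01
                ) * spec.noise_level * max(l.abundance for l in spec.lipids)
        if not bucket:
            scans.append((float(rt), np.empty(0), np.empty(0)))
            continue
        keys = sorted(bucket)
        mz = np.array([k * spec.mz_step for k in keys])
        inten = np.array([bucket[k] for k in keys])
        if spec.saturation_level is not None:
            inten = np.minimum(inten, spec.saturation_level)
        keep = inten > 0
        scans.append((float(rt), mz[keep], inten[keep]))

    polarity = "negative" if any(get_adduct(l.adduct).charge < 0 for l in spec.lipids) else "positive"
    run = RawRun(scans, polarity=polarity, run_id=f"sim-seed{spec.seed}")
    truth = pd.DataFrame(truth_rows)
    return run, truth


# ---------------------------------------------------------------------------
# training-corpus generation


_CORPUS_LIPIDS = [
    # (name, adduct) pool the corpus generator cycles through
    ("PC(16:0/18:1)", "[M+H]+"),
    ("PC(16:0/18:2)", "[M+H]+"),
    ("PE(16:0/18:1)", "[M-H]-"),
    ("PG(17:0/20:3)", "[M-H]-"),
    ("PG(16:0/18:1)", "[M-H]-"),
    ("PS(18:0/18:1)", "[M-H]-"),
]


def _random_truths(name: str, rng: np.random.Generator, rules: EnumerationRules):
    """Pick a consistent set of true positions for every unsaturated chain."""
    species = parse_target_name(name)
    truths = {}
    for ci, chain in enumerate(species.chains):
        d = chain.double_bonds
        if d == 0:
            continue
        # draw index-1 position, then space the rest methylene-interrupted
        max_x1 = chain.carbons - 2 - rules.min_spacing * (d - 1)
        x1 = int(rng.integers(rules.x_min, max_x1 + 1))
        truths[ci] = tuple(x1 + rules.min_spacing * i for i in range(d))
    return truths


def make_training_corpus(
    n_true: int,
    n_false: int,
    seed: int,
    image_size: int = 32,
    noise_level: float = 0.0,
    interference: str = "none",
) -> list[ProfileImage]:
    """Labeled source images: ``n_true`` true sites and ``n_false`` decoys.

    Small single-lipid runs are simulated until the requested class counts
    are reached; every image is tagged with a unique source id so
    augmentation and splitting can stay leakage-free.
    """
    if n_true < 1 or n_false < 1:
        raise ValueError("n_true and n_false must be >= 1")
    rng = np.random.default_rng(seed)
    rules = EnumerationRules()
    images: list[ProfileImage] = []
    got_true = got_false = 0
    run_idx = 0
    while got_true < n_true or got_false < n_false:
        name, adduct = _CORPUS_LIPIDS[run_idx % len(_CORPUS_LIPIDS)]
        rt = float(rng.uniform(4.0, 8.0))
        lip = SimulatedLipid(
            name,
            adduct,
            rt=rt,
            abundance=float(rng.uniform(5e4, 2e5)),
            true_positions=_random_truths(name, rng, rules),
        )
        spec = SimulationSpec(
            lipids=(lip,),
            noise_level=noise_level,
            interference=interference,
            rt_start=max(0.0, rt - 3.5),
            rt_end=rt + 3.5,
            seed=int(rng.integers(0, 2**31 - 1)),
            rules=rules,
        )
        run, truth = simulate_run(spec)
        species = parse_target_name(name)
        pairs, _ = predict_fragments(species, get_adduct(adduct), rules=rules)
        order = rng.permutation(len(pairs))
        for k in order:
            pair = pairs[k]
            row = truth.iloc[int(k)]
            label = bool(row["is_true"])
            if label and got_true >= n_true:
                continue
            if not label and got_false >= n_false:
                continue
            img = build_image(
                run,
                float(row["precursor_mz"]),
                pair,
                rt_center=rt,
                size=image_size,
                label=label,
                source_id=f"run{run_idx}_site{k}",
            )
            images.append(img)
            if label:
                got_true += 1
            else:
                got_false += 1
            if got_true >= n_true and got_false >= n_false:
                break
        run_idx += 1
    return images
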