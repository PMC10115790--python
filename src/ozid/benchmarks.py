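"""Self-validation experiments on simulated runs with known ground truth.

These are the package's reproducibility workloads: each function builds a
seeded synthetic dataset, runs the relevant part of the pipeline on it and
returns summary metrics against the planted truth.  They are used by the
test suite and by ``scripts/acceptance.py``.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from . import cnn
from .formula import MolecularFormula, get_adduct
from .images import augment, split_train_val
from .isotopes import isotope_triplet
from .lipids import parse_target_name
from .peaks import fit_chrom_peak, fit_isotope_peaks, gaussian, select_ms1_rt_window
from .rawdata import Chromatogram, extract_ms1, extract_xic
from .simulate import SimulatedLipid, SimulationSpec, make_training_corpus, simulate_run
from .workflow import Target, run_workflow

__all__ = [
    "clean_standard_recovery",
    "realistic_recovery",
    "signal_recovery",
    "leading_edge_gain",
    "dl_experiment",
]

_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))


def _target(lip: SimulatedLipid) -> Target:
    return Target(
        lip.name, lip.adduct, lip.rt, parse_target_name(lip.name), get_adduct(lip.adduct)
    )


def clean_standard_recovery(seed: int = 0) -> dict:
    """Noise-free run of the triunsaturated PG standard (true n-6/9/12).

    Returns the accepted-site count and how many of them are planted truths.
    """
    lip = SimulatedLipid(
        "D5-PG(17:0/20:3)", "[M-H]-", rt=8.0, abundance=1e5, true_positions={1: (6, 9, 12)}
    )
    spec = SimulationSpec(lipids=(lip,), rt_start=5.0, rt_end=11.0, seed=seed)
    run, truth = simulate_run(spec)
    res = run_workflow([_target(lip)], run)
    merged = res.results.merge(truth, on=["lipid", "adduct", "chain", "index", "n_position"])
    acc = merged["decision"] == "accepted"
    return {
        "n_candidates": len(merged),
        "n_accepted": int(acc.sum()),
        "n_true_accepted": int((acc & merged["is_true"]).sum()),
        "n_decoys_accepted": int((acc & ~merged["is_true"]).sum()),
    }


_REALISTIC_PANEL = [
    ("PC(16:0/18:1)", "[M+H]+", 4.0, 1.0e5, {1: (9,)}),
    ("PC(16:0/18:2)", "[M+H]+", 5.2, 8.0e4, {1: (6, 9)}),
    ("PE(16:0/18:1)", "[M-H]-", 6.4, 1.2e5, {1: (7,)}),
    ("D5-PG(17:0/20:3)", "[M-H]-", 7.6, 1.0e5, {1: (6, 9, 12)}),
    ("PG(16:0/18:1)", "[M-H]-", 8.8, 9.0e4, {1: (9,)}),
    ("PS(18:0/18:1)", "[M-H]-", 10.0, 1.1e5, {1: (9,)}),
    ("PC(16:0/18:1)", "[M+Na]+", 11.2, 7.0e4, {1: (11,)}),
    ("PE(16:0/18:2)", "[M-H]-", 12.4, 1.0e5, {1: (6, 9)}),
    ("TG(16:0/18:1/18:2)", "[M+NH4]+", 13.6, 9.0e4, {1: (9,), 2: (6, 9)}),
    ("LPC(18:1)", "[M+H]+", 3.0, 6.0e4, {0: (9,)}),
]


def realistic_recovery(seed: int = 0) -> dict:
    """Ten-lipid panel under the realistic-interference preset with noise.

    Accuracy is the fraction of candidate sites whose accept/reject call
    matches the planted truth; FDR is false accepts over all accepts.
    """
    lipids = tuple(SimulatedLipid(*row) for row in _REALISTIC_PANEL)
    spec = SimulationSpec(
        lipids=lipids,
        noise_level=1.0,
        interference="realistic",
        rt_start=1.0,
        rt_end=15.0,
        seed=seed,
    )
    run, truth = simulate_run(spec)
    res = run_workflow([_target(l) for l in lipids], run)
    merged = res.results.merge(truth, on=["lipid", "adduct", "chain", "index", "n_position"])
    pred = merged["decision"] == "accepted"
    tp = int((pred & merged["is_true"]).sum())
    fp = int((pred & ~merged["is_true"]).sum())
    fn = int((~pred & merged["is_true"]).sum())
    return {
        "n_candidates": len(merged),
        "accuracy": float((pred == merged["is_true"]).mean()),
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "fdr": fp / max(tp + fp, 1),
    }


def signal_recovery(seed: int = 0, n_peaks: int = 100) -> dict:
    """Fit recovery on Poisson-noised Gaussian peaks at SNR >= 20.

    Chromatographic peaks (FWHM 0.25 min, apex 2e4 counts) and isotope
    envelopes (apex 5e3 counts) are regenerated per replicate; reported are
    the median absolute RT error and the median worst-isotope ratio error.
    """
    rng = np.random.default_rng(seed)
    triplet = isotope_triplet(
        MolecularFormula({"C": 42, "H": 83, "N": 1, "O": 8, "P": 1}), 1
    )
    sigma_mz = 0.03 / _FWHM
    grid = np.arange(triplet.mz[0] - 1.5, triplet.mz[0] + 2.5, 0.003)
    base = np.zeros_like(grid)
    for c, h in zip(triplet.mz, triplet.abundance):
        base += 5e3 * h * np.exp(-0.5 * ((grid - c) / sigma_mz) ** 2)
    rt_errors, ratio_errors = [], []
    for _ in range(n_peaks):
        mean = rng.uniform(5.0, 9.0)
        rt = np.arange(4.0, 10.0, 1 / 120)
        y = rng.poisson(gaussian(rt, 2e4, mean, 0.25 / _FWHM)).astype(float)
        fit = fit_chrom_peak(Chromatogram(rt, y), mean + rng.uniform(-0.1, 0.1))
        if fit.ok:
            rt_errors.append(abs(fit.mean - mean))
        obs = fit_isotope_peaks((grid, rng.poisson(base).astype(float)), triplet)
        ratio_errors.append(
            float(np.max(np.abs(np.array(obs.triplet.abundance) - triplet.abundance)))
        )
    return {
        "n": n_peaks,
        "median_rt_error_min": float(np.median(rt_errors)),
        "median_ratio_error": float(np.median(ratio_errors)),
    }


def leading_edge_gain(seed: int = 0, n_reps: int = 50) -> dict:
    """Isotope-ratio bias on clipped peaks: leading-edge vs apex windows.

    Each replicate simulates a saturated precursor (detector clip at 30% of
    the apex), then extracts the MS1 isotope ratios from both the
    leading-edge window the saturation rule selects and the apex window it
    would have used; the error against the theoretical ratios is compared.
    """
    rng = np.random.default_rng(seed)
    lead_err, apex_err = [], []
    species = parse_target_name("PC(16:0/18:1)")
    adduct = get_adduct("[M+H]+")
    from .lipids import species_formula

    ion = adduct.ion_formula(species_formula(species))
    triplet = isotope_triplet(ion, 1)
    theo = np.array(triplet.abundance)
    mz = adduct.mz(species_formula(species))
    for _ in range(n_reps):
        lip = SimulatedLipid("PC(16:0/18:1)", "[M+H]+", 5.0, 1e6, {1: (9,)})
        spec = SimulationSpec(
            lipids=(lip,),
            rt_start=3.0,
            rt_end=7.0,
            seed=int(rng.integers(0, 2**31 - 1)),
            saturation_level=3e5,
            noise_level=0.5,
        )
        run, _ = simulate_run(spec)
        xic = extract_xic(run, mz, 0.02, 3.0, 7.0)
        fit = fit_chrom_peak(xic, 5.0, saturation_threshold=2.9e5)
        if not fit.ok or not fit.saturated:
            continue
        windows = {
            "lead": select_ms1_rt_window(fit, xic.rt[0], xic.rt[-1]),
            "apex": select_ms1_rt_window(
                replace(fit, saturated=False), xic.rt[0], xic.rt[-1]
            ),
        }
        errs = {}
        for name, win in windows.items():
            spec_slice = extract_ms1(run, win[0], win[1], triplet.mz[0] - 1.5, triplet.mz[0] + 2.5)
            obs = fit_isotope_peaks(spec_slice, triplet)
            errs[name] = float(np.max(np.abs(np.array(obs.triplet.abundance) - theo)))
        lead_err.append(errs["lead"])
        apex_err.append(errs["apex"])
    return {
        "n": len(lead_err),
        "median_leading_edge_error": float(np.median(lead_err)),
        "median_apex_error": float(np.median(apex_err)),
        "fraction_improved": float(np.mean(np.array(lead_err) < np.array(apex_err))),
    }


def dl_experiment(
    seed: int = 0,
    n_true: int = 50,
    n_false: int = 200,
    epochs: int = 8,
    batch_size: int = 128,
    image_size: int = 32,
) -> dict:
    """Corpus generation, 10-fold augmentation, 4:1 split and CNN training."""
    sources = make_training_corpus(n_true, n_false, seed=seed, image_size=image_size)
    images = []
    for src in sources:
        images.append(src)
        images.extend(augment(src))
    train_set, val_set = split_train_val(images, seed=seed)
    model = cnn.train(
        train_set, val_set, cnn.TrainConfig(epochs=epochs, batch_size=batch_size, seed=seed)
    )
    # accuracy of the kept (minimal-validation-loss) parameters
    xva, yva = cnn._to_arrays(val_set)
    weights = cnn.class_weight_vector(cnn._to_arrays(train_set)[1])
    _, val_accuracy = cnn.evaluate(model.network, xva, yva, weights)
    return {
        "n_sources": len(sources),
        "n_images": len(images),
        "images_per_source": len(images) // len(sources),
        "n_train": len(train_set),
        "n_val": len(val_set),
        "val_accuracy": float(val_accuracy),
        "best_epoch": model.best_epoch,
        "model": model,
        "train_sources": {im.source_id for im in train_set},
        "val_sources": {im.source_id for im in val_set},
    }
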