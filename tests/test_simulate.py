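"""Run simulator: determinism, shared fragment chemistry, conservation."""

import hashlib

import numpy as np
import pytest

from ozid.formula import get_adduct
from ozid.fragments import predict_fragments
from ozid.lipids import parse_target_name
from ozid.rawdata import write_run_store
from ozid.simulate import (
    SimulatedLipid,
    SimulationSpec,
    make_training_corpus,
    simulate_run,
)
from ozid.workflow import run_workflow

from conftest import make_target


def file_hash(path):
    return hashlib.sha256(path.read_bytes()).hexdigest()


class TestDeterminism:
    def test_same_seed_byte_identical_run_store(self, tmp_path):
        lip = SimulatedLipid("PC(16:0/18:1)", "[M+H]+", 5.0, 1e5, {1: (9,)})
        spec = SimulationSpec(
            lipids=(lip,), rt_start=2.0, rt_end=8.0, seed=3,
            noise_level=1.0, interference="realistic",
        )
        p1, p2 = tmp_path / "a.h5", tmp_path / "b.h5"
        write_run_store(simulate_run(spec)[0], p1)
        write_run_store(simulate_run(spec)[0], p2)
        assert file_hash(p1) == file_hash(p2)

    def test_different_seed_differs(self, tmp_path):
        lip = SimulatedLipid("PC(16:0/18:1)", "[M+H]+", 5.0, 1e5, {1: (9,)})
        mk = lambda s: SimulationSpec(
            lipids=(lip,), rt_start=2.0, rt_end=8.0, seed=s, noise_level=1.0
        )
        p1, p2 = tmp_path / "a.h5", tmp_path / "b.h5"
        write_run_store(simulate_run(mk(1))[0], p1)
        write_run_store(simulate_run(mk(2))[0], p2)
        assert file_hash(p1) != file_hash(p2)

    def test_spec_json_roundtrip(self, tmp_path):
        lip = SimulatedLipid(
            "D5-PG(17:0/20:3)", "[M-H]-", 8.0, 1e5, {1: (6, 9, 12)}, ((1, 6),)
        )
        spec = SimulationSpec(lipids=(lip,), rt_start=5.0, rt_end=11.0, seed=7)
        p = tmp_path / "spec.json"
        spec.to_json(p)
        assert SimulationSpec.from_json(p) == spec


class TestSharedChemistry:
    def test_truth_mz_matches_fragment_prediction_exactly(self, pg_standard_run):
        _, truth, target = pg_standard_run
        pairs, _ = predict_fragments(target.species, target.adduct_obj)
        assert len(pairs) == len(truth)
        for pair, (_, row) in zip(pairs, truth.iterrows()):
            assert row["aldehyde_mz"] == pair.aldehyde_mz
            assert row["criegee_mz"] == pair.criegee_mz

    def test_truth_marks_planted_sites(self, pg_standard_run):
        _, truth, _ = pg_standard_run
        planted = truth[truth["is_true"]]
        assert set(zip(planted["index"], planted["n_position"])) == {(1, 6), (2, 9), (3, 12)}


class TestConservation:
    def test_planted_intensity_equals_tic_noise_free(self):
        lip = SimulatedLipid("PC(16:0/18:1)", "[M+H]+", 5.0, 1e5, {1: (9,)})
        spec = SimulationSpec(lipids=(lip,), rt_start=2.0, rt_end=8.0, seed=1)
        run, _ = simulate_run(spec)
        tic = sum(s[2].sum() for s in run.scans)

        # independent expectation: sum of Gaussian elution x Gaussian m/z
        # profiles over the same scan/point grids for every planted signal
        from ozid.isotopes import isotope_triplet
        from ozid.lipids import species_formula

        species = parse_target_name(lip.name)
        adduct = get_adduct(lip.adduct)
        ion = adduct.ion_formula(species_formula(species))
        sigma_rt = spec.peak_fwhm_rt / (2 * np.sqrt(2 * np.log(2)))
        sigma_mz = spec.peak_fwhm_mz / (2 * np.sqrt(2 * np.log(2)))
        scan_rts = np.arange(spec.rt_start, spec.rt_end, 1 / (spec.scan_rate_hz * 60))
        expected = 0.0
        pairs, _ = predict_fragments(species, adduct)
        planted = [(isotope_triplet(ion, adduct.charge), lip.abundance)]
        for pair in pairs:
            if pair.site.chain == 1 and pair.site.position == 9 and pair.site.index == 1:
                planted.append(
                    (isotope_triplet(pair.aldehyde_formula, 1), spec.fragment_yield * lip.abundance)
                )
                planted.append(
                    (isotope_triplet(pair.criegee_formula, 1), 0.8 * spec.fragment_yield * lip.abundance)
                )
        for trip, apex in planted:
            elut = np.exp(-0.5 * ((scan_rts - lip.rt) / sigma_rt) ** 2).sum()
            for c, h in zip(trip.mz, trip.abundance):
                ks = np.arange(
                    round((c - 5 * sigma_mz) / spec.mz_step), round((c + 5 * sigma_mz) / spec.mz_step) + 1
                )
                amps = h * np.exp(-0.5 * ((ks * spec.mz_step - c) / sigma_mz) ** 2)
                expected += apex * elut * amps.sum()
        assert tic == pytest.approx(expected, rel=0.01)


class TestValidation:
    def test_invalid_spec_lists_fields(self):
        lip = SimulatedLipid("PC(16:0/18:1)", "[M+H]+", 50.0, 1e5, {1: (9,)})
        with pytest.raises(ValueError, match="rt"):
            SimulationSpec(lipids=(lip,), rt_start=0.0, rt_end=10.0, seed=0)

    def test_unknown_preset_rejected(self):
        lip = SimulatedLipid("PC(16:0/18:1)", "[M+H]+", 5.0, 1e5, {1: (9,)})
        with pytest.raises(ValueError, match="interference"):
            SimulationSpec(lipids=(lip,), rt_start=2.0, rt_end=8.0, interference="wild")


class TestCriegeeSuppression:
    def test_suppressed_site_yields_partial_assignment(self):
        lip = SimulatedLipid(
            "PC(16:0/18:1)", "[M+H]+", 5.0, 1e5, {1: (9,)}, criegee_suppressed=((1, 9),)
        )
        spec = SimulationSpec(lipids=(lip,), rt_start=2.0, rt_end=8.0, seed=2)
        run, _ = simulate_run(spec)
        res = run_workflow([make_target(lip.name, lip.adduct, lip.rt)], run)
        row = res.results[(res.results["n_position"] == 9) & (res.results["index"] == 1)]
        assert list(row["decision"]) == ["partial"]
        assert "criegee-missing" in row["flags"].iloc[0]
        assert (res.results["decision"] == "accepted").sum() == 0


class TestCorpus:
    def test_exact_class_counts(self):
        images = make_training_corpus(5, 20, seed=1, image_size=16)
        labels = [im.label for im in images]
        assert sum(labels) == 5 and len(labels) == 25

    def test_regenerable_from_seed(self):
        a = make_training_corpus(3, 6, seed=4, image_size=16)
        b = make_training_corpus(3, 6, seed=4, image_size=16)
        for ia, ib in zip(a, b):
            assert ia.source_id == ib.source_id and ia.label == ib.label
            np.testing.assert_array_equal(ia.tensor, ib.tensor)

    def test_counts_must_be_positive(self):
        with pytest.raises(ValueError):
            make_training_corpus(0, 5, seed=0)

    def test_noise_free_true_sources_pass_heuristic(self):
        # cross-module consistency: the corpus generator's True images come
        # from sites the cutoff heuristic accepts on the same runs
        images = make_training_corpus(4, 4, seed=11, image_size=16)
        for im in images:
            if im.label:
                t = im.tensor
                assert t[1].max() > 0.5 and t[2].max() > 0.5
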