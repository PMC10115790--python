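"""Cosine-distance scoring, the cutoff heuristic and results export."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.spatial.distance import cosine as scipy_cosine

from ozid.formula import MolecularFormula
from ozid.fragments import DoubleBondSite, OzidFragmentPair
from ozid.isotopes import isotope_triplet
from ozid.peaks import PeakFit, gaussian
from ozid.rawdata import Chromatogram
from ozid.scoring import (
    FragmentScores,
    assign,
    composite_score,
    cosine_distance,
    export_results,
    score_fragment,
    spectral_cosine,
)

FWHM = 2 * np.sqrt(2 * np.log(2))


class TestCosineDistance:
    def test_identical_is_zero(self):
        v = np.array([1.0, 2.0, 3.0])
        assert cosine_distance(v, v) == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_is_one(self):
        assert cosine_distance(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == 1.0

    def test_closed_form_half_overlap(self):
        d = cosine_distance(np.array([1.0, 1.0]), np.array([1.0, 0.0]))
        assert d == pytest.approx(1 - 1 / np.sqrt(2), abs=1e-12)

    def test_zero_vector_convention(self):
        assert cosine_distance(np.zeros(3), np.array([1.0, 2.0, 3.0])) == 1.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            cosine_distance(np.ones(3), np.ones(4))

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1e3), min_size=2, max_size=8),
        st.lists(st.floats(min_value=0.0, max_value=1e3), min_size=2, max_size=8),
        st.floats(min_value=1e-3, max_value=1e3),
    )
    def test_symmetry_and_scale_invariance(self, a, b, scale):
        n = min(len(a), len(b))
        va, vb = np.array(a[:n]), np.array(b[:n])
        d = cosine_distance(va, vb)
        assert 0.0 <= d <= 1.0
        assert d == pytest.approx(cosine_distance(vb, va), abs=1e-9)
        assert cosine_distance(scale * va, vb) == pytest.approx(d, abs=1e-9)

    def test_agrees_with_scipy(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a, b = rng.uniform(0.1, 1, 16), rng.uniform(0.1, 1, 16)
            assert cosine_distance(a, b) == pytest.approx(scipy_cosine(a, b), abs=1e-9)


TRIPLET = isotope_triplet(MolecularFormula({"C": 30, "H": 58, "O": 4}), 1)


def chrom(mean, height=1e4, fwhm=0.25, lo=4.0, hi=8.0):
    rt = np.arange(lo, hi, 1 / 120)
    return Chromatogram(rt, gaussian(rt, height, mean, fwhm / FWHM))


def spectrum(triplet, scale=1e3, fwhm=0.03, shift=0.0):
    grid = np.arange(triplet.mz[0] - 1.5, triplet.mz[0] + 2.5, 0.003)
    y = np.zeros_like(grid)
    for c, h in zip(triplet.mz, triplet.abundance):
        y += scale * h * np.exp(-0.5 * ((grid - (c + shift)) / (fwhm / FWHM)) ** 2)
    return grid, y


def precursor_fit(mean=6.0, fwhm=0.25):
    return PeakFit(mean, 1e4, fwhm, 0.999, False, "ok")


class TestScoreFragment:
    def test_coeluting_matching_fragment_scores_low(self):
        rt_cos, mz_cos = score_fragment(
            chrom(6.0), chrom(6.0, height=500.0), spectrum(TRIPLET), TRIPLET, precursor_fit()
        )
        assert rt_cos < 0.1 and mz_cos < 0.1

    def test_absent_fragment_maximal_distances(self):
        empty = Chromatogram(chrom(6.0).rt, np.zeros_like(chrom(6.0).rt))
        grid = spectrum(TRIPLET)[0]
        rt_cos, mz_cos = score_fragment(
            chrom(6.0), empty, (grid, np.zeros_like(grid)), TRIPLET, precursor_fit()
        )
        assert rt_cos == 1.0 and mz_cos == 1.0

    def test_rt_shift_three_fwhm_fails_chromatographic_axis(self):
        rt_cos, mz_cos = score_fragment(
            chrom(6.0), chrom(6.0 + 3 * 0.25), spectrum(TRIPLET), TRIPLET, precursor_fit()
        )
        assert rt_cos > 0.5
        assert mz_cos < 0.1

    def test_mass_shifted_envelope_fails_spectral_axis(self):
        rt_cos, mz_cos = score_fragment(
            chrom(6.0), chrom(6.0), spectrum(TRIPLET, shift=-1.003), TRIPLET, precursor_fit()
        )
        assert rt_cos < 0.1
        assert mz_cos > 0.25

    def test_scale_invariance_of_both_axes(self):
        base = score_fragment(
            chrom(6.0), chrom(6.0, height=500.0), spectrum(TRIPLET), TRIPLET, precursor_fit()
        )
        scaled = score_fragment(
            chrom(6.0, height=7e5),
            chrom(6.0, height=3.3e4),
            spectrum(TRIPLET, scale=8.8e4),
            TRIPLET,
            precursor_fit(),
        )
        assert scaled == pytest.approx(base, abs=1e-6)

    def test_spectral_cosine_ignores_interpolation_bridges(self):
        # two sparse points far apart must not be linearly bridged
        grid_mz = np.array([TRIPLET.mz[0] - 1.2, TRIPLET.mz[0] + 2.2])
        inten = np.array([100.0, 100.0])
        d = spectral_cosine((grid_mz, inten), TRIPLET, 0.03)
        assert d > 0.9


def make_pair(index, position):
    f = MolecularFormula({"C": 30, "H": 57, "O": 4})
    return OzidFragmentPair(
        DoubleBondSite(0, index, position), f, f + {"O": 1}, 500.0 - position, 516.0 - position, 1
    )


def scores(*comps):
    return FragmentScores(*comps)


class TestAssignmentHeuristic:
    def test_all_components_below_cutoff_accepted(self):
        out = assign("L", "[M+H]+", [(make_pair(1, 9), scores(0.10, 0.08, 0.12, 0.09))])
        assert out[0].decision == "accepted"

    def test_one_component_above_cutoff_rejects_full(self):
        out = assign("L", "[M+H]+", [(make_pair(1, 9), scores(0.30, 0.08, 0.12, 0.09))])
        assert out[0].decision == "partial"
        assert "aldehyde-missing" in out[0].flags

    def test_partial_when_criegee_fails(self):
        out = assign("L", "[M+H]+", [(make_pair(1, 9), scores(0.10, 0.08, 0.60, 0.70))])
        assert out[0].decision == "partial"
        assert "criegee-missing" in out[0].flags

    def test_both_fragments_failing_rejected(self):
        out = assign("L", "[M+H]+", [(make_pair(1, 9), scores(0.60, 0.08, 0.60, 0.70))])
        assert out[0].decision == "rejected"

    def test_nan_components_count_as_failing(self):
        nan = float("nan")
        out = assign("L", "[M+H]+", [(make_pair(1, 9), scores(0.1, 0.1, nan, nan))])
        assert out[0].decision == "partial"

    def test_ranked_by_composite_then_position(self):
        cands = [
            (make_pair(1, 11), scores(0.20, 0.20, 0.20, 0.20)),
            (make_pair(1, 9), scores(0.01, 0.01, 0.01, 0.01)),
            (make_pair(1, 7), scores(0.20, 0.20, 0.20, 0.20)),
        ]
        out = assign("L", "[M+H]+", cands)
        assert [a.position for a in out] == [9, 7, 11]

    def test_empty_candidates_empty_output(self):
        assert assign("L", "[M+H]+", []) == []


class TestComposite:
    def test_mean_of_components(self):
        s = scores(0.1, 0.2, 0.3, 0.4)
        assert composite_score(s) == pytest.approx(0.25)

    def test_missing_fragment_penalty(self):
        nan = float("nan")
        s = scores(0.1, 0.2, nan, nan)
        assert composite_score(s) == pytest.approx(0.15 + 0.5)

    def test_all_missing(self):
        nan = float("nan")
        assert composite_score(scores(nan, nan, nan, nan)) == pytest.approx(1.0 + 1.0)


class TestExport:
    def test_row_conservation_and_roundtrip(self, tmp_path):
        import pandas as pd

        cands = [(make_pair(1, x), scores(0.1, 0.1, 0.1, 0.1)) for x in range(2, 5)]
        cands += [(make_pair(1, x), scores(0.9, 0.9, 0.9, 0.9)) for x in range(5, 17)]
        out = assign("PC(16:0/18:1)", "[M+H]+", cands)
        path = tmp_path / "results.csv"
        df = export_results(out, path, xlsx=True)
        assert len(df) == 15
        back = pd.read_csv(path)
        assert list(back.columns) == list(df.columns)
        assert (back["decision"] == df["decision"]).all()
        assert (tmp_path / "results.xlsx").exists()
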