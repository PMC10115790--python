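"""Double-bond site enumeration and aldehyde/criegee fragment prediction."""

import itertools

import pytest

from ozid.formula import delta_mass, get_adduct
from ozid.fragments import (
    DoubleBondSite,
    EnumerationRules,
    enumerate_sites,
    neutral_loss_delta,
    neutral_loss_mass,
    predict_fragments,
)
from ozid.lipids import AcylChain, parse_target_name, species_formula

O_MASS = 15.994915


def brute_force_sites(carbons: int, d: int, x_min: int = 2, spacing: int = 3):
    """Oracle: enumerate every legal placement of d bonds, collect per-index sets."""
    per_index: dict[int, set[int]] = {i: set() for i in range(1, d + 1)}
    for placement in itertools.combinations(range(x_min, carbons - 1), d):
        if any(b - a < spacing for a, b in zip(placement, placement[1:])):
            continue
        if placement[-1] > carbons - 2:
            continue
        for i, x in enumerate(placement, start=1):
            per_index[i].add(x)
    return per_index


class TestEnumeration:
    def test_monounsaturated_18_carbon(self):
        sites = enumerate_sites(AcylChain(18, 1))
        assert len(sites) == 15
        assert [s.position for s in sites] == list(range(2, 17))
        assert all(s.index == 1 for s in sites)

    def test_triunsaturated_contains_standard_sites(self):
        got = {(s.index, s.position) for s in enumerate_sites(AcylChain(20, 3))}
        assert {(1, 6), (2, 9), (3, 12)} <= got

    def test_saturated_chain_empty(self):
        assert enumerate_sites(AcylChain(16, 0)) == []

    @pytest.mark.parametrize("carbons, d", [(18, 1), (18, 2), (20, 3), (22, 6), (16, 2)])
    def test_matches_brute_force_placement_oracle(self, carbons, d):
        oracle = brute_force_sites(carbons, d)
        got: dict[int, set[int]] = {i: set() for i in range(1, d + 1)}
        for s in enumerate_sites(AcylChain(carbons, d)):
            got[s.index].add(s.position)
        assert got == oracle

    def test_conjugated_spacing_widens_ranges(self):
        strict = enumerate_sites(AcylChain(18, 2))
        conj = enumerate_sites(AcylChain(18, 2), rules=EnumerationRules(min_spacing=2))
        assert len(conj) > len(strict)

    def test_sorted_and_deterministic(self):
        sites = enumerate_sites(AcylChain(22, 4))
        keys = [(s.index, s.position) for s in sites]
        assert keys == sorted(keys)
        assert sites == enumerate_sites(AcylChain(22, 4))


class TestNeutralLoss:
    def test_n9_aldehyde_is_octadienyl_loss(self):
        # canonical n-9 diagnostic: loss of C8H14 (110.11 Da)
        delta = neutral_loss_delta(DoubleBondSite(0, 1, 9), "aldehyde")
        assert delta == {"C": 8, "H": 14}
        assert delta_mass(delta) == pytest.approx(110.1096, abs=1e-3)

    def test_n9_criegee_is_one_oxygen_lighter(self):
        assert neutral_loss_mass(DoubleBondSite(0, 1, 9), "criegee") == pytest.approx(
            94.1147, abs=1e-3
        )

    def test_structural_hydrogen_count(self):
        # the lost methyl-terminal piece is a C(x-1) hydrocarbon carrying
        # i+1 degrees of unsaturation: H = 2(x-1)+2 - 2(i+1)
        for i in range(1, 4):
            for x in range(2 + 3 * (i - 1), 18):
                delta = neutral_loss_delta(DoubleBondSite(0, i, x), "aldehyde")
                n_c = x - 1
                assert delta["C"] == n_c
                assert delta["H"] == 2 * n_c + 2 - 2 * (i + 1)

    def test_one_ch2_per_position_step(self):
        m1 = neutral_loss_mass(DoubleBondSite(0, 1, 9), "aldehyde")
        m2 = neutral_loss_mass(DoubleBondSite(0, 1, 10), "aldehyde")
        assert m2 - m1 == pytest.approx(14.01565, abs=1e-4)

    def test_impossible_site_raises(self):
        with pytest.raises(ValueError):
            neutral_loss_delta(DoubleBondSite(0, 2, 2), "aldehyde")

    def test_criegee_minus_aldehyde_is_O_everywhere(self):
        for site in enumerate_sites(AcylChain(22, 6)):
            ald = neutral_loss_mass(site, "aldehyde")
            cri = neutral_loss_mass(site, "criegee")
            assert ald - cri == pytest.approx(O_MASS, abs=1e-9)


RANDOM_SPECIES = [
    "PC(16:0/18:1)", "PC(16:0/18:2)", "PC(18:1/18:1)", "PE(16:0/18:1)",
    "PE(18:0/20:4)", "PE(16:0/22:6)", "PG(17:0/20:3)", "PG(16:0/18:1)",
    "PI(18:0/20:4)", "PS(18:0/18:1)", "PA(16:0/18:2)", "DG(16:0/18:1)",
    "TG(16:0/18:1/18:2)", "LPC(18:1)", "LPE(20:4)", "SM(d18:1/16:0)",
    "Cer(d18:1/24:1)", "D5-PG(17:0/20:3)", "D7-PE(15:0/18:1)", "PC(15:0/22:5)",
]


class TestFragmentPairs:
    def test_pg_standard_three_known_pairs(self):
        species = parse_target_name("D5-PG(17:0/20:3)")
        adduct = get_adduct("[M-H]-")
        pairs, _ = predict_fragments(species, adduct)
        known = [p for p in pairs if (p.site.index, p.site.position) in {(1, 6), (2, 9), (3, 12)}]
        assert len(known) == 3
        mzs = {round(v, 4) for p in known for v in (p.aldehyde_mz, p.criegee_mz)}
        assert len(mzs) == 6

    def test_nominal_16_da_pair_gap(self):
        species = parse_target_name("PC(16:0/18:1)")
        pairs, _ = predict_fragments(species, get_adduct("[M+H]+"))
        for p in pairs:
            assert round(p.criegee_mz) - round(p.aldehyde_mz) == 16
            assert p.criegee_mz - p.aldehyde_mz == pytest.approx(O_MASS, abs=1e-6)

    @pytest.mark.parametrize("name", RANDOM_SPECIES)
    def test_mass_conservation_all_sites(self, name):
        species = parse_target_name(name)
        adduct = get_adduct("[M-H]-" if name.startswith(("PG", "PE", "PI", "PS", "PA", "D")) else "[M+H]+")
        neutral = species_formula(species)
        ion_mass = adduct.ion_formula(neutral).monoisotopic_mass
        pairs, _ = predict_fragments(species, adduct)
        assert pairs, name
        for p in pairs:
            ald_nl = neutral_loss_mass(p.site, "aldehyde")
            assert p.aldehyde_formula.monoisotopic_mass + ald_nl == pytest.approx(
                ion_mass, abs=1e-6
            )
            assert p.criegee_formula.monoisotopic_mass == pytest.approx(
                p.aldehyde_formula.monoisotopic_mass + O_MASS, abs=1e-9
            )
            assert p.aldehyde_mz < adduct.mz(neutral)

    def test_monotonic_in_position_within_index(self):
        species = parse_target_name("PE(16:0/22:6)")
        pairs, _ = predict_fragments(species, get_adduct("[M-H]-"))
        for idx in range(1, 7):
            mzs = [p.aldehyde_mz for p in pairs if p.site.index == idx]
            assert all(a > b for a, b in zip(mzs, mzs[1:]))

    def test_multichain_sites_enumerated_per_chain(self):
        species = parse_target_name("TG(16:0/18:1/18:2)")
        pairs, _ = predict_fragments(species, get_adduct("[M+NH4]+"))
        chains = {p.site.chain for p in pairs}
        assert chains == {1, 2}

    def test_deuterium_label_stays_on_fragment(self):
        species = parse_target_name("D5-PG(17:0/20:3)")
        pairs, _ = predict_fragments(species, get_adduct("[M-H]-"))
        assert all(p.aldehyde_formula["D"] == 5 for p in pairs)
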