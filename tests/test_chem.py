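"""Composition algebra, exact masses, isotope envelopes, isomer rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from parti.chem import (
    ADENOSINE,
    LEU_ENK,
    PROTON_MASS,
    WATER,
    ChiralityClass,
    ElementComposition,
    Linkage,
    Monomer,
    compose_species,
    expected_isomer_count,
    isotope_envelope,
)

C = ElementComposition.from_formula


class TestElementComposition:
    def test_formula_parse_roundtrip(self):
        assert C("C10H13N5O4").counts == {"C": 10, "H": 13, "N": 5, "O": 4}
        assert C("C10H13N5O4").formula == "C10H13N5O4"
        assert C("H2O").formula == "H2O"

    @pytest.mark.parametrize("bad", ["", "Xx2", "C-1", "10C", "c9h11"])
    def test_malformed_formula_rejected(self, bad):
        with pytest.raises(ValueError):
            C(bad)

    def test_negative_subtraction_is_error(self):
        with pytest.raises(ValueError, match="negative"):
            C("CH4") - C("O")

    comps = st.dictionaries(
        st.sampled_from(["C", "H", "N", "O", "S"]),
        st.integers(min_value=0, max_value=40), min_size=1)

    @settings(max_examples=50, derandomize=True)
    @given(a=comps, b=comps)
    def test_addition_commutes_and_mass_is_additive(self, a, b):
        ca, cb = ElementComposition(a), ElementComposition(b)
        assert (ca + cb).counts == (cb + ca).counts
        assert (ca + cb).monoisotopic_mass == pytest.approx(
            ca.monoisotopic_mass + cb.monoisotopic_mass, abs=1e-9)

    def test_scalar_multiplication_matches_repeated_addition(self):
        m = C("C11H22N2O4")
        assert (2 * m).counts == (m + m).counts


class TestComposeSpecies:
    def test_bare_adenosine_identity(self):
        sp = compose_species(None, 0)
        assert sp.composition.counts == ADENOSINE.counts
        assert sp.name == "Ade"

    def test_monoacyl_condensation(self, monomers):
        sp = compose_species(monomers["Phe"], 1)
        assert sp.composition.formula == "C19H22N6O5"

    def test_diacyl_condensation_by_hand_sum(self, monomers):
        # adenosine + 2xBocK - 2xH2O, summed element-wise by hand
        sp = compose_species(monomers["BocK"], 2)
        assert sp.composition.formula == "C32H53N9O10"
        assert sp.name == "di-BocK-Ade"

    def test_acyl_count_domain(self, monomers):
        with pytest.raises(ValueError):
            compose_species(monomers["Phe"], 3)
        with pytest.raises(ValueError):
            compose_species(None, 1)

    def test_monomer_needs_carboxylate(self):
        with pytest.raises(ValueError, match="carboxylate"):
            Monomer("bogus", C("C2H6O"), Linkage.AMIDE, ChiralityClass.CHIRAL)


class TestProtonatedMz:
    # all printed [M+H]+ caption values, 4 dp
    PRINTED = [
        ("Phe", 1, 415.1724), ("BocK", 1, 496.2514), ("N-Me-BocK", 1, 510.2671),
        ("m-Br-Phe", 1, 493.0830), ("m-CF3-bma", 1, 512.1388),
        ("m-Br-bma", 1, 522.0619), ("m-CH3-bma", 1, 458.1670),
    ]

    @pytest.mark.parametrize("name,count,printed", PRINTED)
    def test_printed_masses(self, monomers, name, count, printed):
        assert compose_species(monomers[name], count).protonated_mz == pytest.approx(
            printed, abs=1e-3)

    def test_leu_enk_and_free_adenosine(self):
        assert LEU_ENK.protonated_mz == pytest.approx(556.2766, abs=1e-3)
        # independent atomic-mass summation gives 268.1040 for C10H13N5O4 + H+
        assert compose_species(None, 0).protonated_mz == pytest.approx(
            268.1040, abs=1e-3)

    def test_mass_additivity_mono_to_di(self, monomers):
        # di - mono = monomer - water, exactly, for every monomer
        for m in monomers.values():
            mono = compose_species(m, 1).protonated_mz
            dia = compose_species(m, 2).protonated_mz
            expected = m.composition.monoisotopic_mass - WATER.monoisotopic_mass
            assert dia - mono == pytest.approx(expected, abs=1e-9)

    def test_n_methylation_shift_is_one_ch2_per_acyl(self, monomers):
        ch2 = C("CH2").monoisotopic_mass
        for count in (1, 2):
            d = (compose_species(monomers["N-Me-BocK"], count).protonated_mz
                 - compose_species(monomers["BocK"], count).protonated_mz)
            assert d == pytest.approx(count * ch2, abs=1e-4)
        assert ch2 == pytest.approx(14.01565, abs=1e-4)


class TestIsotopeEnvelope:
    def test_single_carbon_base_case(self):
        env = isotope_envelope(C("C"), n_peaks=2)
        total = 0.9893 + 0.0107
        assert env.abundance_at(0) == pytest.approx(0.9893 / total, abs=1e-6)
        assert env.abundance_at(1) == pytest.approx(0.0107 / total, abs=1e-6)

    def test_water_is_nearly_monoisotopic(self):
        assert isotope_envelope(C("H2O")).abundance_at(0) > 0.997

    def test_adenosine_m1_ratio_against_polynomial_oracle(self):
        # brute-force polynomial expansion over all isotopologues
        def brute(counts):
            dists = {"C": [0.9893, 0.0107], "H": [0.999885, 0.000115],
                     "N": [0.99636, 0.00364], "O": [0.99757, 0.00038, 0.00205]}
            poly = [1.0]
            for el, n in counts.items():
                for _ in range(n):
                    d = dists[el]
                    new = [0.0] * (len(poly) + len(d) - 1)
                    for i, a in enumerate(poly):
                        for j, b in enumerate(d):
                            new[i + j] += a * b
                    poly = new
            return poly
        oracle = brute({"C": 10, "H": 13, "N": 5, "O": 4})
        env = isotope_envelope(ADENOSINE, n_peaks=4)
        assert env.m1_over_m0 == pytest.approx(oracle[1] / oracle[0], rel=1e-9)
        assert env.m1_over_m0 == pytest.approx(0.125, abs=0.005)

    def test_bromine_shifts_weight_to_m2(self, monomers):
        env = isotope_envelope(compose_species(monomers["m-Br-Phe"], 1).composition)
        assert env.abundance_at(2) > env.abundance_at(1)

    @settings(max_examples=30, derandomize=True)
    @given(st.dictionaries(st.sampled_from(["C", "H", "N", "O", "S", "Br"]),
                           st.integers(min_value=1, max_value=30), min_size=1))
    def test_envelope_normalized(self, counts):
        env = isotope_envelope(ElementComposition(counts))
        assert sum(env.abundances) == pytest.approx(1.0, abs=1e-9)
        assert env.offsets[0] == 0

    def test_monoisotopic_composition_is_single_line(self):
        env = isotope_envelope(C("F6P2"), n_peaks=4)
        assert env.abundance_at(0) == pytest.approx(1.0)


class TestIsomerCount:
    def test_rules(self, monomers):
        assert expected_isomer_count(compose_species(None, 0)) == (1, 1)
        assert expected_isomer_count(compose_species(monomers["Phe"], 1)) == (1, 2)
        assert expected_isomer_count(
            compose_species(monomers["m-CF3-bma"], 1)) == (1, 4)
        assert expected_isomer_count(
            compose_species(monomers["R-b2-OH-BocK"], 2)) == (1, 1)
        assert expected_isomer_count(LEU_ENK) == (1, 1)


def test_registry_contents(registry):
    monomers, standards = registry
    assert set(monomers) >= {"Phe", "BocK", "N-Me-BocK", "OH-BocK",
                             "R-b2-OH-BocK", "S-b2-OH-BocK", "m-Br-Phe",
                             "m-CF3-bma", "m-Br-bma", "m-CH3-bma"}
    assert monomers["N-Me-BocK"].n_alkylated
    assert monomers["m-Br-bma"].chirality_class is ChiralityClass.PROCHIRAL
    assert standards["Leu-Enk"].composition.formula == "C28H37N5O7"
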