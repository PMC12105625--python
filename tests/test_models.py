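"""The M1-M4 potential models, speciation and pathway selection."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from redoxph.constants import PhysicalConstants
from redoxph.models import (
    AcidBaseSpec,
    RedoxCouple,
    m1_potential,
    m2_potential,
    m3_potential,
    m4_potential,
    mole_fractions,
    neutralization_term,
    pka_to_delta_g,
    prototropic_correction,
    select_pathway,
    speciation_curve,
)

SHE = PhysicalConstants(reference="SHE")
SCE = PhysicalConstants(reference="SCE")
NERNST = SHE.nernst_volt  # RT/F at 298.15 K


class TestAcidityConversions:
    def test_pka_zero_gives_zero(self):
        assert pka_to_delta_g(0.0) == 0.0

    def test_one_pka_unit_costs_5p708_kjmol(self):
        assert pka_to_delta_g(1.0) == pytest.approx(5.708, abs=1e-3)

    def test_linearity_in_pka(self):
        assert pka_to_delta_g(-1.0) == pytest.approx(-pka_to_delta_g(1.0))


class TestMoleFractions:
    def test_midpoint(self):
        x = mole_fractions(7.0, 7.0)
        assert x.x_rh == pytest.approx(0.5)
        assert x.x_r_minus == pytest.approx(0.5)

    @pytest.mark.parametrize("ph,pka,expected", [(7.0, 7.5, 0.76), (9.0, 8.9, 0.44)])
    def test_published_speciation_points(self, ph, pka, expected):
        assert round(mole_fractions(ph, pka).x_rh, 2) == expected

    @settings(derandomize=True, max_examples=50)
    @given(ph=st.floats(1, 13), pka=st.floats(2, 12), d=st.floats(0.01, 2))
    def test_monotonicity_and_normalization(self, ph, pka, d):
        x = mole_fractions(ph, pka)
        assert x.x_rh + x.x_r_minus == pytest.approx(1.0, abs=1e-12)
        assert mole_fractions(ph + d, pka).x_rh < x.x_rh  # decreasing in pH
        assert mole_fractions(ph, pka + d).x_rh > x.x_rh  # increasing in pKa


class TestM1:
    @pytest.mark.parametrize(
        "dg,constants,expected",
        [(5.721, SHE, 1.44), (4.281, SHE, 0.0), (5.679, SCE, 1.25)],
    )
    def test_reference_subtraction(self, dg, constants, expected):
        assert m1_potential(dg, constants).E == pytest.approx(expected, abs=1e-9)


class TestM2:
    def couple(self, e_neutral, e_deprot, pka):
        return RedoxCouple(
            dg_ie_neutral_ev=e_neutral + 4.281,
            dg_ie_deprotonated_ev=e_deprot + 4.281,
            acid_base=AcidBaseSpec.from_pka(pka_reduced_0=pka),
        )

    def test_high_pka_limit_equals_m1_neutral(self):
        c = self.couple(1.89, 0.92, pka=13.0)
        assert m2_potential(c, 7.0).E == pytest.approx(1.89, abs=1e-5)

    @pytest.mark.parametrize(
        "e_pair,pka,ph,expected",
        [
            # xanthine-like couple at pH 7 and hypoxanthine-like at pH 9,
            # recomposed from rounded published components
            ((1.89, 0.92), 7.5, 7.0, 1.66),
            ((2.04, 1.14), 8.9, 9.0, 1.54),
        ],
    )
    def test_published_mole_fraction_averages(self, e_pair, pka, ph, expected):
        c = self.couple(*e_pair, pka=pka)
        assert m2_potential(c, ph).E == pytest.approx(expected, abs=0.01)

    def test_m2_bounded_by_pathway_potentials(self):
        c = self.couple(1.9, 0.9, pka=8.0)
        for ph in np.linspace(0, 14, 15):
            assert 0.9 - 1e-12 <= m2_potential(c, ph).E <= 1.9 + 1e-12

    def test_missing_deprotonated_pathway_rejected_when_needed(self):
        c = RedoxCouple(
            dg_ie_neutral_ev=6.0,
            acid_base=AcidBaseSpec.from_pka(pka_reduced_0=5.0),
        )
        with pytest.raises(ValueError, match="deprotonated"):
            m2_potential(c, 7.0)


class TestM3:
    def test_equal_ka_collapses_to_standard_potential(self):
        ab = AcidBaseSpec(ka_oxidized_plus1=1e-5, ka_reduced_0=1e-5)
        assert m3_potential(1.0, ab, 7.0).E == pytest.approx(1.0)

    def test_literal_ka_worked_example(self):
        # radical cation with Ka = 1 vs non-acidic parent (Ka = 0) at pH 7
        ab = AcidBaseSpec(ka_oxidized_plus1=1.0, ka_reduced_0=0.0)
        corr = prototropic_correction(ab, 7.0)
        assert round(corr, 2) == -0.41

    def test_correction_negative_when_cation_more_acidic(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            ka_red = 10.0 ** rng.uniform(-14, -2)
            ka_ox = ka_red * 10.0 ** rng.uniform(0.1, 6)
            ab = AcidBaseSpec(ka_oxidized_plus1=ka_ox, ka_reduced_0=ka_red)
            assert prototropic_correction(ab, rng.uniform(0, 14)) < 0


class TestM4:
    def test_equal_ka_collapses_to_standard_potential(self):
        ab = AcidBaseSpec(ka_oxidized_plus1=1e-6, ka_reduced_0=1e-6)
        assert m4_potential(1.0, ab, 7.0).E == pytest.approx(1.0)

    def test_non_acidic_reduced_molecule_rejected(self):
        ab = AcidBaseSpec(ka_oxidized_plus1=1.0, ka_reduced_0=0.0)
        with pytest.raises(ValueError, match="M3"):
            m4_potential(1.0, ab, 7.0)

    @settings(derandomize=True, max_examples=100)
    @given(
        pka_ox=st.floats(-2, 12),
        dpka=st.floats(0, 10),
        ph=st.floats(0, 14),
        e0=st.floats(-1, 3),
    )
    def test_m4_minus_m3_algebraic_identity(self, pka_ox, dpka, ph, e0):
        ab = AcidBaseSpec.from_pka(
            pka_oxidized_plus1=pka_ox, pka_reduced_0=pka_ox + dpka
        )
        m3 = m3_potential(e0, ab, ph).E
        m4 = m4_potential(e0, ab, ph).E
        expected = neutralization_term(
            ab.ka_oxidized_plus1, ab.ka_reduced_0
        ) + prototropic_correction(ab, ph)
        assert m4 - m3 == pytest.approx(expected, abs=1e-12)

    def test_same_correction_preserves_pathway_difference(self):
        # the strongly acidic carboxy derivative: neutral vs deprotonated
        # standard potentials move in lockstep under the same M4 correction
        ab = AcidBaseSpec.from_pka(pka_oxidized_plus1=2.0, pka_reduced_0=4.28)
        e_neutral, e_deprot = 2.59, 2.06
        diff = m4_potential(e_deprot, ab, 7.0).E - m4_potential(e_neutral, ab, 7.0).E
        assert diff == pytest.approx(-0.53, abs=1e-12)


class TestNeutralizationTerm:
    def test_equal_ka_gives_zero(self):
        assert neutralization_term(1e-5, 1e-5) == 0.0

    def test_one_pka_unit_gap(self):
        assert neutralization_term(1e-4, 1e-5) == pytest.approx(
            NERNST * math.log(10), abs=1e-12
        )
        assert neutralization_term(1e-4, 1e-5) == pytest.approx(0.0592, abs=1e-4)

    def test_positive_when_cation_more_acidic(self):
        assert neutralization_term(1e-3, 1e-9) > 0

    def test_non_positive_ka_rejected(self):
        with pytest.raises(ValueError):
            neutralization_term(0.0, 1e-5)


class TestSelectPathway:
    def couple(self, pka):
        return RedoxCouple(
            dg_ie_neutral_ev=6.0,
            dg_ie_deprotonated_ev=5.5,
            acid_base=AcidBaseSpec.from_pka(pka_reduced_0=pka),
        )

    def test_carboxylic_acid_fully_ionized_at_ph7(self):
        assert select_pathway(self.couple(4.28), 7.0) == "deprotonated"

    def test_weak_acid_stays_neutral(self):
        assert select_pathway(self.couple(12.2), 7.0) == "neutral"

    def test_tie_goes_to_neutral(self):
        assert select_pathway(self.couple(7.0), 7.0) == "neutral"


class TestSpeciationCurve:
    def couple(self):
        return RedoxCouple(
            dg_ie_neutral_ev=6.0,
            dg_ie_deprotonated_ev=5.5,
            acid_base=AcidBaseSpec.from_pka(
                pka_oxidized_plus1=3.0, pka_reduced_0=9.0
            ),
        )

    def test_single_point_matches_model_call(self):
        c = self.couple()
        curve = speciation_curve(c, 1.2, "M3", [7.0])
        assert curve.shape[0] == 1
        assert curve["E_volts"].iloc[0] == pytest.approx(
            m3_potential(1.2, c.acid_base, 7.0).E
        )

    def test_low_ph_limit_returns_standard_potential(self):
        c = RedoxCouple(
            dg_ie_neutral_ev=6.0,
            acid_base=AcidBaseSpec.from_pka(
                pka_oxidized_plus1=6.0, pka_reduced_0=9.0
            ),
        )
        curve = speciation_curve(c, 1.2, "M3", [0.0])
        assert curve["E_volts"].iloc[0] == pytest.approx(1.2, abs=1e-3)

    def test_monotone_non_increasing_when_cation_more_acidic(self):
        curve = speciation_curve(self.couple(), 1.2, "M3", np.linspace(0, 14, 141))
        assert (np.diff(curve["E_volts"]) <= 1e-12).all()

    def test_high_ph_limit_of_m3(self):
        c = self.couple()
        curve = speciation_curve(c, 1.2, "M3", [14.0])
        limit = 1.2 + NERNST * math.log(
            c.acid_base.ka_reduced_0 / c.acid_base.ka_oxidized_plus1
        )
        assert curve["E_volts"].iloc[0] == pytest.approx(limit, abs=1e-3)

    def test_descending_grid_rejected(self):
        with pytest.raises(ValueError, match="ascending"):
            speciation_curve(self.couple(), 1.2, "M3", [7.0, 6.0])


class TestRedoxCoupleInvariant:
    def test_deprotonated_pathway_cannot_cost_more(self):
        with pytest.raises(ValueError, match="deprotonated pathway"):
            RedoxCouple(dg_ie_neutral_ev=5.0, dg_ie_deprotonated_ev=5.5)
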