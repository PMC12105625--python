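"""Synthetic-system generators, ground-truth recovery, packaged fixtures."""
import numpy as np
import pytest

from redoxph.models import (
    m1_potential,
    m2_potential,
    m3_potential,
    m4_potential,
)
from redoxph.constants import PhysicalConstants
from redoxph.synthetic import (
    FIXTURE_TABLES,
    SyntheticSystemSpec,
    fixture_metadata,
    generate_ensemble,
    generate_redox_couple,
    generate_species_table,
    load_fixture,
    parse_censored,
)

SHE = PhysicalConstants(reference="SHE")


class TestGenerateEnsemble:
    def test_single_conformer_no_noise_is_the_base_energy(self):
        spec = SyntheticSystemSpec(
            seed=1, n_tautomers=1, n_conformers_per_tautomer=1,
            conformer_spread=0.0, noise_sd=0.0,
        )
        ens = generate_ensemble(spec)
        assert len(ens.records) == 1
        assert ens.g_sol_ensemble == ens.records[0].g_sol

    def test_zero_spread_gives_degenerate_uniform_weights(self):
        spec = SyntheticSystemSpec(seed=2, conformer_spread=0.0, noise_sd=0.0)
        ens = generate_ensemble(spec)
        n = len(ens.records)
        assert ens.weights == pytest.approx([1.0 / n] * n)

    def test_deterministic_under_fixed_seed(self):
        spec = SyntheticSystemSpec(seed=3, conformer_spread=5.0)
        a = generate_ensemble(spec)
        b = generate_ensemble(spec)
        assert [r.g_sol for r in a.records] == [r.g_sol for r in b.records]

    def test_distinct_seeds_give_distinct_ensembles(self):
        a = generate_ensemble(SyntheticSystemSpec(seed=4, conformer_spread=5.0))
        b = generate_ensemble(SyntheticSystemSpec(seed=5, conformer_spread=5.0))
        assert [r.g_sol for r in a.records] != [r.g_sol for r in b.records]

    def test_offsets_bounded_by_spread(self):
        spec = SyntheticSystemSpec(seed=6, conformer_spread=4.0, noise_sd=0.0,
                                   n_tautomers=5, n_conformers_per_tautomer=10)
        ens = generate_ensemble(spec)
        gs = np.array([r.g_sol for r in ens.records])
        assert (gs - gs.min() <= 4.0 + 1e-12).all()


class TestGenerateRedoxCouple:
    def test_noiseless_m1_recovers_truth_exactly(self):
        spec = SyntheticSystemSpec(seed=1, true_e_standard=1.37, noise_sd=0.0)
        couple, truth = generate_redox_couple(spec)
        assert m1_potential(couple.dg_ie_neutral_ev, SHE).E == pytest.approx(
            1.37, abs=1e-12
        )
        assert truth.e_standard_neutral == 1.37

    def test_noiseless_model_corrections_match_closed_forms(self):
        spec = SyntheticSystemSpec(
            seed=1, true_e_standard=1.50, pka_ladder=(9.5,),
            radical_acidity_shift=6.0, noise_sd=0.0,
        )
        couple, truth = generate_redox_couple(spec)
        e0 = truth.e_standard_neutral
        assert m2_potential(couple, 7.0).E == pytest.approx(
            mole_frac_avg(couple, 7.0), abs=1e-10
        )
        m3 = m3_potential(e0, couple.acid_base, 7.0).E
        m4 = m4_potential(e0, couple.acid_base, 7.0).E
        assert np.isfinite([m3, m4]).all()
        assert m3 < e0  # cation more acidic -> negative correction

    def test_degenerate_shift_collapses_m3_m4_onto_m1(self):
        spec = SyntheticSystemSpec(
            seed=1, true_e_standard=1.2, radical_acidity_shift=0.0, noise_sd=0.0
        )
        couple, truth = generate_redox_couple(spec)
        e0 = truth.e_standard_neutral
        assert m3_potential(e0, couple.acid_base, 7.0).E == pytest.approx(e0, abs=1e-12)
        assert m4_potential(e0, couple.acid_base, 7.0).E == pytest.approx(e0, abs=1e-12)

    def test_decreasing_pka_ladder_rejected(self):
        with pytest.raises(ValueError, match="non-decreasing"):
            SyntheticSystemSpec(pka_ladder=(9.5, 4.0))

    def test_monte_carlo_recovery_unbiased(self):
        # 500 noisy replicates: the mean recovered potential stays within
        # 3 standard errors of the ground truth
        truth_e, noise_sd, n = 1.50, 2.0, 500
        recovered = np.empty(n)
        for i in range(n):
            spec = SyntheticSystemSpec(
                seed=i, true_e_standard=truth_e, noise_sd=noise_sd
            )
            couple, _ = generate_redox_couple(spec)
            recovered[i] = m1_potential(couple.dg_ie_neutral_ev, SHE).E
        sem = recovered.std(ddof=1) / np.sqrt(n)
        assert abs(recovered.mean() - truth_e) < 3 * sem


def mole_frac_avg(couple, ph):
    """Independent closed-form M2: Henderson-Hasselbalch weights applied to
    the two pathway potentials."""
    from redoxph.models import ka_to_pka

    pka = ka_to_pka(couple.acid_base.ka_reduced_0)
    x_rh = 1.0 / (1.0 + 10.0 ** (ph - pka))
    e_n = couple.dg_ie_neutral_ev - 4.281
    e_d = couple.dg_ie_deprotonated_ev - 4.281
    return x_rh * e_n + (1 - x_rh) * e_d


class TestSpeciesTable:
    def test_round_trips_through_gsol_assembly(self, tmp_path):
        from redoxph.fileio import read_species_energies

        spec = SyntheticSystemSpec(seed=9, conformer_spread=3.0)
        table = generate_species_table(spec)
        path = tmp_path / "species.csv"
        table.to_csv(path, index=False)
        ensembles = read_species_energies(path)
        direct = generate_ensemble(spec, "reduced", "neutral")
        key = ("synthetic", "reduced", 0)
        assert ensembles[key].g_sol_ensemble == pytest.approx(
            direct.g_sol_ensemble, abs=1e-8
        )


class TestFixtures:
    def test_all_tables_load(self):
        for name in FIXTURE_TABLES:
            df = load_fixture(name)
            assert not df.empty
            assert "compound" in df.columns
            assert fixture_metadata(name)["title"]

    def test_unknown_fixture_rejected(self):
        with pytest.raises(ValueError, match="unknown fixture"):
            load_fixture("table7")

    def test_known_reference_values(self):
        t1 = load_fixture("table1").set_index("abbrev")
        assert float(t1.loc["C", "pKa_zero_r"]) == 12.2
        t5 = load_fixture("table5").set_index("compound")
        assert float(t5.loc["5caC", "M1_SMD_CBS_H2O"]) == 2.59
        t6 = load_fixture("table6").set_index("compound")
        assert float(t6.loc["C", "SMD_CBS_H2O"]) == 1.44
        assert float(t6.loc["U", "SMD_CBS_H2O"]) == 1.34
        assert bool(t6.loc["C", "is_anchor"]) and bool(t6.loc["U", "is_anchor"])

    def test_censored_entries_preserved_and_parsed(self):
        t2 = load_fixture("table2")
        u = t2.set_index("compound").loc["U", "Eac_exp"]
        assert u == ">2.15"
        vals, flags = parse_censored([u, 1.72, None])
        assert vals[0] == 2.15 and flags[0] == "lower_bound"
        assert vals[1] == 1.72 and flags[1] == "exact"

    def test_fixture_round_trip(self, tmp_path):
        import pandas as pd

        df = load_fixture("table5")
        path = tmp_path / "t5.csv"
        df.to_csv(path, index=False)
        again = pd.read_csv(path)
        pd.testing.assert_frame_equal(df, again)
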