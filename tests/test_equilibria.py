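"""Equilibrium solvers, species concentrations, and exchange matrices."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from titrshape import (
    FourStateModel,
    InvalidInputError,
    ThreeStateModel,
    TitrationPoint,
    TwoStateModel,
    exchange_matrix,
    solve_free_ligand,
    species_concentrations,
)
from titrshape.equilibria import ligand_stoichiometry

from conftest import bisection_free_ligand, random_models

# frozen oracle values (quadratic formula / bisection, computed independently)
L_2STATE_300_300_KD10 = 50.0              # root of L² + 10L − 3000 = 0
L_3STATE_KEQ1 = (-5.0 + np.sqrt(6025.0)) / 2.0   # root of 2L² + 10L − 3000 = 0


class TestFreeLigand:
    def test_no_ligand_gives_zero(self):
        pt = TitrationPoint(300.0, 0.0)
        assert solve_free_ligand(pt, TwoStateModel(kd=10.0)) == 0.0
        assert solve_free_ligand(pt, ThreeStateModel(kd=10.0, keq=1.0)) == 0.0
        assert solve_free_ligand(
            pt, FourStateModel(kd_a1=10.0, kd_b1=10.0, kd_a2=10.0)) == 0.0

    def test_vanishing_protein_leaves_ligand_free(self):
        pt = TitrationPoint(1e-9, 100.0)
        ell = solve_free_ligand(pt, TwoStateModel(kd=10.0))
        assert ell == pytest.approx(100.0, rel=1e-6)

    def test_two_state_quadratic_oracle(self):
        ell = solve_free_ligand(TitrationPoint(300.0, 300.0), TwoStateModel(kd=10.0))
        assert ell == pytest.approx(L_2STATE_300_300_KD10, rel=1e-12)

    def test_three_state_quadratic_oracle(self):
        ell = solve_free_ligand(TitrationPoint(300.0, 300.0),
                                ThreeStateModel(kd=10.0, keq=1.0))
        assert ell == pytest.approx(L_3STATE_KEQ1, rel=1e-12)

    def test_three_state_reduces_to_two_state_at_large_keq(self):
        ell = solve_free_ligand(TitrationPoint(300.0, 300.0),
                                ThreeStateModel(kd=10.0, keq=1e9))
        assert ell == pytest.approx(L_2STATE_300_300_KD10, rel=1e-6)

    def test_four_state_reduces_to_two_state_when_b_site_disabled(self):
        model = FourStateModel(kd_a1=10.0, kd_b1=1e12, kd_a2=1e12)
        ell = solve_free_ligand(TitrationPoint(300.0, 300.0), model)
        assert ell == pytest.approx(L_2STATE_300_300_KD10, rel=1e-6)

    def test_four_state_matches_bisection_oracle(self):
        model = FourStateModel(kd_a1=10.0, kd_b1=10.0, kd_a2=10.0)
        ell = solve_free_ligand(TitrationPoint(300.0, 300.0), model)
        oracle = bisection_free_ligand(300.0, 300.0, model)
        assert ell == pytest.approx(oracle, rel=1e-8)

    def test_result_never_exceeds_ltotal(self):
        ell = solve_free_ligand(TitrationPoint(1.0, 900.0), TwoStateModel(kd=1e-3))
        assert 0.0 <= ell <= 900.0

    def test_rejects_nonfinite_and_nonpositive_inputs(self):
        with pytest.raises(InvalidInputError):
            TwoStateModel(kd=np.nan)
        with pytest.raises(InvalidInputError):
            TwoStateModel(kd=-1.0)
        with pytest.raises(InvalidInputError):
            TitrationPoint(0.0, 100.0)
        with pytest.raises(InvalidInputError):
            TitrationPoint(300.0, -5.0)


class TestSpecies:
    def test_two_state_worked_example(self):
        st_ = species_concentrations(TitrationPoint(300.0, 300.0), TwoStateModel(kd=10.0))
        assert st_["P"] == pytest.approx(50.0, rel=1e-12)
        assert st_["PL"] == pytest.approx(250.0, rel=1e-12)
        assert st_.free_ligand == pytest.approx(50.0, rel=1e-12)

    def test_apo_point_is_pure_free_protein(self):
        for model in (TwoStateModel(kd=10.0),
                      ThreeStateModel(kd=10.0, keq=2.0),
                      FourStateModel(kd_a1=10.0, kd_b1=20.0, kd_a2=5.0)):
            st_ = species_concentrations(TitrationPoint(300.0, 0.0), model)
            assert st_["P"] == pytest.approx(300.0)
            assert st_.concentrations[1:] == pytest.approx(0.0)

    def test_three_state_keq_ratio_is_exact(self):
        model = ThreeStateModel(kd=10.0, keq=3.5)
        st_ = species_concentrations(TitrationPoint(300.0, 900.0), model)
        assert st_["PL"] / st_["P'L"] == pytest.approx(3.5, rel=1e-12)

    def test_four_state_symmetric_sites_give_equal_singly_bound(self):
        model = FourStateModel(kd_a1=10.0, kd_b1=10.0, kd_a2=25.0)
        st_ = species_concentrations(TitrationPoint(300.0, 400.0), model)
        assert st_["PL"] == pytest.approx(st_["LP"], rel=1e-12)

    @pytest.mark.parametrize("kind", ["2state", "3state", "4state"])
    def test_mass_conservation_random_draws(self, kind):
        """Protein and ligand balances hold to 1e-9 relative over random models."""
        rng = np.random.default_rng(42)
        for ptotal, ltotal, model in random_models(rng, kind, 200):
            st_ = species_concentrations(TitrationPoint(ptotal, ltotal), model)
            assert np.all(st_.concentrations >= 0)
            p_sum = st_.concentrations.sum()
            l_sum = st_.free_ligand + st_.concentrations @ ligand_stoichiometry(model)
            assert p_sum == pytest.approx(ptotal, rel=1e-9)
            assert l_sum == pytest.approx(ltotal, rel=1e-9, abs=1e-9 * ptotal)

    @pytest.mark.parametrize("kind", ["2state", "3state", "4state"])
    def test_solver_matches_bisection_oracle(self, kind):
        """Analytic [L] agrees with bracketed bisection to 1e-8 relative."""
        rng = np.random.default_rng(7)
        for ptotal, ltotal, model in random_models(rng, kind, 1000):
            ell = solve_free_ligand(TitrationPoint(ptotal, ltotal), model)
            oracle = bisection_free_ligand(ptotal, ltotal, model)
            assert abs(ell - oracle) <= 1e-8 * max(oracle, 1e-6 * max(ltotal, 1e-30))

    def test_model_nesting_three_to_two_state(self):
        two = species_concentrations(TitrationPoint(300.0, 450.0), TwoStateModel(kd=10.0))
        three = species_concentrations(TitrationPoint(300.0, 450.0),
                                       ThreeStateModel(kd=10.0, keq=1e6))
        assert three["P"] == pytest.approx(two["P"], rel=1e-4)
        assert three["PL"] == pytest.approx(two["PL"], rel=1e-4)

    def test_model_nesting_four_to_two_state(self):
        two = species_concentrations(TitrationPoint(300.0, 450.0), TwoStateModel(kd=10.0))
        four = species_concentrations(
            TitrationPoint(300.0, 450.0),
            FourStateModel(kd_a1=10.0, kd_b1=1e9, kd_a2=1e9))
        assert four["P"] == pytest.approx(two["P"], rel=1e-4)
        assert four["PL"] == pytest.approx(two["PL"], rel=1e-4)

    @given(ptotal=st.floats(1.0, 1e4), ratio=st.floats(0.0, 5.0),
           kd=st.floats(1e-2, 1e4), keq=st.floats(1e-2, 1e2))
    @settings(max_examples=100, deadline=None)
    def test_three_state_mass_balance_property(self, ptotal, ratio, kd, keq):
        model = ThreeStateModel(kd=kd, keq=keq)
        st_ = species_concentrations(TitrationPoint(ptotal, ratio * ptotal), model)
        assert st_.concentrations.sum() == pytest.approx(ptotal, rel=1e-9)


class TestExchangeMatrix:
    def test_two_state_hand_evaluated(self):
        # [L]=50, kon=0.5 µM⁻¹s⁻¹ (koff=5, KD=10) -> [[-25, 5], [25, -5]]
        model = TwoStateModel(kd=10.0, koff=5.0)
        st_ = species_concentrations(TitrationPoint(300.0, 300.0), model)
        k = exchange_matrix(model, st_)
        assert k == pytest.approx(np.array([[-25.0, 5.0], [25.0, -5.0]]))

    @pytest.mark.parametrize("kind", ["2state", "3state", "4state"])
    def test_zero_column_sums_and_stationarity(self, kind):
        rng = np.random.default_rng(11)
        for ptotal, ltotal, model in random_models(rng, kind, 100):
            st_ = species_concentrations(TitrationPoint(ptotal, ltotal), model)
            k = exchange_matrix(model, st_)
            assert k.sum(axis=0) == pytest.approx(np.zeros(k.shape[0]), abs=1e-9 * max(
                1.0, np.abs(k).max()))
            flux = k @ st_.concentrations
            assert np.abs(flux).max() <= 1e-9 * max(
                1.0, np.abs(k).max()) * np.abs(st_.concentrations).max() + 1e-12

    def test_dimension_mismatch_rejected(self):
        model = TwoStateModel(kd=10.0, koff=5.0)
        st3 = species_concentrations(TitrationPoint(300.0, 300.0),
                                     ThreeStateModel(kd=10.0, keq=1.0))
        with pytest.raises(InvalidInputError):
            exchange_matrix(model, st3)

    def test_derived_rates(self):
        m = FourStateModel(kd_a1=10.0, kd_b1=20.0, kd_a2=5.0,
                           koff_a1=8.0, koff_b1=6.0, koff_a2=4.0, koff_b2=2.0)
        assert m.kd_b2 == pytest.approx(20.0 * 5.0 / 10.0)
        assert m.kon_a1 == pytest.approx(0.8)
        assert m.kon_b2 == pytest.approx(2.0 / m.kd_b2)
        assert ThreeStateModel(kd=10.0, keq=2.0, koff=6.0, krev=4.0).kfwd == pytest.approx(2.0)
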