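"""Fitting pipeline: normalization, pre-fit, objective, recovery, MC CIs."""

import numpy as np
import pytest

from titrshape import (
    FitConfig,
    InvalidInputError,
    Param,
    SpinParams,
    Spectrum,
    TitrationSeries,
    classify_boundary,
    estimate_spin_params,
    fit_model,
    monte_carlo_ci,
    normalize_series,
    objective,
)
from titrshape.fixtures import (
    four_state_dataset,
    three_state_dataset,
    two_state_dataset,
)

TRUE_2STATE_SPINS = SpinParams.from_linewidths([0.0, 500.0], [100.0, 100.0])
TRUE_3STATE_SPINS = SpinParams.from_linewidths([0.0, 500.0, 1000.0], [100.0] * 3)
TRUE_4STATE_SPINS = SpinParams.from_linewidths([0.0, 400.0, 600.0, 1000.0], [100.0] * 4)


def _affine(series, a, b):
    spectra = [Spectrum(s.freq, a * s.intensity + b, resonance=s.resonance,
                        titration_index=s.titration_index, ptotal=s.ptotal,
                        ltotal=s.ltotal) for s in series.spectra]
    return TitrationSeries(series.ptotal, series.ltotals, spectra,
                           resonance=series.resonance, model=series.model,
                           spins=series.spins)


class TestNormalize:
    def test_series_maximum_becomes_one(self):
        series = two_state_dataset(koff=5.0, seed=0, noisy=False)
        scaled = _affine(series, 2.0, 0.0)
        normed = normalize_series(scaled)
        assert normed.max_intensity() == pytest.approx(1.0, rel=1e-12)

    def test_already_normalized_series_unchanged(self):
        series = normalize_series(two_state_dataset(koff=5.0, seed=0, noisy=False))
        again = normalize_series(series)
        for a, b in zip(series.spectra, again.spectra):
            assert a.intensity == pytest.approx(b.intensity, rel=1e-12)

    def test_all_zero_series_rejected(self):
        grid = np.linspace(0, 100, 20)
        series = TitrationSeries(300.0, [0.0], [Spectrum(grid, np.zeros(20))])
        with pytest.raises(InvalidInputError):
            normalize_series(series)


class TestSpinPreFit:
    def test_slow_exchange_endpoints_recovered(self):
        series = two_state_dataset(koff=5.0, seed=1)
        est = estimate_spin_params(normalize_series(series), "2state")
        assert est.spins.omega0[0] == pytest.approx(0.0, abs=5.0)
        assert est.spins.omega0[1] == pytest.approx(500.0, abs=15.0)
        assert est.fixed[0]           # apo state pinned by the pre-fit
        assert not est.fixed[1]       # bound state searched during fitting

    def test_single_point_series_estimates_apo_only(self):
        series = two_state_dataset(koff=5.0, seed=1)
        single = TitrationSeries(series.ptotal, series.ltotals[:1],
                                 series.spectra[:1], resonance="res1")
        est = estimate_spin_params(single, "2state")
        assert est.fixed[0]
        assert est.spins.omega0[0] == pytest.approx(0.0, abs=5.0)

    def test_flat_spectra_leave_all_free_with_warning(self):
        grid = np.linspace(-100, 600, 50)
        spectra = [Spectrum(grid, np.zeros(50), ltotal=lt) for lt in (0.0, 300.0)]
        series = TitrationSeries(300.0, [0.0, 300.0], spectra)
        with pytest.warns(UserWarning, match="pre-fit failed"):
            est = estimate_spin_params(series, "2state")
        assert not est.fixed.any()


class TestObjective:
    def test_zero_at_generating_parameters(self):
        series = two_state_dataset(koff=50.0, seed=0, noisy=False)
        cfg = FitConfig.two_state(spins={"res1": TRUE_2STATE_SPINS}, fix_spins=True)
        sse = objective({"kd": 10.0, "koff": 50.0}, [series], cfg)
        total = sum(float(s.intensity @ s.intensity) for s in series.spectra)
        assert sse < 1e-16 * total

    def test_affine_rescaling_absorbed_by_scale_factors(self):
        series = two_state_dataset(koff=50.0, seed=0, noisy=False)
        cfg = FitConfig.two_state(spins={"res1": TRUE_2STATE_SPINS}, fix_spins=True)
        base = objective({"kd": 10.0, "koff": 50.0}, [series], cfg)
        scaled = _affine(series, 3.0, 0.1)
        cfg_raw = FitConfig.two_state(spins={"res1": TRUE_2STATE_SPINS},
                                      fix_spins=True, normalize=False)
        assert objective({"kd": 10.0, "koff": 50.0}, [scaled], cfg_raw) == pytest.approx(
            base, abs=1e-10)

    def test_additive_over_resonances(self):
        s1 = two_state_dataset(koff=50.0, seed=1, resonance="resA")
        s2 = two_state_dataset(koff=50.0, seed=2, resonance="resB")
        cfg = FitConfig.two_state(
            spins={"resA": TRUE_2STATE_SPINS, "resB": TRUE_2STATE_SPINS},
            fix_spins=True)
        v = {"kd": 12.0, "koff": 70.0}
        both = objective(v, [s1, s2], cfg)
        assert both == pytest.approx(objective(v, [s1], cfg) + objective(v, [s2], cfg),
                                     rel=1e-9)

    def test_wrong_parameters_increase_objective(self):
        series = two_state_dataset(koff=50.0, seed=0, noisy=False)
        cfg = FitConfig.two_state(spins={"res1": TRUE_2STATE_SPINS}, fix_spins=True)
        right = objective({"kd": 10.0, "koff": 50.0}, [series], cfg)
        wrong = objective({"kd": 100.0, "koff": 50.0}, [series], cfg)
        assert wrong > right + 1e-3


class TestRecovery:
    def test_two_state_noise_free_recovery(self):
        series = two_state_dataset(koff=50.0, seed=0, noisy=False)
        cfg = FitConfig.two_state(spins={"res1": TRUE_2STATE_SPINS},
                                  fix_spins=True, n_starts=3, seed=0)
        res = fit_model(series, cfg)
        assert res.params["kd"] == pytest.approx(10.0, rel=0.01)
        assert res.params["koff"] == pytest.approx(50.0, rel=0.01)

    def test_three_state_noise_free_recovery(self):
        series = three_state_dataset(koff=200.0, krev=200.0, seed=0, noisy=False)
        cfg = FitConfig.three_state(spins={"res1": TRUE_3STATE_SPINS},
                                    fix_spins=True, n_starts=3, seed=0)
        res = fit_model(series, cfg)
        assert res.params["kd"] == pytest.approx(10.0, rel=0.01)
        assert res.params["keq"] == pytest.approx(1.0, rel=0.01)
        assert res.params["koff"] == pytest.approx(200.0, rel=0.01)
        assert res.params["krev"] == pytest.approx(200.0, rel=0.01)

    def test_four_state_noise_free_recovery(self):
        series = four_state_dataset(koff_a=50.0, koff_b=200.0, seed=0, noisy=False)
        cfg = FitConfig.four_state(spins={"res1": TRUE_4STATE_SPINS},
                                   fix_spins=True, n_starts=3, seed=0)
        res = fit_model(series, cfg)
        assert res.params["kd"] == pytest.approx(10.0, rel=0.01)
        assert res.params["koff_a"] == pytest.approx(50.0, rel=0.01)
        assert res.params["koff_b"] == pytest.approx(200.0, rel=0.01)

    def test_global_fit_with_duplicate_resonance_matches_single(self):
        s1 = two_state_dataset(koff=50.0, seed=3, resonance="resA")
        s2 = two_state_dataset(koff=50.0, seed=3, resonance="resB")
        cfg = FitConfig.two_state(
            spins={"resA": TRUE_2STATE_SPINS, "resB": TRUE_2STATE_SPINS},
            fix_spins=True, n_starts=2, seed=0)
        single = fit_model(s1, FitConfig.two_state(
            spins={"resA": TRUE_2STATE_SPINS}, fix_spins=True, n_starts=2, seed=0))
        both = fit_model([s1, s2], cfg)
        assert both.params["kd"] == pytest.approx(single.params["kd"], rel=1e-3)
        assert both.params["koff"] == pytest.approx(single.params["koff"], rel=1e-3)


class TestMonteCarlo:
    def test_zero_noise_collapses_ci_to_point(self):
        series = two_state_dataset(koff=50.0, seed=0, noisy=False)
        cfg = FitConfig.two_state(spins={"res1": TRUE_2STATE_SPINS}, fix_spins=True,
                                  n_starts=2, seed=0, noise_sigma=0.0)
        res = monte_carlo_ci(series, cfg, fit_model(series, cfg))
        assert res.ci["kd"] == (res.params["kd"], res.params["kd"])
        assert res.flags["kd"] == ""

    def test_ci_brackets_truth_on_noisy_data(self):
        series = two_state_dataset(koff=50.0, seed=9)
        cfg = FitConfig.two_state(spins={"res1": TRUE_2STATE_SPINS}, fix_spins=True,
                                  n_starts=2, seed=0, snr=50.0)
        res = monte_carlo_ci(series, cfg, fit_model(series, cfg))
        lo, hi = res.ci["kd"]
        assert lo < hi
        assert res.n_mc >= 50
        assert lo < 10.0 < hi or abs(res.params["kd"] - 10.0) < 2.0

    def test_estimate_inside_reported_ci(self):
        series = two_state_dataset(koff=50.0, seed=12)
        cfg = FitConfig.two_state(spins={"res1": TRUE_2STATE_SPINS}, fix_spins=True,
                                  n_starts=2, seed=1, snr=50.0)
        res = monte_carlo_ci(series, cfg, fit_model(series, cfg))
        for name, ci in res.ci.items():
            if ci is not None:
                assert ci[0] <= res.params[name] <= ci[1]


class TestBoundaryFlags:
    def test_estimate_at_upper_bound_flagged(self):
        assert classify_boundary(1e5, (0.1, 1e5), None) == "UB"

    def test_estimate_at_lower_bound_flagged(self):
        assert classify_boundary(0.1, (0.1, 1e5), None) == "LB"

    def test_mid_range_estimate_with_normal_spread_unflagged(self):
        samples = np.array([40.0, 45.0, 50.0, 55.0, 60.0])
        assert classify_boundary(50.0, (0.1, 1e5), samples) == ""

    def test_small_variation_flagged_sv(self):
        samples = np.full(100, 123.456)
        assert classify_boundary(123.456, (0.1, 1e5), samples) == "SV"

    def test_samples_pinned_at_bound_flagged(self):
        samples = np.concatenate([np.full(60, 1e5), np.full(40, 5e3)])
        assert classify_boundary(5e3, (0.1, 1e5), samples) == "UB"


class TestConfigValidation:
    def test_mc_reps_minimum_enforced(self):
        with pytest.raises(InvalidInputError, match="at least 50"):
            FitConfig.two_state(mc_reps=10)

    def test_param_ordering_enforced(self):
        with pytest.raises(InvalidInputError):
            Param("kd", init=5.0, lb=10.0, ub=1000.0)

    def test_missing_parameter_spec_rejected(self):
        with pytest.raises(InvalidInputError, match="missing"):
            FitConfig("2state", {"kd": Param("kd", 10.0, 1e-3, 1e3)})
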