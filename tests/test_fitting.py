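"""cSSD objective, Pearson scoring, the k1/k5 metric and the MCMC fitter."""

import numpy as np
import pytest

from degronkinetics import (
    FitConfig,
    MULTI_MONO,
    ModelTopology,
    RateConstants,
    Trajectory,
    UndefinedCorrelationError,
    ValidationError,
    compare_models,
    cssd,
    k1_over_k5,
    mcmc_fit,
    pearson_r,
    reference_parameters,
    simulate,
)
from degronkinetics.fitting import _reflect, metropolis_accept

from conftest import make_dataset


def trajectory_from(times, mono, di=None, tri=None, tetra=None):
    n = len(times)
    zeros = np.zeros(n)
    cols = [np.linspace(1, 0.5, n), np.asarray(mono)]
    for series in (di, tri, tetra):
        cols.append(zeros if series is None else np.asarray(series))
    cols.append(zeros)
    return Trajectory(np.asarray(times, dtype=float), np.column_stack(cols))


class TestCssd:
    def test_perfect_fit_is_zero(self, bonger):
        times = (10.0, 60.0, 240.0)
        traj = simulate(bonger, MULTI_MONO, times=times)
        data = make_dataset(
            times, {s: traj.species(s) for s in ("mono", "di", "tri", "tetra")}
        )
        assert cssd(traj, data) == 0.0

    def test_uniform_offset_sums_squares(self):
        times = (10.0, 30.0)
        delta = 0.05
        model = trajectory_from(times, [0.2, 0.3])
        data = make_dataset(times, {"mono": np.array([0.2, 0.3]) + delta})
        assert cssd(model, data) == pytest.approx(2 * delta**2)

    def test_hand_example(self):
        model = trajectory_from((10.0, 30.0), [0.5, 0.3])
        data = make_dataset((10.0, 30.0), {"mono": [0.4, 0.5]})
        assert cssd(model, data) == pytest.approx(0.05)

    def test_absent_cells_skipped(self):
        model = trajectory_from((10.0, 30.0), [0.5, 0.3])
        data = make_dataset((10.0, 30.0), {"mono": [0.4, np.nan]})
        assert cssd(model, data) == pytest.approx(0.01)

    def test_time_mismatch_rejected(self):
        model = trajectory_from((10.0, 30.0), [0.5, 0.3])
        data = make_dataset((10.0, 60.0), {"mono": [0.4, 0.5]})
        with pytest.raises(ValidationError):
            cssd(model, data)


class TestPearson:
    def test_identity_is_one(self):
        model = trajectory_from((10.0, 30.0, 60.0), [0.1, 0.2, 0.3])
        data = make_dataset((10.0, 30.0, 60.0), {"mono": [0.1, 0.2, 0.3]})
        assert pearson_r(model, data, "mono") == pytest.approx(1.0)

    def test_negative_affine_is_minus_one(self):
        model = trajectory_from((10.0, 30.0, 60.0), [0.1, 0.2, 0.3])
        data = make_dataset((10.0, 30.0, 60.0), {"mono": [0.9, 0.7, 0.5]})
        assert pearson_r(model, data, "mono") == pytest.approx(-1.0)

    def test_hand_example(self):
        model = trajectory_from((1.0, 2.0, 3.0), [1.0, 2.0, 3.0])
        data = make_dataset((1.0, 2.0, 3.0), {"mono": [1.0, 2.0, 4.0]})
        assert pearson_r(model, data, "mono") == pytest.approx(0.98198, abs=1e-5)

    def test_zero_variance_raises(self):
        model = trajectory_from((10.0, 30.0), [0.2, 0.2])
        data = make_dataset((10.0, 30.0), {"mono": [0.1, 0.3]})
        with pytest.raises(UndefinedCorrelationError):
            pearson_r(model, data, "mono")


class TestRatioMetric:
    def test_printed_constants_reproduce_printed_ratios(self):
        assert k1_over_k5(reference_parameters("Bonger")) == 2.03
        assert k1_over_k5(reference_parameters("p53")) == 1.51

    def test_equal_rates_give_one(self):
        params = RateConstants(5e-3, 0, 0, 0, 5e-3, 0, 0, 0, 0)
        assert k1_over_k5(params) == 1.00

    def test_zero_k5_rejected(self):
        params = RateConstants(5e-3, 0, 0, 0, 0, 0, 0, 0, 0)
        with pytest.raises(ValidationError):
            k1_over_k5(params)


class TestMetropolisStep:
    def test_downhill_always_accepted(self):
        assert metropolis_accept(1.0, 0.5, temperature=0.1, u=0.999999)

    def test_uphill_accepted_below_boltzmann_probability(self):
        # delta = 0.1, T = 0.2 -> acceptance probability exp(-0.5) ~ 0.6065
        p = np.exp(-0.5)
        assert metropolis_accept(1.0, 1.1, temperature=0.2, u=p - 1e-6)
        assert not metropolis_accept(1.0, 1.1, temperature=0.2, u=p + 1e-6)

    def test_reflection_stays_inside_box(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(-30, 10, 1000)
        y = _reflect(x, -11.0, 0.0)
        assert np.all((y >= -11.0) & (y <= 0.0))
        # interior points are untouched
        assert _reflect(np.array([-5.0]), -11.0, 0.0)[0] == -5.0


class TestMcmcFit:
    def test_same_seed_bitwise_identical(self, bonger_dataset, quick_config):
        a = mcmc_fit(bonger_dataset, MULTI_MONO, quick_config)
        b = mcmc_fit(bonger_dataset, MULTI_MONO, quick_config)
        assert a.params == b.params
        assert a.cssd == b.cssd
        assert np.array_equal(a.chain, b.chain)

    def test_chain_respects_bounds(self, bonger_dataset, quick_config):
        res = mcmc_fit(bonger_dataset, MULTI_MONO, quick_config)
        assert res.chain.min() >= quick_config.lower
        assert res.chain.max() <= quick_config.upper
        assert np.all(res.params.as_array() >= quick_config.lower)
        assert np.all(res.params.as_array() <= quick_config.upper)

    def test_best_trace_monotone_nonincreasing(self, bonger_dataset, quick_config):
        res = mcmc_fit(bonger_dataset, MULTI_MONO, quick_config)
        assert np.all(np.diff(res.best_trace) <= 0)

    def test_acceptance_rate_in_unit_interval(self, bonger_dataset, quick_config):
        res = mcmc_fit(bonger_dataset, MULTI_MONO, quick_config)
        assert 0.0 < res.acceptance_rate < 1.0

    def test_noiseless_data_recovers_k1_within_5_percent(self, bonger, noiseless_dataset):
        res = mcmc_fit(noiseless_dataset, MULTI_MONO, FitConfig(iterations=50_000, seed=7))
        assert res.params.k1 == pytest.approx(bonger.k1, rel=0.05)

    def test_zero_ubiquitination_data_drives_k1_to_lower_bound(self):
        # with no product bands the objective is minimized by (nearly)
        # shutting off production; k1 is driven to the search floor
        # while k2-k4 become progressively less identifiable
        times = (10.0, 30.0, 60.0, 120.0, 180.0, 240.0)
        zeros = np.zeros(len(times))
        data = make_dataset(
            times, {"mono": zeros, "di": zeros, "tri": zeros, "tetra": zeros}
        )
        config = FitConfig(iterations=20_000, seed=3)
        res = mcmc_fit(data, MULTI_MONO, config)
        assert res.params.k1 < 5 * config.lower
        assert max(res.params.k2, res.params.k3, res.params.k4) < 1e-3

    def test_too_few_time_points_rejected(self):
        data = make_dataset((10.0,), {"mono": [0.1]})
        with pytest.raises(ValidationError):
            mcmc_fit(data, MULTI_MONO, FitConfig(iterations=100, seed=0))

    def test_config_validation(self):
        with pytest.raises(ValidationError):
            FitConfig(iterations=0)
        with pytest.raises(ValidationError):
            FitConfig(lower=0.0)
        with pytest.raises(ValidationError):
            FitConfig(lower=1.0, upper=0.1)
        with pytest.raises(ValidationError):
            FitConfig(proposal_scale=0.0)
        with pytest.raises(ValidationError):
            FitConfig(fit_target="medians")

    def test_replicate_level_fitting_runs(self, bonger_dataset):
        config = FitConfig(iterations=2_000, seed=5, fit_target="replicates")
        res = mcmc_fit(bonger_dataset, MULTI_MONO, config)
        assert res.cssd > 0


class TestCompareModels:
    def test_multi_mono_generated_data_prefers_multi_mono(self, bonger_dataset):
        comp = compare_models(bonger_dataset, FitConfig(iterations=10_000, seed=1))
        assert comp.winner == "multi_mono"
        assert comp.results["multi_mono"].cssd <= comp.results["poly"].cssd

    def test_phi_one_is_an_exact_tie(self, bonger_dataset):
        comp = compare_models(
            bonger_dataset, FitConfig(iterations=2_000, seed=2), phi=1.0
        )
        assert comp.tie
        assert comp.winner is None
        assert comp.results["multi_mono"].cssd == comp.results["poly"].cssd

    def test_poly_generated_data_prefers_poly(self, bonger):
        from degronkinetics import NoiseModel, aggregate_replicates, generate_timecourse, normalize_to_parent

        table = generate_timecourse(
            bonger, ModelTopology("poly", 0.01), noise=NoiseModel(cv=0.10), n_reps=3, seed=1
        )
        data = aggregate_replicates(normalize_to_parent(table))
        comp = compare_models(data, FitConfig(iterations=50_000, seed=1), phi=0.01)
        assert comp.results["poly"].cssd <= comp.results["multi_mono"].cssd
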