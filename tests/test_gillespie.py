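import numpy as np
import pytest
from scipy import stats as sps

from pulsedrug.gillespie import (
    EstimationError,
    OutcomeKind,
    RecordMode,
    SimulationConfig,
    estimate_half_period_extinction_prob,
    estimate_p0,
    replicate_seeds,
    run_trajectory,
)
from pulsedrug.model_core import AlternationSchedule, ModelParameters


def _config(params, schedule, **kwargs):
    return SimulationConfig(params=params, schedule=schedule, **kwargs)


class TestRunTrajectory:
    def test_empty_population_extinct_at_zero(self, default_params):
        config = _config(default_params, AlternationSchedule(period=20.0), init_S=0)
        outcome, _ = run_trajectory(config)
        assert outcome.kind is OutcomeKind.EXTINCT
        assert outcome.t_event == 0.0
        assert outcome.extinct_before_C_fixation

    def test_timeout_outcome_not_exception(self, default_params):
        config = _config(default_params, AlternationSchedule.always_off(), t_max=1.0, seed=3)
        outcome, _ = run_trajectory(config)
        assert outcome.kind is OutcomeKind.TIMEOUT
        assert outcome.t_event == 1.0

    def test_pure_death_mean_extinction_time(self):
        # oracle: harmonic sum (1/g) sum_{i=1}^{900} 1/i = 73.80
        params = ModelParameters.create(fS_drug=0.0, K=1000, mu1=0.0, mu2=0.0)
        expected = sum(1.0 / i for i in range(1, 901)) / 0.1
        seeds = replicate_seeds(21, 300)
        times = []
        for s in seeds:
            config = _config(
                params, AlternationSchedule.always_on(), init_S=900, seed=int(s)
            )
            outcome, _ = run_trajectory(config)
            assert outcome.kind is OutcomeKind.EXTINCT
            times.append(outcome.t_event)
        times = np.asarray(times)
        se = times.std(ddof=1) / np.sqrt(len(times))
        assert abs(times.mean() - expected) < 2 * se + 1e-9

    def test_equilibrium_size_long_time_average(self):
        # deterministic equilibrium K(1 - gS/fS) = 900
        params = ModelParameters.create(fS_drug=0.0, K=1000, mu1=0.0, mu2=0.0)
        config = _config(
            params,
            AlternationSchedule.always_off(),
            init_S=10,
            t_max=500.0,
            seed=5,
            record=RecordMode.SAMPLED,
            sample_dt=1.0,
        )
        _, traj = run_trajectory(config)
        mask = (traj.t >= 50) & (traj.t <= 500)
        mean_N = (traj.S + traj.R + traj.C)[mask].mean()
        assert mean_N == pytest.approx(900, rel=0.05)

    def test_no_mutants_when_mu1_zero(self, default_params):
        params = default_params.with_(mu1=0.0)
        config = _config(
            params,
            AlternationSchedule(period=40.0),
            t_max=200.0,
            seed=8,
            record=RecordMode.EVENTS,
        )
        _, traj = run_trajectory(config)
        assert np.all(traj.R == 0) and np.all(traj.C == 0)

    def test_counts_bounded_and_steps_unit(self, default_params):
        config = _config(
            default_params,
            AlternationSchedule(period=20.0),
            t_max=100.0,
            seed=13,
            record=RecordMode.EVENTS,
        )
        _, traj = run_trajectory(config)
        N = traj.S + traj.R + traj.C
        assert np.all(N <= max(10, default_params.K))
        assert np.all(traj.S >= 0) and np.all(traj.R >= 0) and np.all(traj.C >= 0)
        assert np.all(np.diff(traj.t) > 0)
        steps = np.abs(np.diff(traj.S)) + np.abs(np.diff(traj.R)) + np.abs(np.diff(traj.C))
        assert np.all(steps == 1)

    def test_extinct_with_drug_always_on(self):
        params = ModelParameters.create(fS_drug=1.0, gS_drug=2.0, K=1000, mu1=0.0, mu2=0.0)
        config = _config(params, AlternationSchedule.always_on(), init_S=900, seed=2)
        outcome, _ = run_trajectory(config)
        assert outcome.kind is OutcomeKind.EXTINCT

    def test_reproducible_bit_for_bit(self, default_params):
        config = _config(
            default_params,
            AlternationSchedule(period=20.0),
            t_max=50.0,
            seed=99,
            record=RecordMode.EVENTS,
        )
        out1, traj1 = run_trajectory(config)
        out2, traj2 = run_trajectory(config)
        assert out1 == out2
        np.testing.assert_array_equal(traj1.t, traj2.t)
        np.testing.assert_array_equal(traj1.S, traj2.S)

    def test_different_seed_different_path(self, default_params):
        c1 = _config(default_params, AlternationSchedule(period=20.0), t_max=50.0, seed=1)
        c2 = _config(default_params, AlternationSchedule(period=20.0), t_max=50.0, seed=2)
        assert run_trajectory(c1)[0] != run_trajectory(c2)[0]

    def test_single_death_times_are_exponential(self):
        # 1-individual pure-death process: extinction times ~ Exp(g)
        g = 1.0
        params = ModelParameters.create(
            fS=1.0, fS_drug=0.0, gS=g, gS_drug=g, K=1000, mu1=0.0, mu2=0.0
        )
        seeds = replicate_seeds(17, 10_000)
        times = np.empty(len(seeds))
        for k, s in enumerate(seeds):
            config = _config(
                params, AlternationSchedule.always_on(), init_S=1, seed=int(s)
            )
            outcome, _ = run_trajectory(config)
            times[k] = outcome.t_event
        _, p_value = sps.kstest(times, "expon", args=(0, 1 / g))
        assert p_value > 0.01

    def test_trajectory_dataframe_columns(self, default_params):
        config = _config(
            default_params,
            AlternationSchedule(period=20.0),
            t_max=30.0,
            seed=4,
            record=RecordMode.SAMPLED,
            sample_dt=5.0,
        )
        _, traj = run_trajectory(config)
        df = traj.to_dataframe()
        assert list(df.columns) == ["t", "S", "R", "C", "drug_on"]
        # environment annotation matches the schedule convention
        assert not df.loc[df.t < 10, "drug_on"].any()
        assert df.loc[(df.t >= 10) & (df.t < 20), "drug_on"].all()


class TestEstimateP0:
    def test_fast_alternation_no_extinction(self, default_params):
        # resistance systematically takes over for T/2 << tau_S
        config = _config(default_params, AlternationSchedule(period=20.0), seed=11)
        est = estimate_p0(config, 30)
        assert est.estimate == 0.0
        assert est.counts["C_FIXED"] == 30
        assert np.isfinite(est.mean_t_fix)

    def test_ci_contains_estimate(self, default_params):
        config = _config(default_params, AlternationSchedule(period=1000.0), seed=12)
        est = estimate_p0(config, 50)
        assert est.ci_low <= est.estimate <= est.ci_high
        assert 0.0 <= est.estimate <= 1.0
        assert sum(est.counts.values()) == est.n_rep == 50

    def test_all_timeout_raises(self, default_params):
        config = _config(default_params, AlternationSchedule.always_off(), t_max=0.5, seed=1)
        with pytest.raises(EstimationError):
            estimate_p0(config, 5)

    def test_invalid_n_rep(self, default_params):
        config = _config(default_params, AlternationSchedule(period=20.0))
        with pytest.raises(ValueError):
            estimate_p0(config, 0)

    def test_seeds_logged(self, default_params):
        config = _config(default_params, AlternationSchedule(period=20.0), seed=5)
        est = estimate_p0(config, 10)
        assert len(est.seeds) == 10
        np.testing.assert_array_equal(est.seeds, replicate_seeds(5, 10))


class TestHalfPeriodExtinction:
    def test_tiny_period_gives_zero(self, small_K_params):
        est = estimate_half_period_extinction_prob(small_K_params, T=1e-4, n_rep=50, seed=1)
        assert est.estimate == 0.0

    def test_long_period_perfect_biostatic_certain(self, small_K_params):
        # T/2 far beyond 2 tau_S ~ 100: extinction is certain without divisions
        est = estimate_half_period_extinction_prob(small_K_params, T=2000.0, n_rep=50, seed=2)
        assert est.estimate == 1.0

    def test_counts_and_ci(self, small_K_params):
        params = small_K_params.with_(fS_drug=0.11, gS_drug=0.1)
        est = estimate_half_period_extinction_prob(params, T=10**2.5, n_rep=200, seed=3)
        assert est.counts["within_half_period"] + est.counts["beyond"] == 200
        assert est.ci_low <= est.estimate <= est.ci_high
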