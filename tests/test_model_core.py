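import math

import numpy as np
import pytest
import yaml
from hypothesis import given, settings
from hypothesis import strategies as st

from pulsedrug.model_core import (
    AlternationSchedule,
    EnvironmentRates,
    ModelParameters,
    PopulationState,
    ScheduleMode,
    classify_regime,
    config_to_objects,
    environment_at,
    load_config,
    propensities,
    r_ratio,
    rates_from_r_ratio,
)


class TestEnvironmentAt:
    def test_drug_absent_at_origin(self):
        sched = AlternationSchedule(period=20.0)
        drug, _ = environment_at(sched, 0.0)
        assert drug is False

    def test_drug_starts_at_half_period_boundary(self):
        sched = AlternationSchedule(period=20.0)
        drug, next_switch = environment_at(sched, 10.0)
        assert drug is True
        assert next_switch == 20.0

    def test_mid_second_period(self):
        # 1500.5 mod 1000 = 500.5 >= 500 -> drug present
        drug, _ = environment_at(AlternationSchedule(period=1000.0), 1500.5)
        assert drug is True

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            environment_at(AlternationSchedule(period=20.0), -1.0)

    def test_constant_modes(self):
        assert environment_at(AlternationSchedule.always_off(), 123.0) == (False, math.inf)
        assert environment_at(AlternationSchedule.always_on(), 123.0) == (True, math.inf)

    @given(
        t=st.floats(min_value=0.0, max_value=1e5, allow_nan=False),
        T=st.floats(min_value=1e-2, max_value=1e4, allow_nan=False),
    )
    @settings(max_examples=50, deadline=None)
    def test_periodicity(self, t, T):
        sched = AlternationSchedule(period=T)
        assert environment_at(sched, t)[0] == environment_at(sched, t + T)[0]

    def test_invalid_period(self):
        with pytest.raises(ValueError):
            AlternationSchedule(period=0.0)
        with pytest.raises(ValueError):
            AlternationSchedule(period=None)


class TestPropensities:
    def test_logistic_division_and_death(self, default_params):
        state = PopulationState(t=0.0, S=900, R=0, C=0)
        a = propensities(state, default_params.rates_no_drug, default_params)
        assert a[0] == pytest.approx(90.0)  # 1 * (1 - 0.9) * 900
        assert a[3] == pytest.approx(90.0)  # 0.1 * 900
        assert np.all(a[[1, 2, 4, 5]] == 0)

    def test_divisions_vanish_at_capacity(self, default_params):
        state = PopulationState(t=0.0, S=1000, R=0, C=0)
        a = propensities(state, default_params.rates_no_drug, default_params)
        assert np.all(a[:3] == 0)

    def test_clamped_above_capacity(self, default_params):
        state = PopulationState(t=0.0, S=1500, R=0, C=0)
        a = propensities(state, default_params.rates_no_drug, default_params)
        assert np.all(a[:3] == 0) and np.all(a >= 0)

    def test_empty_population_absorbing(self, default_params):
        state = PopulationState(t=0.0, S=0, R=0, C=0)
        assert np.all(propensities(state, default_params.rates_no_drug, default_params) == 0)

    @given(
        s=st.integers(min_value=0, max_value=1500),
        r=st.integers(min_value=0, max_value=300),
        c=st.integers(min_value=0, max_value=300),
    )
    @settings(max_examples=50, deadline=None)
    def test_total_rate_conservation(self, s, r, c):
        params = ModelParameters.create(fS_drug=0.0, K=1000)
        rates = params.rates_no_drug
        state = PopulationState(t=0.0, S=s, R=r, C=c)
        a = propensities(state, rates, params)
        logistic = max(0.0, 1.0 - state.N / params.K)
        expected = (
            s * (rates.f_S * logistic + rates.g_S)
            + r * (rates.f_R * logistic + rates.g_R)
            + c * (rates.f_C * logistic + rates.g_C)
        )
        assert np.sum(a) == pytest.approx(expected, rel=1e-12)


class TestRRatio:
    def test_perfect_biostatic(self):
        assert r_ratio(0.0, 0.1) == pytest.approx(1.0)

    def test_just_above_mic(self):
        assert r_ratio(1.0, 1.1) == pytest.approx(1 / 11, rel=1e-9)

    def test_at_mic(self):
        assert r_ratio(1.0, 1.0) == 0.0

    def test_invalid_death_rate(self):
        with pytest.raises(ValueError):
            r_ratio(1.0, 0.0)

    @given(
        f=st.floats(min_value=0.01, max_value=5.0),
        g1=st.floats(min_value=0.01, max_value=5.0),
        dg=st.floats(min_value=1e-3, max_value=2.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_g(self, f, g1, dg):
        # strict monotonicity needs f' > 0 (at f' = 0 the ratio is pinned at 1)
        assert r_ratio(f, g1 + dg) > r_ratio(f, g1)

    @given(
        f=st.floats(min_value=0.0, max_value=5.0),
        df=st.floats(min_value=1e-3, max_value=2.0),
        g=st.floats(min_value=0.01, max_value=5.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_f(self, f, df, g):
        assert r_ratio(f + df, g) < r_ratio(f, g)


class TestRatesFromRRatio:
    def test_roundtrip_biocidal(self, default_params):
        p = rates_from_r_ratio(-0.1, "biocidal", default_params)
        assert p.rates_drug.f_S == 1.0
        assert r_ratio(p.rates_drug.f_S, p.rates_drug.g_S) == pytest.approx(-0.1)

    def test_roundtrip_biostatic(self, default_params):
        p = rates_from_r_ratio(-0.1, "biostatic", default_params)
        assert p.rates_drug.g_S == 0.1
        assert p.rates_drug.f_S == pytest.approx(0.11)
        assert r_ratio(p.rates_drug.f_S, p.rates_drug.g_S) == pytest.approx(-0.1)

    def test_bad_mode(self, default_params):
        with pytest.raises(ValueError):
            rates_from_r_ratio(0.1, "bio", default_params)


class TestClassifyRegime:
    def test_weak_biocidal_no_decay(self):
        params = ModelParameters.create(fS_drug=1.0, gS_drug=1.1)
        report = classify_regime(params)
        assert report.fast_alternation_decay is False
        assert report.above_mic is True

    def test_strong_biocidal_decay(self):
        # g'_S = 2 > 2 fS - gS = 1.9
        params = ModelParameters.create(fS_drug=1.0, gS_drug=2.0)
        report = classify_regime(params)
        assert report.fast_alternation_decay is True

    def test_effective_fitness_perfect_biostatic(self):
        params = ModelParameters.create(fS_drug=0.0)
        report = classify_regime(params)
        assert report.f_S_eff == 0.5
        assert report.g_S_eff == pytest.approx(0.1)
        assert report.fast_alternation_decay is False

    def test_critical_ratio(self, default_params):
        # (fS - gS)/(2 fS - gS) = 0.9/1.9
        assert classify_regime(default_params).critical_r_biocidal == pytest.approx(0.9 / 1.9)


class TestModelParameters:
    def test_drug_must_not_touch_R_rates(self):
        with pytest.raises(ValueError, match="R/C rates"):
            ModelParameters(
                rates_no_drug=EnvironmentRates(1.0, 0.9, 1.0, 0.1, 0.1, 0.1),
                rates_drug=EnvironmentRates(0.0, 0.8, 1.0, 0.1, 0.1, 0.1),
                K=1000,
                mu1=1e-5,
                mu2=1e-3,
            )

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            EnvironmentRates(-1.0, 0.9, 1.0, 0.1, 0.1, 0.1)

    def test_K_and_mu_validation(self):
        with pytest.raises(ValueError):
            ModelParameters.create(K=0.5)
        with pytest.raises(ValueError):
            ModelParameters.create(mu1=1.5)

    def test_time_unit_warning(self):
        with pytest.warns(UserWarning, match="time unit"):
            ModelParameters.create(fS=2.0)

    def test_with_unknown_key(self, default_params):
        with pytest.raises(TypeError):
            default_params.with_(bogus=1.0)


class TestPopulationState:
    def test_total(self):
        assert PopulationState(t=1.0, S=3, R=2, C=1).N == 6

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            PopulationState(t=0.0, S=-1, R=0, C=0)


class TestConfig:
    def test_unknown_key_hard_error(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("K: 100\nbogus_key: 3\n")
        with pytest.raises(ValueError, match="unknown config key"):
            load_config(path)

    def test_defaults_fill_in(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("K: 100\n")
        cfg = load_config(path)
        assert cfg["K"] == 100
        assert cfg["mu1"] == 1e-5
        assert cfg["gS_drug"] == cfg["gS"]  # perfect biostatic default

    def test_json_dialect(self, tmp_path):
        path = tmp_path / "cfg.json"
        path.write_text('{"K": 250, "T": 50, "gS_drug": 1.1, "fS_drug": 1.0}')
        cfg = load_config(path)
        params, schedule, extras = config_to_objects(cfg)
        assert params.K == 250
        assert params.rates_drug.g_S == 1.1
        assert schedule.period == 50
        assert extras["init_S"] == 10

    def test_yaml_roundtrip(self, tmp_path):
        cfg_in = {"K": 500, "mu1": 1e-4, "T": 200.0, "seed": 7}
        path = tmp_path / "cfg.yaml"
        path.write_text(yaml.safe_dump(cfg_in))
        cfg = load_config(path)
        for key, value in cfg_in.items():
            assert cfg[key] == value
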