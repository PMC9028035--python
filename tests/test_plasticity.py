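"""Fluctuation rule: period sampling, sinusoid phases, reward updates."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import rlctrnn as r
from rlctrnn.plasticity import FluctuationArray

WIDE = r.FluctuationConfig(value_bounds=(-100.0, 100.0), amplitude_max=100.0)


def scalar(center=0.0, amplitude=4.0, period=2.0, start=0.0, bounds=(-100, 100)):
    return r.FluctuatingScalar(
        center=center,
        amplitude=amplitude,
        period=period,
        period_start=start,
        value_bounds=bounds,
        amplitude_bounds=(0.0, 100.0),
    )


class TestSamplePeriod:
    def test_degenerate_sd_returns_mean(self, rng):
        cfg = r.FluctuationConfig(period_min=2.0, period_sd=0.0)
        assert all(r.sample_period(cfg, rng) == cfg.period_mean for _ in range(20))

    def test_always_within_bounds(self, rng):
        cfg = r.FluctuationConfig(period_min=1.0, period_sd=5.0)
        draws = np.array([r.sample_period(cfg, rng) for _ in range(2000)])
        assert np.all((draws >= cfg.period_min) & (draws <= cfg.period_max))

    def test_mean_matches_clamped_normal_moment(self, rng):
        # oracle: E[clip(X, a, b)] for X ~ N(mu, omega^2) by numerical integration
        pmin = 2.0
        cfg = r.FluctuationConfig(
            period_min=pmin, period_mean=1.5 * pmin, period_sd=0.5 * pmin
        )
        a, b, mu, sd = pmin, 2 * pmin, cfg.period_mean, cfg.period_sd
        grid = np.linspace(mu - 8 * sd, mu + 8 * sd, 20001)
        expected = np.trapezoid(
            np.clip(grid, a, b) * stats.norm.pdf(grid, mu, sd), grid
        )
        draws = np.array([r.sample_period(cfg, rng) for _ in range(10000)])
        se = draws.std(ddof=1) / np.sqrt(draws.size)
        assert abs(draws.mean() - expected) < 3 * se


class TestFluctuationValue:
    def test_phase_points(self):
        fs = scalar(center=5.0, amplitude=2.0, period=4.0)
        assert r.fluctuation_value(fs, 0.0) == pytest.approx(5.0, abs=1e-12)
        assert r.fluctuation_value(fs, 1.0) == pytest.approx(7.0, abs=1e-12)
        assert r.fluctuation_value(fs, 3.0) == pytest.approx(3.0, abs=1e-12)

    def test_before_period_start_rejected(self):
        fs = scalar(start=10.0)
        with pytest.raises(ValueError):
            r.fluctuation_value(fs, 9.0)

    def test_clamped_to_value_bounds(self):
        fs = scalar(center=15.0, amplitude=4.0, period=4.0, bounds=(-16, 16))
        assert r.fluctuation_value(fs, 1.0) == 16.0

    @settings(derandomize=True, max_examples=100)
    @given(
        st.floats(-10, 10),
        st.floats(0, 8),
        st.floats(0.5, 4),
        st.floats(0, 0.999),
    )
    def test_value_within_amplitude_band(self, c, a, period, frac):
        fs = scalar(center=c, amplitude=a, period=period)
        v = r.fluctuation_value(fs, frac * period)
        assert c - a - 1e-9 <= v <= c + a + 1e-9


class TestAdvanceFluctuation:
    def test_no_resample_before_boundary(self, rng):
        fs = scalar(period=2.0)
        out = r.advance_fluctuation(fs, t=0.5, dt=0.01, config=WIDE, rng=rng)
        assert out.period == fs.period and out.period_start == fs.period_start

    def test_boundary_crossing_resamples_once(self, rng):
        fs = scalar(period=2.0, start=1.0)
        out = r.advance_fluctuation(fs, t=2.995, dt=0.01, config=WIDE, rng=rng)
        assert out.period_start == pytest.approx(3.0)
        assert WIDE.period_min <= out.period <= WIDE.period_max

    def test_resample_count_over_sweep(self, rng):
        # omega = 0 makes every period exactly T: floor(D/T) resamples in D seconds
        T, D, dt = 2.0, 21.0, 0.01
        cfg = r.FluctuationConfig(period_min=T, period_max=T, period_mean=T, period_sd=0.0)
        fs = r.FluctuatingScalar.from_config(0.0, cfg, rng)
        resamples = 0
        t = 0.0
        while t < D:
            out = r.advance_fluctuation(fs, t, dt, cfg, rng)
            if out.period_start != fs.period_start:
                resamples += 1
            fs = out
            t += dt
        assert resamples == int(D / T)


class TestApplyReward:
    def test_zero_reward_is_identity(self):
        fs = scalar(center=1.0, amplitude=3.0)
        out = r.apply_reward(fs, p_now=2.5, reward=0.0, config=WIDE, dt=0.01)
        assert out.center == fs.center and out.amplitude == fs.amplitude

    def test_constant_reward_linear_amplitude_decay(self):
        # dA/dt = -beta * R integrates to A0 - beta*R*t under constant reward
        cfg = r.FluctuationConfig(
            learning_rate=0.0, convergence_rate=0.1, value_bounds=(-100, 100),
            amplitude_max=100.0,
        )
        fs = scalar(amplitude=4.0)
        dt, steps = 0.01, 1000  # 10 s
        for _ in range(steps):
            fs = r.apply_reward(fs, p_now=0.0, reward=1.0, config=cfg, dt=dt)
        assert fs.amplitude == pytest.approx(3.0, abs=1e-9)

    def test_center_moves_with_displacement_sign(self):
        fs = scalar(center=1.0)
        up = r.apply_reward(fs, p_now=2.0, reward=0.5, config=WIDE, dt=0.01)
        down = r.apply_reward(fs, p_now=2.0, reward=-0.5, config=WIDE, dt=0.01)
        assert up.center > fs.center > down.center

    def test_alpha_zero_freezes_center(self):
        cfg = r.FluctuationConfig(learning_rate=0.0, convergence_rate=2.0)
        fs = scalar(center=1.0)
        out = r.apply_reward(fs, p_now=5.0, reward=3.0, config=cfg, dt=0.01)
        assert out.center == fs.center and out.amplitude != fs.amplitude

    def test_beta_zero_freezes_amplitude(self):
        cfg = r.FluctuationConfig(learning_rate=2.0, convergence_rate=0.0)
        fs = scalar(center=1.0)
        out = r.apply_reward(fs, p_now=5.0, reward=3.0, config=cfg, dt=0.01)
        assert out.amplitude == fs.amplitude and out.center != fs.center

    def test_amplitude_never_negative(self):
        fs = scalar(amplitude=0.005)
        for _ in range(100):
            fs = r.apply_reward(fs, p_now=0.0, reward=10.0, config=WIDE, dt=0.01)
        assert fs.amplitude == 0.0


class TestFluctuationArray:
    def test_matches_scalar_ops_with_deterministic_periods(self):
        # omega = 0 removes randomness, so the array engine must follow the
        # scalar reference step for step
        T = 1.5
        cfg = r.FluctuationConfig(
            period_min=T, period_max=T, period_mean=T, period_sd=0.0,
            learning_rate=1.0, convergence_rate=0.5,
        )
        rng1, rng2 = np.random.default_rng(0), np.random.default_rng(0)
        centers = np.array([[1.0, -2.0], [0.5, 3.0]])
        arr = FluctuationArray(centers, cfg, rng1)
        scalars = [
            [r.FluctuatingScalar.from_config(centers[j, i], cfg, rng2) for i in range(2)]
            for j in range(2)
        ]
        dt = 0.01
        rewards = 0.3 * np.sin(np.arange(400) * 0.07)
        for k in range(400):
            t, reward = k * dt, rewards[k]
            arr.advance(t, dt)
            vals = arr.values(t + dt)
            arr.apply_reward(vals, reward, dt)
            for j in range(2):
                for i in range(2):
                    fs = r.advance_fluctuation(scalars[j][i], t, dt, cfg, rng2)
                    v = r.fluctuation_value(fs, t + dt)
                    assert abs(v - vals[j, i]) <= 1e-10
                    scalars[j][i] = r.apply_reward(fs, v, reward, cfg, dt)
        for j in range(2):
            for i in range(2):
                assert abs(scalars[j][i].center - arr.centers[j, i]) <= 1e-9
                assert abs(scalars[j][i].amplitude - arr.amplitudes[j, i]) <= 1e-9

    def test_periods_always_within_bounds(self, rng):
        cfg = r.FluctuationConfig(period_min=1.0)
        arr = FluctuationArray(np.zeros((3, 3)), cfg, rng)
        for k in range(5000):
            arr.advance(k * 0.01, 0.01)
        assert np.all((arr.periods >= cfg.period_min) & (arr.periods <= cfg.period_max))


class TestEffectiveParameters:
    def test_zero_amplitude_gives_centers(self, rng, oscillator):
        cfg = r.FluctuationConfig(init_flux=0.0)
        net = r.PlasticNetwork(base=oscillator, config=cfg, rng=rng)
        eff = r.effective_parameters(net, t=0.37)
        assert np.allclose(eff.weights, oscillator.weights)

    def test_static_biases_untouched(self, rng, oscillator):
        net = r.PlasticNetwork(base=oscillator, config=r.FluctuationConfig(), rng=rng)
        eff = r.effective_parameters(net, t=0.0)
        assert np.array_equal(eff.biases, oscillator.biases)

    def test_single_plastic_weight_at_quarter_period(self, rng):
        T = 2.0
        cfg = r.FluctuationConfig(
            init_flux=2.0, period_min=T, period_max=T, period_mean=T, period_sd=0.0,
        )
        base = r.NetworkParameters(np.full((2, 2), 5.0), np.zeros(2), np.ones(2))
        mask = np.zeros((2, 2), dtype=bool)
        mask[0, 1] = True
        net = r.PlasticNetwork(base=base, config=cfg, rng=rng, plastic_weight_mask=mask)
        eff = r.effective_parameters(net, t=T / 4)
        assert eff.weights[0, 1] == pytest.approx(7.0, abs=1e-12)
        others = np.ones((2, 2), dtype=bool) & ~mask
        assert np.all(eff.weights[others] == 5.0)
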