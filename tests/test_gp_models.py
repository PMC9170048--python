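"""Simulators and analytic correlation functions for the Gaussian models."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import linalg

import behavdim as bd
from behavdim.errors import (
    CoverageError,
    ModelError,
    ParameterError,
    SizeError,
    StabilityError,
)


def lag_corr(x, k):
    """Plain biased lag-k autocovariance of a zero-mean-ish sample."""
    x = x - x.mean()
    return float((x[: len(x) - k] @ x[k:]) / len(x))


class TestAnalyticCorrelations:
    @pytest.mark.parametrize(
        "tau_c, var, tau, expected",
        [
            (1.0, 1.0, 0.0, 1.0),
            (1.0, 1.0, 1.0, np.exp(-1)),
            (2.0, 3.0, 2.0, 3 * np.exp(-1)),
        ],
    )
    def test_ou_corr_values(self, tau_c, var, tau, expected):
        corr = bd.corr_ou_analytic(tau_c, var)
        assert corr.at(tau) == pytest.approx(expected, rel=1e-12)

    def test_two_d_amplitudes_and_timescales(self):
        # A+- = var (1 - a^2) / (2 (1 +- a)): 0.125 and 0.875 at a = 0.75
        corr = bd.corr_2d_analytic(tau_c=1.0, a=0.75, variance=1.0)
        assert corr.amplitudes == pytest.approx([0.125, 0.875], rel=1e-12)
        assert corr.timescales == pytest.approx([1 / 1.75, 1 / 0.25], rel=1e-12)

    @given(
        a=st.floats(-0.95, 0.95).filter(lambda v: abs(v) > 1e-3),
        var=st.floats(0.1, 10.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_two_d_amplitudes_sum_to_variance(self, a, var):
        corr = bd.corr_2d_analytic(tau_c=1.0, a=a, variance=var)
        assert corr.at(0.0) == pytest.approx(var, rel=1e-10)

    def test_two_d_degenerate_coupling_raises(self):
        with pytest.raises(ModelError):
            bd.corr_2d_analytic(tau_c=1.0, a=0.0, variance=1.0)
        with pytest.raises(StabilityError):
            bd.corr_2d_analytic(tau_c=1.0, a=1.5, variance=1.0)


class TestSimulateOU:
    def test_stationary_variance(self):
        ts = bd.simulate_ou(tau_c=1.0, variance=1.0, dt=0.01, n=10**5, seed=11)
        assert ts.values.var() == pytest.approx(1.0, rel=0.05)

    def test_correlation_at_tau_c(self):
        ts = bd.simulate_ou(tau_c=1.0, variance=1.0, dt=0.1, n=10**6, seed=7)
        got = lag_corr(ts.values, 10)  # lag tau_c = 10 steps
        assert got == pytest.approx(np.exp(-1), abs=0.01)

    @pytest.mark.parametrize("ratio", [0.01, 0.1, 1.0])
    def test_exact_discretization_lag1(self, ratio):
        # lag-1 sample autocorrelation must equal exp(-dt/tau_c) within 4 SE
        n = 10**6
        ts = bd.simulate_ou(tau_c=1.0, variance=1.0, dt=ratio, n=n, seed=42)
        rho = np.exp(-ratio)
        got = lag_corr(ts.values, 1) / ts.values.var()
        se = np.sqrt((1 - rho**2) / n) * np.sqrt((1 + rho**2) / (1 - rho**2))
        assert abs(got - rho) < 4 * max(se, 1e-6)

    def test_parameter_errors(self):
        with pytest.raises(ParameterError):
            bd.simulate_ou(-1.0, 1.0, 0.1, 100, seed=0)
        with pytest.raises(SizeError):
            bd.simulate_ou(1.0, 1.0, 0.1, 1, seed=0)


class TestSimulateTwoD:
    def test_stationary_variance(self):
        ts = bd.simulate_2d(tau_c=1.0, a=0.75, variance=1.0, dt=0.05, n=4 * 10**5, seed=5)
        assert ts.values.var() == pytest.approx(1.0, rel=0.05)

    def test_matches_analytic_correlation(self):
        dt, tau_c = 0.05, 1.0
        ts = bd.simulate_2d(tau_c=tau_c, a=0.75, variance=1.0, dt=dt, n=10**6, seed=9)
        ana = bd.corr_2d_analytic(tau_c, 0.75, 1.0)
        for tau in (0.5 * tau_c, 2.0 * tau_c):
            got = lag_corr(ts.values, round(tau / dt))
            # Monte-Carlo error for correlated samples: ~sqrt(2 tau_c / (n dt))
            se = np.sqrt(2 * tau_c / (len(ts) * dt))
            assert abs(got - ana.at(tau)) < 4 * se

    def test_decoupled_limit_is_ou(self):
        dt = 0.1
        ts = bd.simulate_2d(tau_c=1.0, a=0.0, variance=1.0, dt=dt, n=2 * 10**5, seed=3)
        assert ts.values.var() == pytest.approx(1.0, rel=0.05)
        got = lag_corr(ts.values, 10) / ts.values.var()
        assert got == pytest.approx(np.exp(-1), abs=0.02)

    def test_unstable_coupling_raises(self):
        with pytest.raises(StabilityError):
            bd.simulate_2d(1.0, 1.5, 1.0, 0.1, 100, seed=0)

    def test_hidden_variable_rescaling_invariance(self):
        """Rescaling the hidden y leaves every statistic of x unchanged:
        the analytic autocovariance of x is identical for the original and
        y-rescaled system."""
        tau_c, a, var, c = 1.0, 0.75, 1.0, 3.7
        amp = np.sqrt(2 * var * (1 - a**2) / tau_c)
        base = bd.LinearGaussianModel(
            np.array([[1.0, a], [a, 1.0]]) / tau_c, [amp, amp], 0
        )
        scaled = bd.LinearGaussianModel(
            np.array([[1.0, a / c], [a * c, 1.0]]) / tau_c, [amp, c * amp], 0
        )
        taus = np.linspace(0, 4 * tau_c, 20)
        for tau in taus:
            cb = (linalg.expm(-base.dynamics * tau) @ base.stationary_cov())[0, 0]
            cs = (linalg.expm(-scaled.dynamics * tau) @ scaled.stationary_cov())[0, 0]
            assert cb == pytest.approx(cs, rel=1e-10)


class TestSimulateLinear:
    def test_d1_reduces_to_ou(self):
        tau_c, var, dt = 2.0, 1.5, 0.2
        model = bd.LinearGaussianModel(
            [[1 / tau_c]], [np.sqrt(2 * var / tau_c)], 0
        )
        ts = bd.simulate_linear(model, dt=dt, n=2 * 10**5, seed=21)
        assert ts.values.var() == pytest.approx(var, rel=0.05)
        rho = lag_corr(ts.values, 1) / ts.values.var()
        assert rho == pytest.approx(np.exp(-dt / tau_c), abs=0.01)

    def test_observed_coordinate_of_d3_system(self):
        # one coordinate of a diagonal 3-variable system is itself OU
        rates = np.array([1 / 4, 1 / 32, 1 / 256])
        model = bd.LinearGaussianModel(np.diag(rates), np.sqrt(2 * rates / 3), 1)
        ts = bd.simulate_linear(model, dt=1.0, n=4 * 10**5, seed=8)
        assert ts.values.var() == pytest.approx(1 / 3, rel=0.05)
        rho = lag_corr(ts.values, 32) / ts.values.var()
        assert rho == pytest.approx(np.exp(-1), abs=0.03)

    def test_three_mode_sum_matches_mixture(self):
        # equal-weight sum of three independent modes with rates 1/4, 1/32,
        # 1/256 per step has the three-exponential mixture correlation
        # (oracle: stationary Lyapunov variances 1/3 per mode)
        rates = np.array([1 / 4, 1 / 32, 1 / 256])
        amps = np.sqrt(2 * rates / 3)  # each mode has stationary variance 1/3
        n, dt = 10**6, 1.0
        total = np.zeros(n)
        for i, (rate, amp) in enumerate(zip(rates, amps)):
            model = bd.LinearGaussianModel([[rate]], [amp], 0)
            total += bd.simulate_linear(model, dt=dt, n=n, seed=100 + i).values
        mix = bd.ExpMixtureCorr([1 / 3] * 3, 1 / rates)
        for lag in (0, 4, 32, 128):
            got = lag_corr(total, lag)
            se = np.sqrt(2 * 256 / n)  # dominated by the slowest mode
            assert abs(got - mix.at(float(lag))) < 4 * se

    def test_unstable_drift_rejected(self):
        with pytest.raises(StabilityError):
            bd.LinearGaussianModel([[-0.1]], [1.0], 0)


class TestSimulatePowerlaw:
    def test_across_draw_covariance(self, powerlaw_half):
        n, n_draws = 64, 10**4
        draws = bd.simulate_powerlaw_ensemble(powerlaw_half, 1.0, n, n_draws, seed=17)
        emp = draws.T @ draws / n_draws
        lags = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        theo = powerlaw_half.at(lags.astype(float))
        # entrywise MC error ~ sqrt((1 + c^2)/n_draws) <= sqrt(2/n_draws)
        assert np.abs(emp - theo).max() < 5 * np.sqrt(2 / n_draws)

    def test_single_draw_variance(self, powerlaw_half):
        n, n_draws = 32, 4000
        draws = bd.simulate_powerlaw_ensemble(powerlaw_half, 1.0, n, n_draws, seed=2)
        assert draws.var() == pytest.approx(1.0, rel=0.05)
        # lag-4 across-draw correlation: 1/(1 + 4^0.5) = 1/3
        c4 = (draws[:, :-4] * draws[:, 4:]).mean()
        assert c4 == pytest.approx(1 / 3, abs=0.05)

    def test_returns_timeseries(self, powerlaw_half):
        ts = bd.simulate_powerlaw(powerlaw_half, dt=1.0, n=128, seed=1)
        assert len(ts) == 128 and ts.dt == 1.0

    def test_alpha_out_of_range(self):
        with pytest.raises(ParameterError):
            bd.PowerLawCorr(variance=1.0, t0=1.0, alpha=2.5)


class TestEstimateCorr:
    def test_constant_series_is_zero(self):
        ts = bd.TimeSeries(values=np.full(1000, 3.2), dt=1.0)
        corr = bd.estimate_corr(ts, 10)
        assert np.allclose(corr.values, 0.0)

    def test_white_noise_decorrelated(self):
        n = 10**5
        rng = np.random.default_rng(0)
        ts = bd.TimeSeries(values=rng.standard_normal(n), dt=1.0)
        corr = bd.estimate_corr(ts, 20)
        assert np.abs(corr.values[1:]).max() < 3 / np.sqrt(n)
        assert corr.n_samples_per_lag[0] == n

    def test_ou_series_matches_analytic(self):
        n = 10**6
        ts = bd.simulate_ou(tau_c=10.0, variance=1.0, dt=1.0, n=n, seed=13)
        corr = bd.estimate_corr(ts, 30)
        se = np.sqrt(2 * 10 / n)
        for lag in (0, 10, 20):
            assert abs(corr.values[lag] - np.exp(-lag / 10)) < 4 * se

    def test_max_lag_guard(self):
        ts = bd.TimeSeries(values=np.arange(100.0), dt=1.0)
        with pytest.raises(SizeError):
            bd.estimate_corr(ts, 40)

    def test_grid_lookup_guard(self):
        corr = bd.CorrFunction(lags=np.arange(5.0), values=np.exp(-np.arange(5.0)))
        with pytest.raises(CoverageError):
            corr.at(10.0)


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=10, deadline=None)
def test_seed_determinism(seed):
    a = bd.simulate_ou(1.0, 1.0, 0.1, 500, seed=seed)
    b = bd.simulate_ou(1.0, 1.0, 0.1, 500, seed=seed)
    assert np.array_equal(a.values, b.values)
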