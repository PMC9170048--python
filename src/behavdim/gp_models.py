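"""Gaussian-process models of behavioral trajectories.

A scalar behavioral observable x(t) is modeled as a stationary Gaussian
process.  The canonical examples are

* the Ornstein-Uhlenbeck (OU) process
  ``tau_c dx/dt = -x + eta``, with white noise eta, whose autocorrelation is a
  single exponential ``C(tau) = <x^2> exp(-|tau|/tau_c)``;
* a two-variable relaxation in which the observable x is symmetrically
  coupled (strength ``a``) to a hidden variable y, giving a correlation that
  is a mixture of two exponentials with rates ``(1 +/- a)/tau_c``;
* a general D-dimensional linear-Gaussian system, of which one coordinate is
  observed;
* a Gaussian process with power-law correlation
  ``C(tau) = <x^2> t0^alpha / (t0^alpha + |tau|^alpha)``, the standard example
  of behavior whose effective dimensionality grows without bound.

All simulators use *exact* discretization (AR(1) coefficients / matrix
exponentials with noise covariances from the Lyapunov relation), so sample
statistics can be compared directly to the continuous-time formulas without
dt-bias, and every simulator draws its initial condition from the stationary
distribution -- no burn-in is required.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy import linalg, signal

from .errors import (
    CoverageError,
    ModelError,
    ParameterError,
    SizeError,
    StabilityError,
)

__all__ = [
    "TimeSeries",
    "ExpMixtureCorr",
    "PowerLawCorr",
    "WhiteNoiseCorr",
    "LinearGaussianModel",
    "CorrFunction",
    "CorrModel",
    "simulate_ou",
    "simulate_2d",
    "simulate_linear",
    "simulate_powerlaw",
    "simulate_powerlaw_ensemble",
    "corr_ou_analytic",
    "corr_2d_analytic",
    "estimate_corr",
]

# Relative diagonal jitter ladder used to repair marginally non-PD power-law
# covariances before giving up (capped at 1e-8 of the variance).
_JITTER_LADDER = (0.0, 1e-12, 1e-10, 1e-8)


@dataclass(frozen=True)
class TimeSeries:
    """A uniformly sampled scalar trajectory.

    Parameters
    ----------
    values : ndarray
        The observable x(t) (or a +/-1 spin sequence cast to float).
    dt : float
        Sampling step, strictly positive.
    seed : int, optional
        Seed used to generate the trajectory, kept as a provenance record.
    """

    values: np.ndarray
    dt: float
    seed: Optional[int] = None

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size < 2:
            raise SizeError("a time series needs at least 2 scalar samples")
        if not np.all(np.isfinite(values)):
            raise ParameterError("time series contains non-finite values")
        if not (self.dt > 0):
            raise ParameterError(f"dt must be positive, got {self.dt}")

    def __len__(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) * self.dt


@dataclass(frozen=True)
class ExpMixtureCorr:
    """Autocorrelation that is a finite mixture of decaying exponentials.

    ``C(tau) = sum_mu A_mu exp(-|tau|/tau_mu)`` with all amplitudes positive
    and timescales strictly increasing.  ``C(0)`` equals the process variance
    ``sum(A_mu)``.  This is the signature of finite-dimensional linear
    Gaussian dynamics: k terms <=> k dynamical variables.
    """

    amplitudes: np.ndarray
    timescales: np.ndarray

    def __post_init__(self):
        amps = np.atleast_1d(np.asarray(self.amplitudes, dtype=float))
        taus = np.atleast_1d(np.asarray(self.timescales, dtype=float))
        object.__setattr__(self, "amplitudes", amps)
        object.__setattr__(self, "timescales", taus)
        if amps.shape != taus.shape or amps.ndim != 1 or amps.size == 0:
            raise ParameterError("amplitudes and timescales must be matching 1-d sequences")
        if np.any(taus <= 0):
            raise ParameterError("all timescales must be positive")
        if np.any(np.diff(taus) <= 0):
            raise ParameterError("timescales must be strictly increasing")
        if np.any(amps <= 0):
            raise ParameterError("all amplitudes must be positive")

    @property
    def variance(self) -> float:
        return float(self.amplitudes.sum())

    def at(self, tau) -> np.ndarray:
        tau = np.abs(np.asarray(tau, dtype=float))
        return (self.amplitudes * np.exp(-tau[..., None] / self.timescales)).sum(axis=-1)


@dataclass(frozen=True)
class PowerLawCorr:
    """Power-law autocorrelation ``<x^2> t0^a / (t0^a + |tau|^a)``.

    Strictly positive, strictly decreasing in |tau|; the exponent ``alpha``
    must lie in (0, 2).  Processes with this correlation have a past-future
    kernel whose rank grows without bound with the analysis window.
    """

    variance: float
    t0: float
    alpha: float

    def __post_init__(self):
        if not (self.variance > 0):
            raise ParameterError("variance must be positive")
        if not (self.t0 > 0):
            raise ParameterError("t0 must be positive")
        if not (0.0 < self.alpha < 2.0):
            raise ParameterError("alpha must lie in (0, 2)")

    def at(self, tau) -> np.ndarray:
        tau = np.abs(np.asarray(tau, dtype=float))
        t0a = self.t0**self.alpha
        return self.variance * t0a / (t0a + tau**self.alpha)


@dataclass(frozen=True)
class WhiteNoiseCorr:
    """Delta correlation: ``C(0) = variance`` and zero at every other lag."""

    variance: float

    def __post_init__(self):
        if not (self.variance > 0):
            raise ParameterError("variance must be positive")

    def at(self, tau) -> np.ndarray:
        tau = np.asarray(tau, dtype=float)
        return np.where(tau == 0.0, self.variance, 0.0)


@dataclass(frozen=True)
class LinearGaussianModel:
    """A D-variable linear stochastic system with one observed coordinate.

    dx/dt = -dynamics @ x + eta,  <eta_i(t) eta_j(t')> = noise_amplitudes[i]^2
    delta_ij delta(t - t').  Stationarity requires every eigenvalue of
    ``dynamics`` to have positive real part.  Driving noises are white and
    mutually independent by construction; the simulator never introduces
    cross- or temporal noise correlations.
    """

    dynamics: np.ndarray
    noise_amplitudes: np.ndarray
    observed_index: int = 0

    def __post_init__(self):
        dyn = np.atleast_2d(np.asarray(self.dynamics, dtype=float))
        amps = np.atleast_1d(np.asarray(self.noise_amplitudes, dtype=float))
        object.__setattr__(self, "dynamics", dyn)
        object.__setattr__(self, "noise_amplitudes", amps)
        d = dyn.shape[0]
        if dyn.shape != (d, d):
            raise ParameterError("dynamics must be a square matrix")
        if amps.shape != (d,):
            raise ParameterError("need one noise amplitude per coordinate")
        if np.any(amps < 0):
            raise ParameterError("noise amplitudes must be non-negative")
        if not (0 <= self.observed_index < d):
            raise ParameterError("observed_index out of range (0-based)")
        eig = np.linalg.eigvals(dyn)
        if np.any(eig.real <= 0):
            raise StabilityError(
                "drift matrix has a non-decaying mode (eigenvalue with "
                f"real part <= 0: {eig[eig.real <= 0]})"
            )

    @property
    def dim(self) -> int:
        return self.dynamics.shape[0]

    def stationary_cov(self) -> np.ndarray:
        """Stationary covariance from the continuous Lyapunov relation
        ``B S + S B^T = diag(amp^2)``."""
        q = np.diag(self.noise_amplitudes**2)
        return linalg.solve_continuous_lyapunov(self.dynamics, q)


@dataclass(frozen=True)
class CorrFunction:
    """Correlation values on a grid of non-negative lags.

    Either an exact evaluation of an analytic model or an estimate from data
    (in which case ``n_samples_per_lag`` records how many products entered
    each lag).  Invariants: lags strictly increasing starting at 0;
    ``|C(tau)| <= C(0)`` (Cauchy-Schwarz).
    """

    lags: np.ndarray
    values: np.ndarray
    n_samples_per_lag: Optional[np.ndarray] = None

    def __post_init__(self):
        lags = np.asarray(self.lags, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "values", values)
        if lags.shape != values.shape or lags.ndim != 1 or lags.size == 0:
            raise ParameterError("lags and values must be matching 1-d sequences")
        if lags[0] != 0.0 or np.any(np.diff(lags) <= 0):
            raise ParameterError("lags must start at 0 and increase strictly")
        if values[0] < 0:
            raise ParameterError("C(0) must be non-negative")
        if np.any(np.abs(values[1:]) > values[0] * (1 + 1e-9) + 1e-300):
            raise ParameterError("|C(tau)| must not exceed C(0) (Cauchy-Schwarz)")

    @property
    def variance(self) -> float:
        return float(self.values[0])

    def at(self, tau) -> np.ndarray:
        """Look up values on the stored grid (nearest-grid matching).

        Raises CoverageError for lags beyond the grid; off-grid lags must be
        within 1e-6 relative of a grid point.
        """
        tau = np.abs(np.asarray(tau, dtype=float))
        if np.any(tau > self.lags[-1] * (1 + 1e-9)):
            raise CoverageError(
                f"requested lag {tau.max():g} exceeds grid maximum {self.lags[-1]:g}"
            )
        step = self.lags[1] - self.lags[0] if self.lags.size > 1 else 1.0
        idx = np.clip(np.rint(tau / step).astype(int), 0, self.lags.size - 1)
        if np.any(np.abs(self.lags[idx] - tau) > 1e-6 * max(step, 1e-30)):
            raise CoverageError("requested lags do not lie on the correlation grid")
        return self.values[idx]


#: Anything build_covariance and the information routines accept.
CorrModel = Union[ExpMixtureCorr, PowerLawCorr, WhiteNoiseCorr, CorrFunction]


# ---------------------------------------------------------------------------
# analytic correlation functions
# ---------------------------------------------------------------------------

def corr_ou_analytic(tau_c: float, variance: float) -> ExpMixtureCorr:
    """Autocorrelation of the OU process: a single exponential
    ``C(tau) = variance * exp(-|tau|/tau_c)``."""
    if not (tau_c > 0 and variance > 0):
        raise ParameterError("tau_c and variance must be positive")
    return ExpMixtureCorr(amplitudes=[variance], timescales=[tau_c])


def corr_2d_analytic(tau_c: float, a: float, variance: float) -> ExpMixtureCorr:
    """Autocorrelation of the symmetric two-variable model.

    ``C(tau) = A+ exp(-(1+a)|tau|/tau_c) + A- exp(-(1-a)|tau|/tau_c)`` with
    ``A+- = variance (1 - a^2) / (2 (1 +- a))``; the amplitudes sum to the
    variance.  The fast timescale ``tau_c/(1+a)`` captures the rough
    small-scale movements, the slow one ``tau_c/(1-a)`` the smooth drift.
    """
    if not (tau_c > 0 and variance > 0):
        raise ParameterError("tau_c and variance must be positive")
    if abs(a) >= 1:
        raise StabilityError(f"|a| must be < 1 for a stable model, got a={a}")
    if a == 0:
        raise ModelError(
            "a=0 collapses the two timescales; use corr_ou_analytic instead"
        )
    a_plus = 0.5 * variance * (1 - a**2) / (1 + a)
    a_minus = 0.5 * variance * (1 - a**2) / (1 - a)
    tau_fast = tau_c / (1 + abs(a))
    tau_slow = tau_c / (1 - abs(a))
    if a > 0:
        amps = [a_plus, a_minus]
    else:  # a<0 swaps which rate is the fast one
        amps = [a_minus, a_plus]
    return ExpMixtureCorr(amplitudes=amps, timescales=[tau_fast, tau_slow])


# ---------------------------------------------------------------------------
# simulators
# ---------------------------------------------------------------------------

def _check_sim_args(dt: float, n: int):
    if not (dt > 0):
        raise ParameterError(f"dt must be positive, got {dt}")
    if n < 2:
        raise SizeError(f"need at least 2 samples, got n={n}")


def simulate_ou(
    tau_c: float, variance: float, dt: float, n: int, seed: int
) -> TimeSeries:
    """Draw a stationary OU trajectory of length ``n``.

    Uses the exact discrete-time update ``x[k+1] = rho x[k] + sqrt(var (1 -
    rho^2)) z[k]`` with ``rho = exp(-dt/tau_c)``, initial point from the
    stationary distribution N(0, var).
    """
    if not (tau_c > 0 and variance > 0):
        raise ParameterError("tau_c and variance must be positive")
    _check_sim_args(dt, n)
    rng = np.random.default_rng(seed)
    rho = np.exp(-dt / tau_c)
    z = rng.standard_normal(n)
    drive = np.empty(n)
    drive[0] = np.sqrt(variance) * z[0]
    drive[1:] = np.sqrt(variance * (1 - rho**2)) * z[1:]
    x = signal.lfilter([1.0], [1.0, -rho], drive)
    return TimeSeries(values=x, dt=dt, seed=seed)


def simulate_linear(
    model: LinearGaussianModel, dt: float, n: int, seed: int
) -> TimeSeries:
    """Draw the observed coordinate of a stationary D-variable linear system.

    The discretization is exact for linear drift: the one-step propagator is
    ``F = expm(-B dt)`` and the per-step noise covariance is ``Q = S - F S
    F^T`` with S the stationary covariance from the continuous Lyapunov
    relation.  The recursion is run per eigenmode of F with an AR(1) filter.
    """
    _check_sim_args(dt, n)
    rng = np.random.default_rng(seed)
    d = model.dim
    big_s = model.stationary_cov()
    f = linalg.expm(-model.dynamics * dt)
    q = big_s - f @ big_s @ f.T
    q = 0.5 * (q + q.T)

    x0 = _psd_factor(big_s) @ rng.standard_normal(d)
    w = rng.standard_normal((n - 1, d)) @ _psd_factor(q).T

    lam, v = np.linalg.eig(f)
    if np.linalg.cond(v) < 1e8:
        # decouple into eigenmodes; each is an AR(1) run by lfilter
        u = np.empty((n, d), dtype=complex)
        u[0] = np.linalg.solve(v, x0)
        u[1:] = np.linalg.solve(v, w.T).T
        m = np.empty_like(u)
        for i in range(d):
            m[:, i] = signal.lfilter([1.0], [1.0, -lam[i]], u[:, i])
        x = (v @ m.T).T.real
    else:  # defective propagator: fall back to the direct recursion
        x = np.empty((n, d))
        x[0] = x0
        for k in range(1, n):
            x[k] = f @ x[k - 1] + w[k - 1]
    return TimeSeries(values=x[:, model.observed_index], dt=dt, seed=seed)


def simulate_2d(
    tau_c: float, a: float, variance: float, dt: float, n: int, seed: int
) -> TimeSeries:
    """Draw x(t) from the two-variable model with hidden y(t).

    The drift is ``(1/tau_c) [[1, a], [a, 1]]`` and both coordinates are
    driven by independent white noises of equal strength ``2 tau_c variance
    (1 - a^2)`` (spectral density), so that ``<x^2> = variance``.  Only the
    observable x is returned.
    """
    if abs(a) >= 1:
        raise StabilityError(f"|a| must be < 1 for stability, got a={a}")
    if not (tau_c > 0 and variance > 0):
        raise ParameterError("tau_c and variance must be positive")
    amp = np.sqrt(2 * variance * (1 - a**2) / tau_c)
    model = LinearGaussianModel(
        dynamics=np.array([[1.0, a], [a, 1.0]]) / tau_c,
        noise_amplitudes=[amp, amp],
        observed_index=0,
    )
    return simulate_linear(model, dt=dt, n=n, seed=seed)


def _psd_factor(mat: np.ndarray) -> np.ndarray:
    """Symmetric square-root factor of a PSD matrix, tolerant of tiny
    negative eigenvalues from roundoff."""
    evals, evecs = np.linalg.eigh(0.5 * (mat + mat.T))
    floor = -1e-10 * max(evals.max(), 1.0)
    if evals.min() < floor:
        raise ModelError(
            f"matrix is not positive semidefinite (min eigenvalue {evals.min():.3e})"
        )
    return evecs * np.sqrt(np.clip(evals, 0.0, None))


def _powerlaw_chol(corr: PowerLawCorr, dt: float, n: int) -> np.ndarray:
    cov = linalg.toeplitz(corr.at(np.arange(n) * dt))
    for jit in _JITTER_LADDER:
        try:
            chol = np.linalg.cholesky(cov + jit * corr.variance * np.eye(n))
        except np.linalg.LinAlgError:
            continue
        if jit > 0:
            warnings.warn(
                f"power-law covariance needed diagonal jitter {jit:g}*variance "
                "to factorize",
                stacklevel=3,
            )
        return chol
    min_eig = float(np.linalg.eigvalsh(cov).min())
    raise ModelError(
        "power-law covariance is not positive definite even after maximum "
        f"jitter {_JITTER_LADDER[-1]:g}*variance (smallest eigenvalue {min_eig:.3e})"
    )


def simulate_powerlaw(corr: PowerLawCorr, dt: float, n: int, seed: int) -> TimeSeries:
    """Exact finite-window draw from the power-law Gaussian process.

    Builds the full n x n covariance, factorizes it (Cholesky, with a small
    documented diagonal jitter ladder up to 1e-8*variance if the factorization
    fails numerically) and multiplies standard normal draws.  Memory is
    O(n^2): keep n at a few thousand.
    """
    _check_sim_args(dt, n)
    rng = np.random.default_rng(seed)
    chol = _powerlaw_chol(corr, dt, n)
    x = chol @ rng.standard_normal(n)
    return TimeSeries(values=x, dt=dt, seed=seed)


def simulate_powerlaw_ensemble(
    corr: PowerLawCorr, dt: float, n: int, n_draws: int, seed: int
) -> np.ndarray:
    """Many independent exact draws (rows) sharing one factorization."""
    _check_sim_args(dt, n)
    if n_draws < 1:
        raise SizeError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    chol = _powerlaw_chol(corr, dt, n)
    return rng.standard_normal((n_draws, n)) @ chol.T


# ---------------------------------------------------------------------------
# estimation
# ---------------------------------------------------------------------------

def estimate_corr(ts: TimeSeries, max_lag: int) -> CorrFunction:
    """Estimate the autocorrelation of a trajectory up to ``max_lag`` steps.

    Mean-subtracted, biased (divide-by-n) estimator: the 1/n normalization
    guarantees a positive-semidefinite correlation sequence, which downstream
    kernel inversion requires.  ``max_lag`` must be below length/4 for the
    estimates to be usable.  Computed by FFT.
    """
    n = len(ts)
    if not (0 <= max_lag < n / 4):
        raise SizeError(f"max_lag must satisfy 0 <= max_lag < n/4 = {n / 4:g}")
    x = ts.values - ts.values.mean()
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    spec = np.abs(np.fft.rfft(x, nfft)) ** 2
    acov = np.fft.irfft(spec)[: max_lag + 1] / n
    counts = n - np.arange(max_lag + 1)
    return CorrFunction(
        lags=np.arange(max_lag + 1) * ts.dt,
        values=acov,
        n_samples_per_lag=counts,
    )
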