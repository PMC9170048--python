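"""Two-state behavioral sequences: Ising chains and maximum-entropy fits.

A binary behavioral state at discrete clock ticks is an Ising variable
``sigma_t = +/-1``.  The pairwise maximum-entropy (maximum-caliber) model
consistent with an observed mean ``<sigma>`` and connected correlations
``C(tau)`` up to range R is

    P({sigma_t}) = (1/Z) exp[ h sum_t sigma_t
                              + sum_t sum_{tau=1..R} J(tau) sigma_t sigma_{t-tau} ]

(each lag counted once, so R=1 with coupling J is the nearest-neighbor chain
with energy ``h sum sigma + J sum sigma_{t-1} sigma_t``).  All exact
computations use the stationary infinite-chain limit obtained from the
leading eigenpair of the 2^R-state transfer matrix; sampling is exact
sequential draws from the induced Markov chain (no MCMC, no burn-in).

Markov (R=1) chains have correlations decaying as a single exponential with
correlation time ``tau_c = 1/ln(lambda_1/|lambda_2|)`` in clock ticks
(``-1/ln tanh J`` at h=0); correlations that are *not* a single exponential
require couplings beyond lag 1, i.e. hidden variables carrying memory.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import linalg, optimize, sparse
import scipy.sparse.linalg  # noqa: F401  (sparse.linalg.eigs)

from .errors import CapacityError, FitError, ParameterError, SizeError
from .gp_models import CorrFunction

__all__ = [
    "SpinSequence",
    "IsingChain",
    "TransferMatrixSolution",
    "sample_ising_nn",
    "sample_ising_general",
    "ising_corr",
    "ising_tau_c",
    "fit_maxent_pairwise",
    "enumerate_ring_moments",
]

_MAX_RANGE = 12  # 2^12 = 4096 transfer-matrix states; beyond this, sample.


@dataclass(frozen=True)
class SpinSequence:
    """A sequence of +/-1 behavioral states at discrete clock ticks."""

    spins: np.ndarray
    dt: float = 1.0

    def __post_init__(self):
        s = np.asarray(self.spins)
        if s.ndim != 1 or s.size < 2:
            raise SizeError("need at least 2 spins")
        s = s.astype(np.int8, copy=False)
        if not np.all(np.abs(s) == 1):
            raise ParameterError("spins must be exactly +1 or -1")
        object.__setattr__(self, "spins", s)
        if not (self.dt > 0):
            raise ParameterError("dt must be positive")

    def __len__(self) -> int:
        return self.spins.size


@dataclass(frozen=True)
class IsingChain:
    """Field h and couplings J(1..R) of a finite-range Ising chain."""

    h: float
    couplings: np.ndarray

    def __post_init__(self):
        j = np.atleast_1d(np.asarray(self.couplings, dtype=float))
        object.__setattr__(self, "couplings", j)
        if j.ndim != 1 or j.size < 1:
            raise ParameterError("couplings must be a non-empty 1-d sequence J(1..R)")

    @property
    def range(self) -> int:
        return self.couplings.size


# ---------------------------------------------------------------------------
# transfer matrix machinery
# ---------------------------------------------------------------------------

def _check_range(r: int):
    if r > _MAX_RANGE:
        raise CapacityError(
            f"exact transfer-matrix computation supports range <= {_MAX_RANGE} "
            f"(2^{_MAX_RANGE} states); got R={r}.  Use sampling instead."
        )


def _spin_of_bit(bits: np.ndarray) -> np.ndarray:
    return 2.0 * bits - 1.0


class TransferMatrixSolution:
    """Eigen-solution of the 2^R-state transfer matrix of an Ising chain.

    State s encodes the block (sigma_{t-R+1}, ..., sigma_t) as R bits, the
    most recent spin in the lowest bit.  T[s, s'] is the Boltzmann weight of
    appending the new spin of s' given block s.  Left/right leading
    eigenvectors give stationary infinite-chain moments; the eigenvalue
    ratio gives the correlation time.
    """

    #: state count above which the leading eigenpair is found with a sparse
    #: Arnoldi solver instead of a dense full eigendecomposition
    _DENSE_LIMIT = 256

    def __init__(self, model: IsingChain):
        _check_range(model.range)
        r = model.range
        n_states = 1 << r
        self.model = model
        self.n_states = n_states
        states = np.arange(n_states)
        mask = n_states - 1
        # local field the block exerts on the appended spin:
        # sum_tau J(tau) * sigma_{t+1-tau}; lag tau spin sits in bit tau-1
        local = np.zeros(n_states)
        for tau in range(1, r + 1):
            local += model.couplings[tau - 1] * _spin_of_bit((states >> (tau - 1)) & 1)
        self._next0 = (states << 1) & mask
        self._next1 = self._next0 | 1
        self._w_up = np.exp(model.h + local)  # weight for appending +1
        self._w_dn = np.exp(-(model.h + local))
        self.t_mat = sparse.csr_matrix(
            (
                np.concatenate([self._w_dn, self._w_up]),
                (
                    np.concatenate([states, states]),
                    np.concatenate([self._next0, self._next1]),
                ),
            ),
            shape=(n_states, n_states),
        )
        if n_states <= self._DENSE_LIMIT:
            dense = self.t_mat.toarray()
            evals, vl, vr = linalg.eig(dense, left=True, right=True)
            order = np.argsort(-np.abs(evals))
            evals, vl, vr = evals[order], vl[:, order], vr[:, order]
            lam1, right, left = evals[0], vr[:, 0].real, vl[:, 0].real
            self.eigenvalues = evals
        else:
            # deterministic start vector: ARPACK's default v0 depends on the
            # global RNG state, which would make exact fits irreproducible
            v0 = np.full(n_states, 1.0 / n_states)
            evals, vr = sparse.linalg.eigs(self.t_mat, k=2, which="LM", v0=v0)
            order = np.argsort(-np.abs(evals))
            evals, vr = evals[order], vr[:, order]
            evals_l, vl = sparse.linalg.eigs(self.t_mat.T, k=1, which="LM", v0=v0)
            lam1, right, left = evals[0], vr[:, 0].real, vl[:, 0].real
            self.eigenvalues = evals
        if abs(lam1.imag) > 1e-12 * abs(lam1):
            raise FitError("leading transfer-matrix eigenvalue is not real")
        if right.sum() < 0:
            right = -right
        if left.sum() < 0:
            left = -left
        self.lam1 = float(lam1.real)
        self.right = right
        self.left = left
        self.spin_op = _spin_of_bit(states & 1)  # sigma_t of each block

    # stationary distribution over block states
    @property
    def stationary(self) -> np.ndarray:
        p = np.clip(self.left * self.right, 0.0, None)
        return p / p.sum()

    def mean_spin(self) -> float:
        """Stationary <sigma> in the infinite-chain limit."""
        return float(self.stationary @ self.spin_op)

    def step_probs(self) -> Tuple[np.ndarray, np.ndarray]:
        """Per-state probabilities (p_down, p_up) of the appended spin in the
        transfer-matrix-induced Markov chain:
        ``P[s -> s'] = T[s, s'] r[s'] / (lambda_1 r[s])``."""
        r = self.right
        p0 = self._w_dn * r[self._next0] / (self.lam1 * r)
        p1 = self._w_up * r[self._next1] / (self.lam1 * r)
        total = p0 + p1  # exactly 1 up to roundoff, since T r = lambda r
        return p0 / total, p1 / total

    def raw_corr(self, max_lag: int) -> np.ndarray:
        """Raw <sigma_t sigma_{t+tau}> for tau = 0..max_lag, by propagating
        the sigma-weighted stationary measure through the induced chain."""
        p = self.stationary
        out = np.empty(max_lag + 1)
        out[0] = float(p @ (self.spin_op**2))
        p0, p1 = self.step_probs()
        vec = p * self.spin_op
        for tau in range(1, max_lag + 1):
            nxt = np.zeros_like(vec)
            np.add.at(nxt, self._next0, vec * p0)
            np.add.at(nxt, self._next1, vec * p1)
            vec = nxt
            out[tau] = float(vec @ self.spin_op)
        return out


def _solution(model: IsingChain) -> TransferMatrixSolution:
    return TransferMatrixSolution(model)


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def sample_ising_general(model: IsingChain, n: int, seed: int) -> SpinSequence:
    """Exact stationary sample of length n from a finite-range Ising chain.

    The first R spins are drawn from the stationary block distribution, then
    each spin from the exact conditional of the transfer-matrix-induced
    Markov chain.  No burn-in is needed.
    """
    if n < 2:
        raise SizeError("need n >= 2")
    sol = _solution(model)
    r = model.range
    n_states = sol.n_states
    rng = np.random.default_rng(seed)
    # probability that the appended spin is +1, given the current block
    _, p_up = sol.step_probs()

    total = max(n, r)
    spins = np.empty(total, dtype=np.int8)
    state = int(rng.choice(n_states, p=sol.stationary))
    for k in range(r):
        spins[r - 1 - k] = 1 if (state >> k) & 1 else -1
    u = rng.random(total)
    for t in range(r, total):
        bit = 1 if u[t] < p_up[state] else 0
        spins[t] = 1 if bit else -1
        state = ((state << 1) & (n_states - 1)) | bit
    return SpinSequence(spins=spins[:n])


def sample_ising_nn(h: float, j: float, n: int, seed: int) -> SpinSequence:
    """Exact sample of the nearest-neighbor chain
    ``P ~ exp(h sum sigma + J sum sigma_{t-1} sigma_t)``."""
    return sample_ising_general(IsingChain(h=h, couplings=[j]), n=n, seed=seed)


def ising_corr(model: IsingChain, max_lag: int) -> CorrFunction:
    """Exact connected correlation ``C(tau) = <sigma_t sigma_{t+tau}> -
    <sigma>^2`` for tau = 0..max_lag, in the stationary infinite-chain limit.
    """
    if max_lag < 0:
        raise SizeError("max_lag must be >= 0")
    sol = _solution(model)
    mean = sol.mean_spin()
    raw = sol.raw_corr(max_lag)
    connected = raw - mean**2
    # clip roundoff that would violate |C| <= C(0)
    c0 = connected[0]
    connected = np.clip(connected, -c0, c0)
    return CorrFunction(lags=np.arange(max_lag + 1, dtype=float), values=connected)


def ising_tau_c(model: IsingChain) -> float:
    """Correlation time in clock ticks from the two leading transfer-matrix
    eigenvalues: ``tau_c = 1 / ln(lambda_1 / |lambda_2|)``.

    Returns 0 for a memoryless chain (lambda_2 = 0, e.g. J = 0).  For R=1 and
    h=0 this reduces to the closed form ``-1/ln tanh J``.
    """
    sol = _solution(model)
    lam2 = abs(sol.eigenvalues[1]) if sol.n_states > 1 else 0.0
    if lam2 <= 1e-14 * sol.lam1:
        return 0.0
    return float(1.0 / np.log(sol.lam1 / lam2))


def fit_maxent_pairwise(
    mean: float,
    corr: CorrFunction,
    range: int,
    tol: float = 1e-10,
    max_iter: int = 200,
) -> IsingChain:
    """Fit the pairwise maximum-entropy chain to a mean and correlations.

    Finds (h, J(1..R)) such that the stationary model reproduces the target
    ``<sigma>`` and connected ``C(1..R)`` within ``tol`` (sup-norm).  The
    moment-matching equations are solved by damped root-finding on the
    residuals, with model moments computed exactly by transfer matrix; the
    problem is the convex dual of entropy maximization, so the solution is
    unique when the targets are realizable.
    """
    if not (abs(mean) < 1):
        raise ParameterError("|mean| must be < 1 for a realizable binary sequence")
    _check_range(range)
    if range < 1:
        raise ParameterError("range must be >= 1")
    if corr.lags.size < range + 1:
        raise ParameterError(f"need correlations out to lag {range}")
    target = np.concatenate([[mean], corr.values[1 : range + 1]])

    def residual(theta: np.ndarray) -> np.ndarray:
        model = IsingChain(h=theta[0], couplings=theta[1:])
        sol = _solution(model)
        m = sol.mean_spin()
        c = sol.raw_corr(range)[1:] - m**2
        return np.concatenate([[m], c]) - target

    x0 = np.concatenate([[np.arctanh(np.clip(mean, -0.999, 0.999))], np.zeros(range)])
    # trust-region least squares on the residuals: damped steps keep the
    # iterates in the region where the transfer-matrix map is well behaved
    sol = optimize.least_squares(
        residual, x0, method="trf", xtol=1e-15, ftol=1e-15, gtol=1e-15,
        max_nfev=200 * (range + 1),
    )
    res = residual(sol.x)
    if np.max(np.abs(res)) > tol:
        raise FitError(
            "maximum-entropy fit did not reach tolerance "
            f"{tol:g}; residuals {res} (targets may not be realizable)"
        )
    return IsingChain(h=float(sol.x[0]), couplings=sol.x[1:].copy())


# ---------------------------------------------------------------------------
# independent brute-force oracle (ring geometry)
# ---------------------------------------------------------------------------

def enumerate_ring_moments(
    model: IsingChain, n: int, max_lag: int
) -> Tuple[float, np.ndarray]:
    """Exhaustive mean and raw correlations on a periodic chain of n spins.

    Sums Boltzmann weights over all 2^n sequences directly; intended as an
    independent check of the transfer-matrix machinery at small n (n <= ~16).
    Returns (mean, raw <sigma_0 sigma_tau> for tau = 0..max_lag).
    """
    if n > 20:
        raise CapacityError("exhaustive enumeration is limited to n <= 20")
    if max_lag >= n:
        raise SizeError("max_lag must be < n on a ring of n spins")
    r = model.range
    states = np.arange(1 << n, dtype=np.int64)
    spins = np.stack(
        [_spin_of_bit(((states >> k) & 1).astype(float)) for k in range(n)], axis=1
    )
    energy = model.h * spins.sum(axis=1)
    for tau in range(1, r + 1):
        energy += model.couplings[tau - 1] * (spins * np.roll(spins, -tau, axis=1)).sum(
            axis=1
        )
    w = np.exp(energy - energy.max())
    z = w.sum()
    mean = float((w @ spins[:, 0]) / z)
    raw = np.empty(max_lag + 1)
    for tau in range(max_lag + 1):
        raw[tau] = float((w @ (spins[:, 0] * spins[:, tau % n])) / z)
    return mean, raw


def ring_transfer_moments(
    model: IsingChain, n: int, max_lag: int
) -> Tuple[float, np.ndarray]:
    """Mean and raw correlations on the same n-spin ring via transfer-matrix
    traces: ``<sigma_0 sigma_tau> = Tr(S T^tau S T^{n-tau}) / Tr(T^n)``.

    Dual route to :func:`enumerate_ring_moments`; the two must agree to
    near machine precision.
    """
    if max_lag >= n:
        raise SizeError("max_lag must be < n on a ring of n spins")
    sol = _solution(model)
    t_mat = sol.t_mat.toarray()
    s_op = np.diag(sol.spin_op)
    powers = [np.eye(sol.n_states)]
    for _ in range(n):
        powers.append(powers[-1] @ t_mat)
    z = np.trace(powers[n])
    mean = float(np.trace(s_op @ powers[n]) / z)
    raw = np.empty(max_lag + 1)
    for tau in range(max_lag + 1):
        raw[tau] = float(np.trace(s_op @ powers[tau] @ s_op @ powers[n - tau]) / z)
    return mean, raw
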