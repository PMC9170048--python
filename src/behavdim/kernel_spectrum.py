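"""Past-future kernel spectra and the spectral definition of dimensionality.

For a stationary Gaussian process observed in a window of 2m samples, the
action is ``S = (1/2) x^T K x`` with ``K = C^{-1}`` the kernel (inverse of the
windowed covariance C).  Splitting the window at its midpoint into past (first
m samples, t <= 0) and future (last m samples, t > 0) block-partitions K; the
off-diagonal block ``K_pf`` is the only coupling between past and future.

Because the process is stationary, the entry of ``K_pf`` linking past time
``-t`` to future time ``t'`` depends (away from window-boundary effects) on
the *sum* ``t + t'``.  Reversing the past axis therefore turns ``K_pf`` into a
symmetric matrix whose eigendecomposition

    K(t + t') = sum_mu a_mu phi_mu(t) phi_mu(t')

yields the coefficients ``a_mu`` and predictive filters ``phi_mu``.  The
number of coefficients distinguishable from zero is the effective
dimensionality of the behavior: the number of linear features of the past
needed to retain all predictive power.  For correlations that are finite
mixtures of exponentials this rank is finite and window-independent; for
power-law correlations it grows without bound as the window lengthens.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import linalg

from .errors import ConditioningError, ModelError, ParameterError, SizeError
from .gp_models import CorrFunction, CorrModel

__all__ = [
    "WindowedKernel",
    "KpfSpectrum",
    "RankReport",
    "build_covariance",
    "invert_to_kernel",
    "kpf_spectrum",
    "effective_rank",
    "rank_vs_window",
    "predictive_filters",
]

#: Default relative eigenvalue threshold separating true rank from the
#: double-precision noise floor (~1e-12..1e-10) in analytic computations.
ANALYTIC_RANK_THRESHOLD = 1e-6
#: Looser threshold recommended for spectra built from estimated correlations,
#: where sampling noise dominates the floor.
ESTIMATED_RANK_THRESHOLD = 1e-2

_MAX_CONDITION = 1e12


@dataclass(frozen=True)
class WindowedKernel:
    """The kernel K = C^{-1} on a window of ``window_len`` samples.

    ``window_len`` = 2m is even; the first m samples are the past, the last m
    the future.  K is symmetric positive definite and satisfies
    ``K @ C = I`` to 1e-8 relative (checked at construction).
    """

    window_len: int
    dt: float
    kernel: np.ndarray

    def __post_init__(self):
        k = np.asarray(self.kernel, dtype=float)
        object.__setattr__(self, "kernel", k)
        if self.window_len % 2 or self.window_len < 2:
            raise SizeError("window_len must be even and >= 2")
        if k.shape != (self.window_len, self.window_len):
            raise ParameterError("kernel shape does not match window_len")
        if not np.allclose(k, k.T, rtol=1e-8, atol=1e-12 * np.abs(k).max()):
            raise ModelError("kernel must be symmetric")

    @property
    def m(self) -> int:
        """Number of past (= future) samples."""
        return self.window_len // 2

    @property
    def k_pp(self) -> np.ndarray:
        return self.kernel[: self.m, : self.m]

    @property
    def k_ff(self) -> np.ndarray:
        return self.kernel[self.m :, self.m :]

    @property
    def k_pf(self) -> np.ndarray:
        return self.kernel[: self.m, self.m :]


@dataclass(frozen=True)
class KpfSpectrum:
    """Eigenvalues ``a_mu`` of the (time-reversed) past-future kernel block.

    Coefficients are sorted by decreasing magnitude (ties broken positive
    first); ``filters`` holds the matching orthonormal eigenvectors
    ``phi_mu`` on the past grid, column mu for coefficient mu, ordered from
    the most recent past sample (t=0) backwards.
    """

    coeffs: np.ndarray
    window_len: int
    filters: Optional[np.ndarray] = None
    estimated_input: bool = False

    def __post_init__(self):
        c = np.asarray(self.coeffs, dtype=float)
        object.__setattr__(self, "coeffs", c)
        if c.ndim != 1 or c.size != self.window_len // 2:
            raise ParameterError("need one coefficient per past sample")
        mags = np.abs(c)
        if np.any(np.diff(mags) > 1e-12 * (mags[0] + 1e-300)):
            raise ParameterError("coefficients must be sorted by decreasing magnitude")


@dataclass(frozen=True)
class RankReport:
    """Effective rank of K_pf as a function of window size."""

    windows: np.ndarray
    ranks: np.ndarray
    threshold: float
    verdict: str  # "finite" | "growing" | "indeterminate"

    def __post_init__(self):
        w = np.asarray(self.windows, dtype=int)
        r = np.asarray(self.ranks, dtype=int)
        object.__setattr__(self, "windows", w)
        object.__setattr__(self, "ranks", r)
        if w.shape != r.shape:
            raise ParameterError("windows and ranks must have the same length")
        if self.verdict not in ("finite", "growing", "indeterminate"):
            raise ParameterError(f"unknown verdict {self.verdict!r}")


# ---------------------------------------------------------------------------


def build_covariance(corr: CorrModel, window_len: int, dt: float) -> np.ndarray:
    """Symmetric Toeplitz covariance with entry (i, j) = C(|i - j| dt).

    ``window_len`` must be even (it will later be split into equal past and
    future halves).  Estimated CorrFunction inputs must cover lags up to
    (window_len - 1) dt and must be numerically positive definite.
    """
    if window_len < 2 or window_len % 2:
        raise SizeError("window_len must be even and >= 2")
    if not (dt > 0):
        raise ParameterError("dt must be positive")
    first_row = np.asarray(corr.at(np.arange(window_len) * dt), dtype=float)
    cov = linalg.toeplitz(first_row)
    if isinstance(corr, CorrFunction):
        min_eig = float(np.linalg.eigvalsh(cov).min())
        if min_eig <= 0:
            raise ConditioningError(
                "estimated correlation gives a non-positive-definite windowed "
                f"covariance (smallest eigenvalue {min_eig:.3e}); shrink or "
                "shorten the window"
            )
    return cov


def invert_to_kernel(cov: np.ndarray, dt: float) -> WindowedKernel:
    """Invert a windowed covariance to the kernel K.

    The discrete kernel is the plain matrix inverse (Kronecker-delta
    normalization); no 1/dt continuum rescaling is applied, since rank and
    relative eigenvalue thresholds are invariant under overall scale.
    Fails with a ConditioningError when cond(C) exceeds 1e12.
    """
    cov = np.asarray(cov, dtype=float)
    n = cov.shape[0]
    if cov.shape != (n, n) or n % 2:
        raise SizeError("covariance must be square with even size")
    if not np.allclose(cov, cov.T, rtol=1e-8, atol=1e-12 * np.abs(cov).max()):
        raise ModelError("covariance must be symmetric")
    try:
        cho = linalg.cho_factor(cov, lower=True)
    except linalg.LinAlgError as exc:
        min_eig = float(np.linalg.eigvalsh(cov).min())
        raise ConditioningError(
            f"covariance is not positive definite (smallest eigenvalue "
            f"{min_eig:.3e})"
        ) from exc
    diag = np.diag(cho[0])
    cond_est = (diag.max() / diag.min()) ** 2
    if cond_est > _MAX_CONDITION:
        raise ConditioningError(
            f"covariance condition number ~{cond_est:.2e} exceeds 1e12; "
            "regularize (shrinkage) or shorten the window"
        )
    kern = linalg.cho_solve(cho, np.eye(n))
    kern = 0.5 * (kern + kern.T)
    return WindowedKernel(window_len=n, dt=dt, kernel=kern)


def _reversed_block(kern: WindowedKernel) -> np.ndarray:
    """K_pf with the past axis time-reversed so entries depend on t + t'."""
    return kern.k_pf[::-1, :]


def kpf_spectrum(kern: WindowedKernel, *, estimated_input: bool = False) -> KpfSpectrum:
    """Eigendecompose the past-future coupling of a windowed kernel.

    With the past axis reversed, row i of the block refers to past time
    ``t = i dt`` (i = 0 is the most recent sample) and the block entry
    depends on ``t + t'``, so it is symmetric up to window-boundary effects.
    The eigenvalues, sorted by decreasing magnitude, are the coefficients
    ``a_mu``; the eigenvectors are the predictive filters ``phi_mu``.
    """
    block = _reversed_block(kern)
    scale = np.abs(block).max()
    asym = np.abs(block - block.T).max()
    if scale > 0 and asym > 1e-8 * scale:
        raise ModelError(
            f"re-indexed past-future block is asymmetric (rel. {asym / scale:.2e}); "
            "the input kernel does not describe a stationary process"
        )
    sym = 0.5 * (block + block.T)
    evals, evecs = np.linalg.eigh(sym)
    # sort by decreasing |a|, ties broken positive-first, for determinism
    order = np.lexsort((-np.sign(evals), -np.abs(evals)))
    evals = evals[order]
    evecs = evecs[:, order]
    # fix filter signs: largest-magnitude component positive
    peak = np.argmax(np.abs(evecs), axis=0)
    signs = np.sign(evecs[peak, np.arange(evecs.shape[1])])
    signs[signs == 0] = 1.0
    evecs = evecs * signs
    return KpfSpectrum(
        coeffs=evals,
        window_len=kern.window_len,
        filters=evecs,
        estimated_input=estimated_input,
    )


def effective_rank(spec: KpfSpectrum, rel_threshold: float = ANALYTIC_RANK_THRESHOLD) -> int:
    """Number of coefficients with magnitude above ``rel_threshold * |a_1|``.

    Returns 0 for an all-zero spectrum.  Use ~1e-6 for spectra from analytic
    correlations and ~1e-2 for spectra from estimated ones (sampling noise
    raises the floor; finite-sample eigenvalue broadening is *not* corrected
    here, so treat estimated ranks as upper bounds).
    """
    if not (0 < rel_threshold <= 1):
        raise ParameterError("rel_threshold must lie in (0, 1]")
    mags = np.abs(spec.coeffs)
    if mags[0] == 0.0:
        return 0
    return int(np.count_nonzero(mags >= rel_threshold * mags[0]))


def rank_vs_window(
    corr: CorrModel,
    windows: Sequence[int],
    rel_threshold: float = ANALYTIC_RANK_THRESHOLD,
    dt: float = 1.0,
) -> RankReport:
    """Effective rank of K_pf at each window size, with a growth verdict.

    ``finite``: the rank is the same at every window.  ``growing``: it
    strictly increases with the window — the signature of effectively
    infinite dimensionality.  Anything else is ``indeterminate`` (a report,
    not an error).
    """
    windows = np.asarray(list(windows), dtype=int)
    if windows.size == 0 or np.any(np.diff(windows) <= 0):
        raise SizeError("windows must be a non-empty increasing sequence")
    if np.any(windows % 2):
        raise SizeError("each window must be even")
    ranks = []
    for w in windows:
        kern = invert_to_kernel(build_covariance(corr, int(w), dt), dt)
        ranks.append(effective_rank(kpf_spectrum(kern), rel_threshold))
    ranks = np.asarray(ranks, dtype=int)
    if np.all(ranks == ranks[0]):
        verdict = "finite"
    elif windows.size >= 2 and np.all(np.diff(ranks) > 0):
        verdict = "growing"
    else:
        verdict = "indeterminate"
    return RankReport(
        windows=windows, ranks=ranks, threshold=rel_threshold, verdict=verdict
    )


def predictive_filters(spec: KpfSpectrum, d: int) -> np.ndarray:
    """Top-d orthonormal filters phi_mu on the past grid (m x d matrix).

    Row i is past time ``i dt`` back from the present; applying column mu to
    a (time-reversed) past segment yields the predictive feature F_mu.
    """
    if spec.filters is None:
        raise ParameterError("spectrum was computed without filters")
    if not (0 <= d <= spec.coeffs.size):
        raise ParameterError(
            f"d must lie in [0, {spec.coeffs.size}], got {d}"
        )
    return spec.filters[:, :d]
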