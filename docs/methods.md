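# Methods

## Models and conventions

All processes are stationary and zero-mean. The continuous-time models are

* **OU**: `τ_c dx/dt = −x + η`, white noise scaled so that ⟨x²⟩ is the
  requested variance; autocorrelation `C(τ) = ⟨x²⟩ e^{−|τ|/τ_c}`.
* **Coupled pair**: observable x symmetrically coupled (strength a, |a| < 1)
  to a hidden y, both driven by independent white noises of equal strength.
  The correlation is a two-exponential mixture with rates `(1 ± a)/τ_c` and
  amplitudes `A± = ½⟨x²⟩(1 − a²)/(1 ± a)`. Because y is hidden, its scale is
  arbitrary; a property test verifies that rescaling y leaves every
  statistic of x unchanged.
* **General linear**: `dx/dt = −B x + η`, diagonal independent noise,
  stationarity required (all eigenvalues of B in the right half plane), one
  observed coordinate (0-based index).
* **Power law**: `C(τ) = ⟨x²⟩ t₀^α/(t₀^α + |τ|^α)`, α ∈ (0, 2) — the
  canonical model of behavior with no finite dimensionality.
* **Ising chain**: binary states σ = ±1 at clock ticks, field h, couplings
  J(1..R), each lag counted once (R = 1 with coupling J is the
  nearest-neighbor chain with energy `h Σσ + J Σ σ_{t−1}σ_t`).

**Discretization is exact, not Euler.** The one-step propagator is
`F = expm(−B Δt)` (scalar `e^{−Δt/τ_c}` for OU) and the per-step noise
covariance is `Q = Σ∞ − F Σ∞ Fᵀ` with Σ∞ from the continuous Lyapunov
relation. This removes all Δt-bias, so sample statistics can be compared
directly against the continuous-time formulas, which is how the simulators
are tested. Initial conditions are drawn from the stationary distribution;
no burn-in exists anywhere in the package. Power-law processes have no
finite-dimensional state, so they are drawn exactly on a finite window by
factorizing the full n×n covariance (memory O(n²); intended for n up to a
few thousand). If the Cholesky factorization fails, a diagonal jitter
ladder (10⁻¹², 10⁻¹⁰, 10⁻⁸ of the variance) is tried with a loud warning
before giving up with the smallest eigenvalue in the error.

**Correlation estimation** is mean-subtracted with 1/n (biased)
normalization, computed by FFT. The biased choice guarantees a
positive-semidefinite correlation sequence, which the kernel inversion
downstream requires; `max_lag` must stay below n/4 for usable estimates.

## The past–future kernel spectrum

A "window of T samples" holds m = T/2 past samples (t ≤ 0) and m future
samples (t > 0); windows are therefore even. The covariance is the
symmetric Toeplitz matrix `C_ij = C(|i−j| Δt)` and the kernel is its plain
matrix inverse (Kronecker-delta convention; no 1/Δt continuum factor —
rank and relative thresholds are scale-invariant, so the choice is free and
the matrix scale keeps printed coefficients O(1)). Inversion goes through a
Cholesky factorization; a condition estimate above 10¹² raises an error
advising regularization rather than returning garbage.

Reversing the past axis of the off-diagonal block K_pf makes its entries
depend on t + t′; persymmetry of Toeplitz inverses makes this re-indexed
block **exactly** symmetric (asymmetry beyond 10⁻⁸ relative indicates a
non-stationary input and is an error). Its eigendecomposition gives the
coefficients a_μ (sorted by decreasing magnitude, ties positive-first, for
deterministic output) and orthonormal predictive filters φ_μ, stored with
the most recent past sample first and signed so the largest-magnitude
component is positive.

**Rank thresholds.** The effective rank counts |a_μ| ≥ threshold·|a₁|.
Default 10⁻⁶ for spectra from analytic correlations, where the noise floor
is double-precision roundoff (~10⁻¹²–10⁻¹⁰ of a₁); 10⁻² for spectra from
estimated correlations, where sampling noise sets the floor. At n = 10⁶
samples the second eigenvalue of an estimated one-dimensional process
fluctuates around 10⁻² of the first — right at the threshold — so
estimated ranks are honest only up to occasional ±1 fluctuations, and the
corresponding test asserts the statistical statement (majority of seeds
exact, no gross overcount). No random-matrix denoising is applied; spectra
from estimated inputs carry a warning in their file header, and
finite-sample eigenvalue broadening means an apparent continuum is not by
itself evidence for either finite or infinite dimensionality.

**Window stability.** For exponential mixtures whose timescales are
resolved by the smaller window, the leading coefficients are
window-independent to better than 1%. When the longest timescale exceeds
the window (the reference 4/32/256 model in a 100-sample window), the
smallest resolved coefficient shifts with the window while the *rank*
remains stable — rank, not coefficient values, is the dimensionality
statement.

## Predictive information

`I_pred = ½ log₂(det C_pp · det C_ff / det C)` bits, via Cholesky
log-determinants (never raw determinants, so 1000-sample windows cannot
overflow). Bits are used throughout; base-2 is the convention of the
predictive-information literature. The per-feature curve uses canonical
correlations of the whitened cross block `L_p^{-1} C_pf L_f^{-T}`; for
jointly Gaussian variables linear features are optimal, so the CCA route
computes the exact maximum over feature maps — nonlinear feature search is
out of scope. A dual-route test checks the determinant and CCA expressions
against each other.

Covariances built from *estimated* correlations are shrunk toward their
diagonal (intensity 10⁻⁴) before determinant computations, since raw
sample covariances on long windows are routinely near-singular.

**Scaling classification.** Over an increasing window ladder the curve is
`saturating` when the last increment is below 10⁻³ bits, `log_divergent`
when it is affine in log T over the top decade with at most 5% relative
residual and positive slope, else `indeterminate` (a verdict, not an
error). The saturation dimensionality is the smallest d with
I(d)/I_full ≥ 1 − tol (default tol 10⁻⁶); if none qualifies the sentinel
`"unsaturated"` is returned. Note that at any *finite* window even a
power-law process eventually saturates as d grows (the strict
non-saturation statement is a T → ∞ limit); its signature at finite T is
that the d needed to reach a fixed information fraction grows with the
window, which is what the tests assert.

**Agreement of the two definitions.** For exponential mixtures the
spectral rank and the saturation dimensionality coincide — provided each
dynamical mode contributes resolvably above the common tolerance on both
scales (eigenvalue above 10⁻⁶·a₁ *and* information share above 10⁻⁶ of
I_pred). A mode with a very small amplitude squeezed between neighboring
timescales can fall below one threshold and not the other; the 10-model
test grid uses modes that are resolvable on both, which is the regime in
which the equivalence is meaningful.

## Discrete states

All exact Ising computations use the stationary infinite-chain limit via
the 2^R-state transfer matrix (R ≤ 12 enforced). The matrix has two
nonzero entries per row, so it is held sparse; the leading left/right
eigenpair comes from a dense solve below 256 states and from an Arnoldi
solver above. Moments follow from the stationary block distribution and
propagation of the σ-weighted measure through the induced Markov chain;
`τ_c = 1/ln(λ₁/|λ₂|)` ticks, which generalizes the h = 0 closed form
`−1/ln tanh J` to h ≠ 0 (and returns 0 for a memoryless chain instead of
erroring). Sampling is exact sequential conditional draws — the first
block from the stationary distribution, then one Bernoulli per tick — so
there is no MCMC and no burn-in.

The pairwise maximum-entropy fit solves the moment-matching conditions
(model ⟨σ⟩ and connected C(1..R) equal to targets) with a trust-region
least-squares solver (finite-difference Jacobian) on the exact
transfer-matrix forward map; the damped trust-region steps keep iterates
inside the region where the map is well conditioned, which matters for
larger coupling ranges. The problem is the convex dual of entropy
maximization, so the solution is unique when the targets are realizable;
non-realizable targets surface as a fit error carrying the residuals.
Tests verify the fit is the inverse of the forward map, recovers planted
couplings (including a power-law-decaying J(τ) truncated at R = 10) to
10⁻⁶ from exact moments, and lands on the same parameters from perturbed
starts.

Two independent oracles pin the machinery down: exhaustive enumeration
over all 2¹² sequences on a periodic ring against transfer-matrix traces
(agreement to 10⁻¹⁰; the ring geometry is used because open-chain
enumeration converges to the stationary limit only like (λ₂/λ₁)^{n/2}),
and the h = 0 closed form C(τ) = (tanh J)^τ for the stationary chain.

## Synthetic data: what it does and does not emulate

Every test input is generated by the package's own simulators under the
reference conditions (unit variance; a = 0.75; timescales 4, 32, 256
steps with equal amplitudes summing to ⟨x²⟩ = 1 — the rank and the
10⁻¹⁰ noise floor are insensitive to the amplitude split, which is a free
choice here; α = 1/2 with t₀ = one step; analysis windows of 100 and 1000
samples). These are exactly stationary, exactly Gaussian (or exactly
maxent-Ising) processes. Real behavioral series are none of these: they
drift, have measurement noise, mix discrete and continuous structure, and
are short. Passing tests therefore demonstrate the *estimators and
algebra* are correct, not that dimensionality is easy to measure in real
data — the estimated-input tests above give a first taste of the
finite-sample difficulty, and random-matrix corrections for it are
deliberately out of scope.

## Problem sizes and determinism

Analytic spectra use windows up to 1000 (a 1000×1000 inversion plus a
500×500 symmetric eigendecomposition — seconds). Simulation-based checks
use 10⁵–10⁶ steps, chosen so that 4-standard-error bands around the
analytic values are tight enough to be meaningful while the whole suite
runs in well under a minute. Every stochastic operation takes a single
integer seed (NumPy PCG64) recorded in its output; identical seeds
reproduce trajectories bit-for-bit, and file regeneration from a fixture
record is byte-identical.

## Known limitations

* Observables are scalar; vector observables are reserved in the API but
  not implemented.
* No state discovery for discrete behavior: the ±1 labeling is the
  caller's.
* No MCMC path for Ising ranges beyond R = 12, and no choice-of-R
  heuristic — R is an explicit modeling decision.
* `dimension_from_saturation` and `effective_rank` answer "how many
  features at this window and tolerance", which is the operational
  question; they do not attempt the T → ∞ extrapolation beyond the
  convergence check in the scaling classifier.
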