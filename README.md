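# behavdim — the dimensionality of behavioral time series

Modern ethology reduces video of a behaving animal to a handful of
time series — a posture mode, a limb angle, the opening of a clamshell.
How many dynamical variables stand behind such a scalar trace x(t)?
`behavdim` implements an operational answer: **the dimensionality of a
behavior is the minimum number of features of the past needed to capture
all predictive information about the future**, and provides simulators,
estimators and exact discrete-state machinery to measure it.

## The idea

For a stationary Gaussian process the probability of a trajectory is
`P[x] ∝ exp(−½ ∫∫ x(t) K(t−t′) x(t′) dt dt′)` where the kernel K is the
inverse of the correlation function, `∫ K(t−t″)⟨x(t″)x(t′)⟩ dt″ = δ(t−t′)`.
Splitting a window into past (t ≤ 0) and future (t > 0) block-partitions K,
and only the off-diagonal block K_pf couples them.  Stationarity makes the
time-reversed K_pf symmetric, so it eigendecomposes as

    K(t + t′) = Σ_μ a_μ φ_μ(t) φ_μ(t′),

and the number D of coefficients a_μ distinguishable from zero is the
dimensionality: the D features `F_μ = ∫ φ_μ(t) x(−t) dt` are sufficient
statistics for prediction.  Equivalently, the predictive information
(past–future mutual information) captured by the best d linear features,

    I(d) = −½ Σ_{μ≤d} log₂(1 − ρ_μ²)   (ρ_μ: canonical correlations),

saturates exactly at d = D.  Correlations that are finite mixtures of
exponentials give finite D; power-law correlations give a rank that grows
without bound with the analysis window and an I_pred(T) that diverges like
log T — effectively infinite dimensionality.  For two-state (binary)
behavior the same program runs through the 1D Ising chain: the pairwise
maximum-entropy model `P({σ}) ∝ exp(h Σσ_t + Σ J(τ) σ_t σ_{t−τ})`, with all
statistics computed exactly by transfer matrix.

## Worked example

```python
import numpy as np
import behavdim as bd

# behavior whose correlation mixes three timescales: 4, 32, 256 steps
mix3 = bd.ExpMixtureCorr(amplitudes=[1/3]*3, timescales=[4., 32., 256.])
for window in (100, 1000):
    cov  = bd.build_covariance(mix3, window, dt=1.0)
    spec = bd.kpf_spectrum(bd.invert_to_kernel(cov, dt=1.0))
    print(window, np.abs(spec.coeffs[:4]), bd.effective_rank(spec))
```

prints

```
100  [5.223e+00 5.828e-02 1.560e-02 1.582e-13] 3
1000 [5.223e+00 5.543e-02 4.274e-03 2.755e-13] 3
```

Three coefficients stand clearly above zero at both window sizes and the
fourth is at the double-precision noise floor (≪ 10⁻¹⁰): the analysis
recovers exactly the three underlying dynamical variables.  The
information route agrees — `bd.ipred_vs_d(mix3, 200, 4)` reaches the full
`bd.gaussian_pred_info(mix3, 200)` at d = 3 and not before.  The scripts in
`examples/` walk through each capability (spectral rank from simulated
data, power-law rank growth, Ising maxent fits, information saturation)
and print what every number means.

A thin CLI mirrors the library: `behavdim simulate ou|two-d|linear|powerlaw`,
`behavdim corr`, `behavdim spectrum`, `behavdim dim`, `behavdim maxent
fit|sample|corr`, `behavdim predinfo`, `behavdim fixtures`; every flag can
come from a `--config run.yaml`, and every output carries a JSON sidecar
with parameters, seed and version.

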