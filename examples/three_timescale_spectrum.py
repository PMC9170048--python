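"""The past-future kernel spectrum of a three-timescale behavior.

Builds the exact windowed covariance of a process whose autocorrelation
mixes three exponential decays (timescales 4, 32, 256 steps, equal
amplitudes, unit variance), inverts it, and prints the leading eigenvalues
of the past-future block at two very different window sizes.
"""

import numpy as np

import behavdim as bd

mix3 = bd.ExpMixtureCorr(amplitudes=[1 / 3] * 3, timescales=[4.0, 32.0, 256.0])

for window in (100, 1000):
    cov = bd.build_covariance(mix3, window, dt=1.0)
    spec = bd.kpf_spectrum(bd.invert_to_kernel(cov, dt=1.0))
    mags = np.abs(spec.coeffs)
    print(f"window {window:5d}: top 5 |a_mu| = "
          f"{np.array2string(mags[:5], formatter={'float': '{:.3e}'.format})}"
          f"  -> rank {bd.effective_rank(spec)}")

print()
print("Exactly three coefficients stand out at both windows; the fourth is")
print("below 1e-10 — pure double-precision noise. The underlying dynamics")
print("has three variables, and the spectrum finds exactly three.")
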