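"""Two-state behavior: exact Ising statistics and a maximum-entropy fit.

Samples a binary behavioral sequence (active/inactive as +1/-1) from a
nearest-neighbor Ising chain, then fits the pairwise maximum-entropy model
back to the observed mean and correlations and compares with the truth.
"""

import numpy as np

import behavdim as bd

truth = bd.IsingChain(h=0.2, couplings=[0.6])
print(f"truth:  h = {truth.h}, J = {truth.couplings.tolist()}, "
      f"tau_c = {bd.ising_tau_c(truth):.4f} ticks")

seq = bd.sample_ising_general(truth, n=2 * 10**5, seed=42)
s = seq.spins.astype(float)
mean = s.mean()
emp = bd.estimate_corr(bd.TimeSeries(values=s, dt=1.0), max_lag=3)

fitted = bd.fit_maxent_pairwise(mean, emp, range=1, tol=1e-9)
print(f"fitted: h = {fitted.h:.4f}, J = {np.round(fitted.couplings, 4).tolist()}, "
      f"tau_c = {bd.ising_tau_c(fitted):.4f} ticks")

exact = bd.ising_corr(truth, 3)
print(f"exact C(1..3):     {np.round(exact.values[1:], 4).tolist()}")
print(f"empirical C(1..3): {np.round(emp.values[1:], 4).tolist()}")

print()
print("The fit recovers the planted field and coupling to within sampling")
print("error of the 2e5-tick sequence. The maxent model is the *least*")
print("structured distribution matching the mean and pair correlations, so")
print("matching parameters means the data carry no evidence of extra memory.")
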