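import numpy as np
import pytest

from behavdim import ExpMixtureCorr, PowerLawCorr, corr_ou_analytic


@pytest.fixture(scope="session")
def mix3():
    """Three-exponential reference model: timescales 4, 32, 256 steps,
    equal amplitudes, unit variance."""
    return ExpMixtureCorr(amplitudes=[1 / 3] * 3, timescales=[4.0, 32.0, 256.0])


@pytest.fixture(scope="session")
def powerlaw_half():
    """Power-law reference model: unit variance, t0 = 1 step, alpha = 1/2."""
    return PowerLawCorr(variance=1.0, t0=1.0, alpha=0.5)


@pytest.fixture(scope="session")
def ou_unit():
    """Unit-variance OU correlation with tau_c = 10 steps."""
    return corr_ou_analytic(tau_c=10.0, variance=1.0)


@pytest.fixture(scope="session")
def mixture_grid():
    """Ten exponential-mixture models spanning ranks 1-4 with varied
    amplitudes and timescales, all resolvable in a 128-sample window."""
    specs = [
        ([1.0], [3.0]),
        ([0.5], [7.0]),
        ([1.0, 0.5], [2.0, 9.0]),
        ([0.2, 1.3], [1.5, 6.0]),
        ([0.7, 0.7], [4.0, 12.0]),
        ([0.4, 0.4, 0.4], [1.0, 4.0, 10.0]),
        ([1.0, 0.5, 0.25], [2.0, 5.0, 14.0]),
        ([0.3, 0.9, 0.1], [1.5, 3.5, 8.0]),
        ([0.25, 0.25, 0.25, 0.25], [1.0, 2.5, 6.0, 12.0]),
        ([0.8, 0.4, 0.6, 0.2], [1.2, 3.0, 7.0, 15.0]),
    ]
    return [
        ExpMixtureCorr(amplitudes=a, timescales=t) for a, t in specs
    ]
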