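"""Deterministic fixture generation for tests, examples and demos.

Each named fixture regenerates, from a single integer seed, the small set of
files (trajectories and model specifications) used throughout the package's
worked examples: regenerating with the same (name, seed) is byte-identical.
The generator parameters are the package's reference study conditions: unit
variance, two-variable coupling a = 0.75, three-exponential timescales of 4,
32 and 256 steps with equal amplitudes, power-law exponent alpha = 1/2, and
analysis windows of 100 and 1000 samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List

from . import io
from .discrete_maxent import IsingChain, sample_ising_general, sample_ising_nn
from .errors import ParameterError
from .gp_models import (
    ExpMixtureCorr,
    PowerLawCorr,
    simulate_2d,
    simulate_ou,
    simulate_powerlaw,
)

__all__ = ["FixtureSet", "make_fixtures", "FIXTURE_NAMES", "REFERENCE_WINDOWS"]

#: Analysis windows (total samples, past+future) used in the worked examples.
REFERENCE_WINDOWS = (100, 1000)

FIXTURE_NAMES = (
    "ou_trajectory",
    "two_d_trajectory",
    "mix3_model",
    "powerlaw_model",
    "ising_nn",
    "maxent_roundtrip",
)


@dataclass(frozen=True)
class FixtureSet:
    name: str
    seed: int
    artifacts: List[Path] = field(default_factory=list)


def make_fixtures(name: str, seed: int, out_dir) -> FixtureSet:
    """Write the named fixture's files under ``out_dir`` and return their
    paths.  Every file gets a ``.run.json`` sidecar with its parameters."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: List[Path] = []

    def _write(obj, fname, writer, params):
        path = out / fname
        writer(obj, path)
        io.write_sidecar(path, params, seed=seed)
        artifacts.append(path)

    if name == "ou_trajectory":
        params = dict(tau_c=1.0, variance=1.0, dt=0.05, n=4000)
        ts = simulate_ou(**params, seed=seed)
        _write(ts, "ou_trajectory.tsv", io.write_timeseries, params)
    elif name == "two_d_trajectory":
        params = dict(tau_c=1.0, a=0.75, variance=1.0, dt=0.05, n=4000)
        ts = simulate_2d(**params, seed=seed)
        _write(ts, "two_d_trajectory.tsv", io.write_timeseries, params)
    elif name == "mix3_model":
        model = ExpMixtureCorr(
            amplitudes=[1 / 3, 1 / 3, 1 / 3], timescales=[4.0, 32.0, 256.0]
        )
        _write(
            model, "mix3_model.txt", io.write_model,
            dict(timescales=[4, 32, 256], variance=1.0),
        )
    elif name == "powerlaw_model":
        model = PowerLawCorr(variance=1.0, t0=1.0, alpha=0.5)
        params = dict(variance=1.0, t0=1.0, alpha=0.5)
        _write(model, "powerlaw_model.txt", io.write_model, params)
        ts = simulate_powerlaw(model, dt=1.0, n=1000, seed=seed)
        _write(ts, "powerlaw_trajectory.tsv", io.write_timeseries, params)
    elif name == "ising_nn":
        params = dict(h=0.0, j=1.0, n=20000)
        seq = sample_ising_nn(**params, seed=seed)
        _write(seq, "ising_nn.txt", io.write_spins, params)
        _write(
            IsingChain(h=0.0, couplings=[1.0]), "ising_nn_model.txt",
            io.write_model, dict(h=0.0, couplings=[1.0]),
        )
    elif name == "maxent_roundtrip":
        model = IsingChain(h=0.2, couplings=[0.4, 0.1])
        _write(
            model, "maxent_roundtrip_model.txt", io.write_model,
            dict(h=0.2, couplings=[0.4, 0.1]),
        )
        seq = sample_ising_general(model, n=20000, seed=seed)
        _write(seq, "maxent_roundtrip_spins.txt", io.write_spins, dict(n=20000))
    else:
        raise ParameterError(
            f"unknown fixture {name!r}; known fixtures: {', '.join(FIXTURE_NAMES)}"
        )
    return FixtureSet(name=name, seed=seed, artifacts=artifacts)
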