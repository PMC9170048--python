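"""Plain-text readers and writers for every artifact the package produces.

The dialect is tab-separated columns with ``#``-prefixed header lines that
carry metadata as ``# key = value`` pairs — greppable and diffable.  Every
writer has a matching reader that reproduces an equal in-memory value, and
every run can drop a JSON sidecar recording parameters, seed and package
version for reproducibility audits.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np

from . import __version__
from .errors import ParameterError
from .gp_models import (
    CorrFunction,
    ExpMixtureCorr,
    PowerLawCorr,
    TimeSeries,
    WhiteNoiseCorr,
)
from .discrete_maxent import IsingChain, SpinSequence
from .kernel_spectrum import KpfSpectrum, RankReport
from .predictive_info import PredInfoCurve

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "read_spins",
    "write_spins",
    "read_corr",
    "write_corr",
    "read_model",
    "write_model",
    "write_spectrum",
    "read_spectrum",
    "write_rank_report",
    "write_predinfo_curve",
    "write_sidecar",
]

_UNIFORM_RTOL = 1e-6


def _parse_meta(path: Path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "=" in line:
                key, _, val = line[1:].partition("=")
                meta[key.strip()] = val.strip()
    return meta


def _meta_lines(**meta) -> str:
    return "".join(
        f"# {k} = {v}\n" for k, v in meta.items() if v is not None
    )


# -- time series -------------------------------------------------------------

def write_timeseries(ts: TimeSeries, path) -> None:
    path = Path(path)
    header = _meta_lines(dt=repr(ts.dt), seed=ts.seed, version=__version__)
    data = np.column_stack([ts.times, ts.values])
    with open(path, "w") as fh:
        fh.write(header)
        fh.write("# time\tvalue\n")
        np.savetxt(fh, data, fmt="%.17g", delimiter="\t")


def read_timeseries(path) -> TimeSeries:
    path = Path(path)
    meta = _parse_meta(path)
    data = np.loadtxt(path, comments="#")
    times, values = data[:, 0], data[:, 1]
    steps = np.diff(times)
    dt = float(np.median(steps))
    if np.any(np.abs(steps - dt) > _UNIFORM_RTOL * max(dt, 1e-300)):
        raise ParameterError(f"{path}: time column is not uniformly sampled")
    seed = int(meta["seed"]) if "seed" in meta else None
    return TimeSeries(values=values, dt=dt, seed=seed)


# -- spin sequences ----------------------------------------------------------

def write_spins(seq: SpinSequence, path, encoding: str = "pm1") -> None:
    path = Path(path)
    if encoding == "pm1":
        col = seq.spins.astype(int)
    elif encoding == "01":
        col = ((seq.spins + 1) // 2).astype(int)
    else:
        raise ParameterError(f"unknown spin encoding {encoding!r}")
    with open(path, "w") as fh:
        fh.write(_meta_lines(dt=repr(seq.dt), encoding=encoding, version=__version__))
        fh.write("# spin\n")
        np.savetxt(fh, col, fmt="%d")


def read_spins(path) -> SpinSequence:
    path = Path(path)
    meta = _parse_meta(path)
    col = np.loadtxt(path, comments="#").astype(int)
    if meta.get("encoding", "pm1") == "01":
        col = 2 * col - 1
    return SpinSequence(spins=col, dt=float(meta.get("dt", 1.0)))


# -- correlation functions ---------------------------------------------------

def write_corr(corr: CorrFunction, path) -> None:
    path = Path(path)
    cols = [corr.lags, corr.values]
    names = "lag\tvalue"
    if corr.n_samples_per_lag is not None:
        cols.append(corr.n_samples_per_lag)
        names += "\tn_samples"
    with open(path, "w") as fh:
        fh.write(_meta_lines(version=__version__))
        fh.write(f"# {names}\n")
        np.savetxt(fh, np.column_stack(cols), fmt="%.17g", delimiter="\t")


def read_corr(path) -> CorrFunction:
    data = np.atleast_2d(np.loadtxt(Path(path), comments="#"))
    counts = data[:, 2].astype(int) if data.shape[1] > 2 else None
    return CorrFunction(lags=data[:, 0], values=data[:, 1], n_samples_per_lag=counts)


# -- correlation-model files (key-value text) --------------------------------

def write_model(model, path) -> None:
    """Serialize an analytic correlation model or an Ising chain."""
    path = Path(path)
    lines = [f"# version = {__version__}"]
    if isinstance(model, ExpMixtureCorr):
        lines += [
            "kind\texp_mixture",
            "amplitudes\t" + ",".join(repr(float(a)) for a in model.amplitudes),
            "timescales\t" + ",".join(repr(float(t)) for t in model.timescales),
        ]
    elif isinstance(model, PowerLawCorr):
        lines += [
            "kind\tpower_law",
            f"variance\t{float(model.variance)!r}",
            f"t0\t{float(model.t0)!r}",
            f"alpha\t{float(model.alpha)!r}",
        ]
    elif isinstance(model, WhiteNoiseCorr):
        lines += ["kind\twhite_noise", f"variance\t{float(model.variance)!r}"]
    elif isinstance(model, IsingChain):
        lines += [
            "kind\tising_chain",
            f"h\t{float(model.h)!r}",
            "couplings\t" + ",".join(repr(float(j)) for j in model.couplings),
        ]
    else:
        raise ParameterError(f"don't know how to serialize {type(model).__name__}")
    path.write_text("\n".join(lines) + "\n")


def read_model(path):
    path = Path(path)
    fields = {}
    for line in path.read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        key, _, val = line.partition("\t")
        fields[key.strip()] = val.strip()
    kind = fields.get("kind")
    if kind == "exp_mixture":
        return ExpMixtureCorr(
            amplitudes=[float(x) for x in fields["amplitudes"].split(",")],
            timescales=[float(x) for x in fields["timescales"].split(",")],
        )
    if kind == "power_law":
        return PowerLawCorr(
            variance=float(fields["variance"]),
            t0=float(fields["t0"]),
            alpha=float(fields["alpha"]),
        )
    if kind == "white_noise":
        return WhiteNoiseCorr(variance=float(fields["variance"]))
    if kind == "ising_chain":
        return IsingChain(
            h=float(fields["h"]),
            couplings=[float(x) for x in fields["couplings"].split(",")],
        )
    raise ParameterError(f"{path}: unknown model kind {kind!r}")


# -- spectra, rank reports, curves -------------------------------------------

def write_spectrum(spec: KpfSpectrum, path) -> None:
    path = Path(path)
    idx = np.arange(1, spec.coeffs.size + 1)
    win = np.full(idx.size, spec.window_len)
    with open(path, "w") as fh:
        fh.write(_meta_lines(version=__version__, estimated=spec.estimated_input))
        if spec.estimated_input:
            fh.write(
                "# warning: spectrum from estimated correlations; finite-sample\n"
                "# broadening can mask the distinction between finite and\n"
                "# infinite-dimensional processes\n"
            )
        fh.write("# index\tcoefficient\twindow_len\n")
        np.savetxt(
            fh, np.column_stack([idx, spec.coeffs, win]),
            fmt=("%d", "%.17g", "%d"), delimiter="\t",
        )


def read_spectrum(path) -> KpfSpectrum:
    path = Path(path)
    meta = _parse_meta(path)
    data = np.atleast_2d(np.loadtxt(path, comments="#"))
    return KpfSpectrum(
        coeffs=data[:, 1],
        window_len=int(data[0, 2]),
        estimated_input=meta.get("estimated", "False") == "True",
    )


def write_rank_report(report: RankReport, path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "windows": report.windows.tolist(),
                "ranks": report.ranks.tolist(),
                "threshold": report.threshold,
                "verdict": report.verdict,
            },
            indent=2,
        )
        + "\n"
    )


def write_predinfo_curve(curve: PredInfoCurve, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_meta_lines(version=__version__, units="bits",
                             classification=curve.classification))
        cols = [curve.windows.astype(float), curve.info]
        names = "window\tinfo_bits"
        if curve.per_d is not None:
            for d in range(curve.per_d.shape[1]):
                cols.append(curve.per_d[:, d])
                names += f"\tinfo_d{d + 1}_bits"
        fh.write(f"# {names}\n")
        np.savetxt(fh, np.column_stack(cols), fmt="%.17g", delimiter="\t")


def write_sidecar(path, params: dict, seed: Optional[int] = None) -> None:
    """Drop ``<path>.run.json`` recording parameters, seed and version."""
    record = {"params": params, "seed": seed, "version": __version__}
    Path(str(path) + ".run.json").write_text(json.dumps(record, indent=2) + "\n")
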