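"""Text round-tripping of panel datasets, truth sidecars and reports.

A dataset is a directory holding ``data.csv`` (long format: one row per
individual-occasion with columns ``id``, ``t``, the series, the optional
time-varying covariate, the repeated between-level covariates and, when
known, the generating state) plus ``meta.json`` recording dimensions and
which columns are latent.  Floats are written with 17 significant
digits, which makes the round trip bitwise exact.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .model import PanelDataset
from .simulate import Sim1Design, Sim2Design, SimulatedDataset

__all__ = ["write_dataset", "read_dataset", "write_truth", "read_truth", "round_trip"]

_FLOAT_FMT = "%.17g"


class ParseError(ValueError):
    pass


def _dataset_frame(data: PanelDataset) -> pd.DataFrame:
    n, t, k = data.N, data.T, data.K
    ids, ts = np.meshgrid(np.arange(1, n + 1), np.arange(1, t + 1), indexing="ij")
    cols = {"id": ids.ravel(), "t": ts.ravel()}
    if k == 1:
        cols["eta_y"] = data.eta_y[:, :, 0].ravel()
    else:
        for j in range(k):
            cols[f"eta_y_{j + 1}"] = data.eta_y[:, :, j].ravel()
    if data.eta_z is not None:
        cols["eta_z"] = data.eta_z.ravel()
    for q in range(data.Q):
        cols[f"x_{q + 1}"] = np.repeat(data.eta_x[:, q], t)
    if data.states is not None:
        cols["state"] = data.states.ravel()
    return pd.DataFrame(cols)


def write_dataset(ds: PanelDataset | SimulatedDataset, outdir) -> Path:
    """Write a dataset directory (data.csv + meta.json [+ truth.json])."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data = ds.data if isinstance(ds, SimulatedDataset) else ds
    frame = _dataset_frame(data)
    frame.to_csv(outdir / "data.csv", index=False, float_format=_FLOAT_FMT)
    meta = {
        "N": data.N,
        "T": data.T,
        "K": data.K,
        "Q": data.Q,
        "has_eta_z": data.eta_z is not None,
        "has_states": data.states is not None,
        "latent_columns": ["eta_y", "eta_z"],
    }
    (outdir / "meta.json").write_text(json.dumps(meta, indent=1))
    if isinstance(ds, SimulatedDataset):
        write_truth(ds, outdir / "truth.json")
    return outdir


def write_truth(ds: SimulatedDataset, path) -> None:
    truth = {
        "beta_star": [float(v) for v in ds.true_beta_star],
        "eps0": [float(v) for v in ds.true_eps0],
        "design_kind": "sim2" if isinstance(ds.design, Sim2Design) else "sim1",
        "design": _jsonable(ds.design_dict()),
        "within": {
            "a2": float(ds.true_within.a2[0]),
            "b2": float(ds.true_within.b2[0, 0]),
            "gamma": float(ds.true_within.gamma),
            "sigma_eps": float(ds.true_within.sigma_eps),
        },
    }
    Path(path).write_text(json.dumps(truth, indent=1))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def read_truth(path) -> dict:
    truth = json.loads(Path(path).read_text())
    truth["beta_star"] = np.asarray(truth["beta_star"], dtype=float)
    truth["eps0"] = np.asarray(truth["eps0"], dtype=float)
    return truth


def read_dataset(indir) -> PanelDataset:
    """Read a dataset directory written by :func:`write_dataset`."""
    indir = Path(indir)
    meta = json.loads((indir / "meta.json").read_text())
    frame = pd.read_csv(indir / "data.csv", float_precision="round_trip")
    n, t, k, q = meta["N"], meta["T"], meta["K"], meta["Q"]
    required = ["id", "t"]
    required += ["eta_y"] if k == 1 else [f"eta_y_{j + 1}" for j in range(k)]
    if meta["has_eta_z"]:
        required.append("eta_z")
    required += [f"x_{j + 1}" for j in range(q)]
    for col in required:
        if col not in frame.columns:
            raise ParseError(f"missing column {col!r} in {indir / 'data.csv'}")
    if len(frame) != n * t:
        raise ParseError(f"expected {n * t} rows, found {len(frame)}")
    frame = frame.sort_values(["id", "t"], kind="stable")
    if k == 1:
        eta_y = frame["eta_y"].to_numpy().reshape(n, t)
    else:
        eta_y = np.stack(
            [frame[f"eta_y_{j + 1}"].to_numpy().reshape(n, t) for j in range(k)], axis=-1
        )
    eta_z = frame["eta_z"].to_numpy().reshape(n, t) if meta["has_eta_z"] else None
    eta_x = frame[[f"x_{j + 1}" for j in range(q)]].iloc[::t].to_numpy()
    states = (
        frame["state"].to_numpy().reshape(n, t).astype(int) if meta.get("has_states") else None
    )
    return PanelDataset(eta_y=eta_y, eta_x=eta_x, eta_z=eta_z, states=states)


def round_trip(ds: PanelDataset | SimulatedDataset, tmpdir) -> PanelDataset:
    """Write then read back; floats survive bitwise via 17-digit text."""
    outdir = write_dataset(ds, tmpdir)
    return read_dataset(outdir)
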