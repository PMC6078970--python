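"""Plain-text I/O: 3-column .dat curves, manifests, traces, fit records.

Curves use the de-facto small-angle-scattering dialect: whitespace
delimited ``q I sigma`` columns with ``#`` comment headers.  A curve
series is a directory of .dat files plus a ``manifest.csv`` with
``filename,time_s`` columns.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .scattering import ObservableTrace, ScatteringCurve

MANIFEST_NAME = "manifest.csv"


def write_dat(path, curve: ScatteringCurve, header: str = "") -> None:
    path = Path(path)
    lines = ["# q(1/A) I(abs) sigma"]
    if header:
        lines = [f"# {h}" for h in header.splitlines()] + lines
    with path.open("w") as fh:
        fh.write("\n".join(lines) + "\n")
        np.savetxt(fh, np.column_stack([curve.q, curve.I, curve.sigma]), fmt="%.10e")


def read_dat(path) -> ScatteringCurve:
    data = np.loadtxt(path, comments="#")
    if data.ndim != 2 or data.shape[1] < 3:
        raise ValidationError(f"{path}: expected 3 columns (q, I, sigma)")
    return ScatteringCurve(q=data[:, 0], I=data[:, 1], sigma=data[:, 2])


def write_series(directory, times, curves: list[ScatteringCurve]) -> None:
    """Write a time series of curves plus its manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    names = []
    for i, (t, c) in enumerate(zip(times, curves)):
        name = f"frame_{i:04d}.dat"
        write_dat(directory / name, c, header=f"time_s = {t:.9g}")
        names.append(name)
    pd.DataFrame({"filename": names, "time_s": np.asarray(times, float)}).to_csv(
        directory / MANIFEST_NAME, index=False
    )


def read_series(directory) -> tuple[np.ndarray, list[ScatteringCurve]]:
    """Read a curve series back from a directory with a manifest."""
    directory = Path(directory)
    manifest = directory / MANIFEST_NAME
    if not manifest.exists():
        raise ValidationError(f"missing manifest: {manifest}")
    df = pd.read_csv(manifest)
    for col in ("filename", "time_s"):
        if col not in df.columns:
            raise ValidationError(f"{manifest}: missing column '{col}'")
    df = df.sort_values("time_s", kind="stable")
    curves = []
    for name in df["filename"]:
        path = directory / name
        if not path.exists():
            raise ValidationError(f"manifest references missing file: {path}")
        curves.append(read_dat(path))
    return df["time_s"].to_numpy(dtype=float), curves


def write_trace(path, trace: ObservableTrace) -> None:
    pd.DataFrame(
        {"time_s": trace.t, "value": trace.value, "sigma": trace.sigma}
    ).to_csv(path, index=False)


def read_trace(path, name: str = "") -> ObservableTrace:
    df = pd.read_csv(path)
    for col in ("time_s", "value", "sigma"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column '{col}'")
    return ObservableTrace(
        t=df["time_s"].to_numpy(float),
        value=df["value"].to_numpy(float),
        sigma=df["sigma"].to_numpy(float),
        name=name,
    )


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def dump_json(path, record) -> None:
    """Serialize a (possibly dataclass-bearing) record as stable JSON."""
    Path(path).write_text(json.dumps(_jsonable(record), indent=2, sort_keys=True))


def stable_json(record) -> str:
    return json.dumps(_jsonable(record), sort_keys=True)
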