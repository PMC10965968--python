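"""Trajectory and trace file formats (TSV) with strict validation."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .hmm import Trajectory

__all__ = ["read_trajectory", "write_trajectory", "read_trace", "write_trace"]

PathLike = Union[str, Path]


class FormatError(ValueError):
    """Malformed input file."""


def write_trajectory(path: PathLike, traj: Trajectory) -> None:
    """Write a trajectory as TSV (time_s, extension_nm[, force_pN]) with a metadata header."""
    cols = {"time_s": traj.time, "extension_nm": traj.extension}
    if traj.force is not None:
        cols["force_pN"] = traj.force
    meta = {"sample_rate_hz": traj.sample_rate, **traj.metadata}
    with open(path, "w", newline="") as fh:
        fh.write("# " + json.dumps(meta) + "\n")
        pd.DataFrame(cols).to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_trajectory(path: PathLike) -> Trajectory:
    """Read a TSV trajectory; accepts LF or CRLF line endings.

    Requires columns ``time_s`` and ``extension_nm``; ``force_pN`` is
    optional.  Malformed rows are reported with their line numbers.
    """
    path = Path(path)
    meta = {}
    with open(path, newline="") as fh:
        first = fh.readline()
        if first.startswith("#"):
            try:
                meta = json.loads(first.lstrip("# ").strip())
            except json.JSONDecodeError:
                meta = {}
            header_offset = 2
            body = fh.read()
        else:
            header_offset = 1
            body = first + fh.read()
    from io import StringIO

    try:
        df = pd.read_csv(StringIO(body), sep="\t")
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse TSV: {exc}") from exc
    missing = {"time_s", "extension_nm"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing required columns {sorted(missing)}")
    if len(df) == 0:
        raise FormatError(f"{path}: no data rows")
    for col in ["time_s", "extension_nm"] + (["force_pN"] if "force_pN" in df.columns else []):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(~np.isfinite(vals.to_numpy()))
        if len(bad):
            lines = ", ".join(str(b + header_offset + 1) for b in bad[:5])
            raise FormatError(f"{path}: non-numeric values in column {col} at line(s) {lines}")
        df[col] = vals
    sample_rate = meta.pop("sample_rate_hz", None)
    if sample_rate is None:
        dt = np.diff(df["time_s"].to_numpy())
        sample_rate = 1.0 / float(np.median(dt)) if len(dt) else 1.0
    return Trajectory(
        time=df["time_s"].to_numpy(),
        extension=df["extension_nm"].to_numpy(),
        sample_rate=float(sample_rate),
        force=df["force_pN"].to_numpy() if "force_pN" in df.columns else None,
        metadata=meta,
    )


def write_trace(path: PathLike, time: np.ndarray, current: np.ndarray) -> None:
    """Write a current trace as TSV (time_s, current_nA)."""
    pd.DataFrame({"time_s": time, "current_nA": current}).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_trace(path: PathLike):
    """Read a TSV current trace; returns (time_s, current_nA) arrays."""
    df = pd.read_csv(path, sep="\t")
    missing = {"time_s", "current_nA"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing required columns {sorted(missing)}")
    return df["time_s"].to_numpy(dtype=float), df["current_nA"].to_numpy(dtype=float)
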