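"""Plain-text trajectory and trace I/O plus periodic unwrapping.

Two trajectory formats are supported:

* ``xyz`` -- standard XYZ (count line, comment line with ``t=<ns>``, then
  ``W x y z [ux uy uz]`` rows).  XYZ carries no molecule ids, so ids are
  assigned by row order within a frame; it is only suitable for
  fixed-population trajectories and the writer refuses otherwise.
* ``table`` -- a delimited table with header
  ``frame  id  x  y  z  [ux uy uz]`` preceded by ``#key=value`` metadata
  lines (``dt``, ``t0``, ``n_frames``, optional ``box``).

Stopped-flow traces are two-column (time, signal) files with the same
``#key=value`` metadata header.
"""

from __future__ import annotations

import io as _io
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import DEFAULT_TRACE_TEMPERATURE_K
from .exceptions import ParseError, ValidationError
from .types import DIPOLE_COLUMNS, StoppedFlowTrace, TrajectorySet

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# trajectory I/O
# ---------------------------------------------------------------------------

def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    return "xyz" if path.suffix.lower() == ".xyz" else "table"


def write_trajectory(traj: TrajectorySet, path, fmt: str | None = None) -> None:
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "xyz":
        _write_xyz(traj, path)
    elif fmt == "table":
        _write_table(traj, path)
    else:
        raise ValidationError(f"unknown trajectory format {fmt!r}")


def read_trajectory(path, fmt: str | None = None) -> TrajectorySet:
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "xyz":
        return _read_xyz(path)
    if fmt == "table":
        return _read_table(path)
    raise ValidationError(f"unknown trajectory format {fmt!r}")


def _write_xyz(traj: TrajectorySet, path: Path) -> None:
    counts = traj.records.groupby("frame").size()
    if len(counts.unique()) > 1:
        raise ValidationError(
            "XYZ cannot represent a varying particle count; use the table format"
        )
    dip = traj.has_dipoles
    with open(path, "w") as fh:
        for i, t in enumerate(traj.times):
            fr = traj.frame(i).sort_values("id")
            fh.write(f"{len(fr)}\n")
            fh.write(f"t={t:.6f}\n")
            for _, row in fr.iterrows():
                line = f"W {row['x']:.6f} {row['y']:.6f} {row['z']:.6f}"
                if dip:
                    line += f" {row['ux']:.6f} {row['uy']:.6f} {row['uz']:.6f}"
                fh.write(line + "\n")


def _read_xyz(path: Path) -> TrajectorySet:
    times, rows = [], []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    i, frame = 0, 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise ParseError(f"bad atom-count line at frame {frame}: {lines[i]!r}") from exc
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        t = float(frame)
        for tok in comment.replace(",", " ").split():
            if tok.startswith("t="):
                t = float(tok[2:])
        body = lines[i + 2 : i + 2 + n]
        if len(body) < n:
            raise ParseError(f"frame {frame} is ragged: expected {n} atom lines")
        for mol, ln in enumerate(body):
            parts = ln.split()
            if len(parts) not in (4, 7):
                raise ParseError(f"frame {frame}: bad atom line {ln!r}")
            vals = [float(v) for v in parts[1:]]
            rows.append([frame, mol] + vals)
        times.append(t)
        frame += 1
        i += 2 + n
    ncol = max((len(r) for r in rows), default=5)
    cols = ["frame", "id", "x", "y", "z"] + (list(DIPOLE_COLUMNS) if ncol == 8 else [])
    rec = pd.DataFrame(rows, columns=cols)
    if len(rec):
        rec = rec.astype({"frame": int, "id": int})
    return TrajectorySet(times=np.asarray(times, float), records=rec)


def _write_table(traj: TrajectorySet, path: Path) -> None:
    dt = float(np.median(np.diff(traj.times))) if traj.n_frames > 1 else 1.0
    t0 = float(traj.times[0]) if traj.n_frames else 0.0
    with open(path, "w") as fh:
        fh.write(f"#dt={dt:.9g}\n#t0={t0:.9g}\n#n_frames={traj.n_frames}\n")
        if traj.box is not None:
            fh.write("#box=" + ",".join(f"{b:.9g}" for b in traj.box) + "\n")
        cols = ["frame", "id", "x", "y", "z"]
        if traj.has_dipoles:
            cols += list(DIPOLE_COLUMNS)
        fh.write("\t".join(cols) + "\n")
        traj.records[cols].to_csv(fh, sep="\t", index=False, header=False, float_format="%.6g")


def _read_table(path: Path) -> TrajectorySet:
    meta: dict[str, str] = {}
    body = []
    with open(path) as fh:
        for ln in fh:
            if ln.startswith("#"):
                key, _, val = ln[1:].strip().partition("=")
                meta[key.strip()] = val.strip()
            else:
                body.append(ln)
    if not body:
        return TrajectorySet(times=np.array([]), records=pd.DataFrame(
            columns=["frame", "id", "x", "y", "z"]))
    df = pd.read_csv(_io.StringIO("".join(body)), sep=r"\s+")
    expected = {5, 8}
    if df.shape[1] not in expected:
        raise ParseError(
            f"table has {df.shape[1]} columns; expected frame,id,x,y,z[,ux,uy,uz]"
        )
    df.columns = ["frame", "id", "x", "y", "z"] + (
        list(DIPOLE_COLUMNS) if df.shape[1] == 8 else []
    )
    df = df.astype({"frame": int, "id": int})
    dt = float(meta.get("dt", 1.0))
    t0 = float(meta.get("t0", 0.0))
    n_frames = int(meta.get("n_frames", df["frame"].max() + 1 if len(df) else 0))
    box = None
    if "box" in meta:
        box = tuple(float(v) for v in meta["box"].split(","))
    times = t0 + dt * np.arange(n_frames)
    return TrajectorySet(times=times, records=df, box=box)


# ---------------------------------------------------------------------------
# trace I/O
# ---------------------------------------------------------------------------

def write_trace(trace: StoppedFlowTrace, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#temperature={trace.temperature:.6g}\n")
        fh.write(f"#condition={trace.condition}\n")
        if trace.gradient is not None:
            fh.write(f"#gradient={trace.gradient}\n")
        for key, val in trace.metadata.items():
            fh.write(f"#{key}={val}\n")
        for t, s in zip(trace.times, trace.signal):
            fh.write(f"{t:.9g}\t{s:.9g}\n")


def read_trace(path) -> StoppedFlowTrace:
    meta: dict[str, str] = {}
    rows = []
    with open(path) as fh:
        for ln in fh:
            ln = ln.strip()
            if not ln:
                continue
            if ln.startswith("#"):
                key, _, val = ln[1:].partition("=")
                meta[key.strip()] = val.strip()
                continue
            parts = ln.replace(",", " ").split()
            if len(parts) != 2:
                raise ParseError(f"trace line is not two numeric columns: {ln!r}")
            rows.append((float(parts[0]), float(parts[1])))
    if not rows:
        raise ParseError("trace file holds no samples")
    arr = np.asarray(rows)
    if not np.all(np.diff(arr[:, 0]) > 0):
        raise ValidationError("trace time column must be strictly increasing")
    if "temperature" in meta:
        temperature = float(meta.pop("temperature"))
    else:
        temperature = DEFAULT_TRACE_TEMPERATURE_K
        logger.warning(
            "trace %s has no temperature metadata; defaulting to %.2f K", path, temperature
        )
        meta["temperature_defaulted"] = "true"
    condition = meta.pop("condition", "osmotic")
    gradient = meta.pop("gradient", None)
    return StoppedFlowTrace(
        times=arr[:, 0],
        signal=arr[:, 1],
        temperature=temperature,
        condition=condition,
        gradient=gradient,
        metadata=meta,
    )


# ---------------------------------------------------------------------------
# periodic unwrapping
# ---------------------------------------------------------------------------

def wrap_to_axis(traj: TrajectorySet, box=None, z_center: float = 0.0) -> TrajectorySet:
    """Minimum-image unwrap per-molecule paths and re-centre the pore axis.

    For periodic inputs, consecutive per-molecule displacements along each
    box dimension are unwrapped to the minimum image; absolute z is then
    shifted so the pore midpoint sits at ``z_center`` (0 by default).
    Non-periodic input (``box is None``) passes through unchanged apart
    from the optional re-centring.

    Gaps in a molecule's presence reset the unwrapping state for that
    molecule (its next displacement is not corrected), and a warning is
    issued when a single-step displacement still exceeds half a box length
    after correction.
    """
    box = box if box is not None else traj.box
    rec = traj.records.sort_values(["id", "frame"], kind="mergesort").reset_index(drop=True)
    if box is None:
        out = rec.copy()
        out["z"] = out["z"] - z_center
        return TrajectorySet(times=traj.times.copy(), records=out, box=None,
                             axis_convention=traj.axis_convention)
    box = np.asarray(box, float)
    if np.any(box <= 0):
        raise ValidationError("box lengths must be positive")
    ids = rec["id"].to_numpy()
    frames = rec["frame"].to_numpy()
    same = (ids[1:] == ids[:-1]) & (frames[1:] == frames[:-1] + 1)
    out = rec.copy()
    for axis, L in zip(("x", "y", "z"), box):
        v = rec[axis].to_numpy(float)
        dv = np.diff(v)
        corr = -L * np.round(dv / L)
        corr[~same] = 0.0
        if np.any(np.abs(dv[same] + corr[same]) > 0.5 * L):
            warnings.warn(
                "per-step displacement exceeds half a box length after "
                "minimum-image correction; molecule state should be reset",
                stacklevel=2,
            )
        # cumulative correction restarts at every new molecule segment
        cum = np.concatenate([[0.0], np.cumsum(corr)])
        seg_start = np.concatenate([[True], ~same])
        base = np.where(seg_start, cum, np.nan)
        base = pd.Series(base).ffill().to_numpy()
        out[axis] = v + (cum - base)
    out["z"] = out["z"] - z_center
    return TrajectorySet(times=traj.times.copy(), records=out, box=None,
                         axis_convention=traj.axis_convention)
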