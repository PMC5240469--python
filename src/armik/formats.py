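"""Text file formats: TRC marker trajectories, MOT/STO joint-angle tables,
CSV markers and quaternion streams.

Conventions
-----------
* TRC positions are stored in the world frame; meters are written, ``mm`` (or
  ``m``) accepted on read.
* Quaternion CSVs are **scalar-first** (qw qx qy qz) world-to-segment
  rotations, one block of four columns per segment (humerus, forearm, hand).
  Conventions vary between vendors; this one is fixed here.
* MOT/STO angle tables are tab-separated with an ``inDegrees=yes`` header and
  a leading time column followed by the seven joint coordinates.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .model import COORDINATES, MARKER_NAMES
from .motion import MarkerTrajectory, OrientationTrajectory

__all__ = [
    "FormatError",
    "read_trc",
    "write_trc",
    "read_motion",
    "write_motion",
    "read_markers_csv",
    "write_markers_csv",
    "read_quaternions_csv",
    "write_quaternions_csv",
]

SEGMENTS = ("humerus", "forearm", "hand")


class FormatError(ValueError):
    """Malformed or incomplete input file."""


# ---------------------------------------------------------------------------
# TRC
# ---------------------------------------------------------------------------


def write_trc(path, trajectory: MarkerTrajectory, units: str = "m") -> None:
    """Write a marker trajectory as a TRC file (tab-separated, standard
    five-line header)."""
    times = np.asarray(trajectory.times, dtype=float)
    pos = np.asarray(trajectory.positions, dtype=float)
    if units == "mm":
        pos = pos * 1000.0
    elif units != "m":
        raise ValueError("units must be 'm' or 'mm'")
    n = len(times)
    rate = 1.0 / np.mean(np.diff(times)) if n > 1 else 100.0
    names = list(trajectory.names)
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"PathFileType\t4\t(X/Y/Z)\t{path.name}\n")
        fh.write(
            "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\t"
            "OrigDataRate\tOrigDataStartFrame\tOrigNumFrames\n"
        )
        fh.write(f"{rate:.2f}\t{rate:.2f}\t{n}\t{len(names)}\t{units}\t{rate:.2f}\t1\t{n}\n")
        fh.write("Frame#\tTime\t" + "\t\t\t".join(names) + "\t\t\n")
        axes = "\t".join(f"X{i+1}\tY{i+1}\tZ{i+1}" for i in range(len(names)))
        fh.write(f"\t\t{axes}\n")
        for i in range(n):
            row = [str(i + 1), f"{times[i]:.8f}"]
            row.extend(f"{v:.10f}" for v in pos[i].reshape(-1))
            fh.write("\t".join(row) + "\n")


def read_trc(path) -> MarkerTrajectory:
    """Read a TRC marker file; positions are converted to meters.

    All 12 prototype markers must be present (matched case-sensitively by
    name); missing markers raise :class:`FormatError` listing the names.
    """
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 6 or not lines[0].startswith("PathFileType"):
        raise FormatError(f"{path}: not a TRC file (missing PathFileType header)")
    meta_keys = lines[1].split("\t")
    meta_vals = lines[2].split("\t")
    meta = dict(zip(meta_keys, meta_vals))
    for key in ("DataRate", "NumFrames", "NumMarkers", "Units"):
        if key not in meta:
            raise FormatError(f"{path}: TRC header missing {key}")
    units = meta["Units"].strip()
    if units not in ("m", "mm"):
        raise FormatError(f"{path}: unsupported units {units!r}")
    scale = 0.001 if units == "mm" else 1.0
    header = lines[3].split("\t")
    names = [h.strip() for h in header[2:] if h.strip()]
    missing = [m for m in MARKER_NAMES if m not in names]
    if missing:
        raise FormatError(f"{path}: missing prototype markers: {missing}")
    col_of = {name: 2 + 3 * names.index(name) for name in MARKER_NAMES}
    times, frames = [], []
    for line in lines[5:]:
        if not line.strip():
            continue
        parts = line.split("\t")
        times.append(float(parts[1]))
        frame = np.full((12, 3), np.nan)
        for j, name in enumerate(MARKER_NAMES):
            c = col_of[name]
            try:
                frame[j] = [float(parts[c + k]) for k in range(3)]
            except (IndexError, ValueError):
                pass  # leave NaN: frame flagged by the caller
        frames.append(frame * scale)
    return MarkerTrajectory(times=np.asarray(times), positions=np.stack(frames))


# ---------------------------------------------------------------------------
# MOT / STO joint-angle tables
# ---------------------------------------------------------------------------


def write_motion(path, times, angles, name: str = "armik joint angles") -> None:
    """Write a joint-angle table in the MOT/STO dialect (or CSV by suffix).

    ``angles`` is (n, 7) in degrees, columns in COORDINATES order; the table
    always carries ``inDegrees=yes``.
    """
    times = np.asarray(times, dtype=float)
    angles = np.asarray(angles, dtype=float)
    if angles.shape != (len(times), 7):
        raise ValueError(f"expected (n, 7) angle table, got {angles.shape}")
    path = Path(path)
    if path.suffix.lower() == ".csv":
        df = pd.DataFrame(angles, columns=list(COORDINATES))
        df.insert(0, "time", times)
        df.to_csv(path, index=False)
        return
    with open(path, "w") as fh:
        fh.write(f"{name}\n")
        fh.write("version=1\n")
        fh.write(f"nRows={len(times)}\n")
        fh.write(f"nColumns={1 + 7}\n")
        fh.write("inDegrees=yes\n")
        fh.write("endheader\n")
        fh.write("time\t" + "\t".join(COORDINATES) + "\n")
        for t, row in zip(times, angles):
            fh.write(f"{t:.8f}\t" + "\t".join(f"{v:.10f}" for v in row) + "\n")


def read_motion(path):
    """Read a MOT/STO (or CSV) joint-angle table -> (times, (n, 7) angles)."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path)
        missing = [c for c in COORDINATES if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing coordinate columns {missing}")
        return df["time"].to_numpy(), df[list(COORDINATES)].to_numpy()
    with open(path) as fh:
        lines = fh.read().splitlines()
    try:
        end = next(i for i, l in enumerate(lines) if l.strip() == "endheader")
    except StopIteration:
        raise FormatError(f"{path}: no endheader line") from None
    header = dict(
        l.split("=", 1) for l in lines[1:end] if "=" in l
    )
    if header.get("inDegrees", "yes").strip() != "yes":
        raise FormatError(f"{path}: only inDegrees=yes tables are supported")
    cols = lines[end + 1].split("\t")
    missing = [c for c in COORDINATES if c not in cols]
    if missing:
        raise FormatError(f"{path}: missing coordinate columns {missing}")
    data = np.array(
        [[float(v) for v in l.split("\t")] for l in lines[end + 2 :] if l.strip()]
    )
    times = data[:, cols.index("time")]
    angles = data[:, [cols.index(c) for c in COORDINATES]]
    return times, angles


# ---------------------------------------------------------------------------
# CSV markers and quaternions
# ---------------------------------------------------------------------------


def write_markers_csv(path, trajectory: MarkerTrajectory) -> None:
    cols = {"time": np.asarray(trajectory.times, dtype=float)}
    for j, name in enumerate(trajectory.names):
        for k, ax in enumerate("XYZ"):
            cols[f"{name}_{ax}"] = trajectory.positions[:, j, k]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_markers_csv(path) -> MarkerTrajectory:
    df = pd.read_csv(path)
    missing = [
        f"{m}_{ax}" for m in MARKER_NAMES for ax in "XYZ" if f"{m}_{ax}" not in df.columns
    ]
    if missing:
        raise FormatError(f"{path}: missing marker columns {missing}")
    n = len(df)
    pos = np.empty((n, 12, 3))
    for j, name in enumerate(MARKER_NAMES):
        for k, ax in enumerate("XYZ"):
            pos[:, j, k] = df[f"{name}_{ax}"]
    return MarkerTrajectory(times=df["time"].to_numpy(), positions=pos)


def write_quaternions_csv(path, trajectory: OrientationTrajectory) -> None:
    """Scalar-first (qw qx qy qz) world-to-segment quaternions per segment."""
    cols = {"time": np.asarray(trajectory.times, dtype=float)}
    for s, seg in enumerate(SEGMENTS):
        for k, comp in enumerate(("qw", "qx", "qy", "qz")):
            cols[f"{seg}_{comp}"] = trajectory.quaternions[:, s, k]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_quaternions_csv(path) -> OrientationTrajectory:
    df = pd.read_csv(path)
    missing = [
        f"{seg}_{c}"
        for seg in SEGMENTS
        for c in ("qw", "qx", "qy", "qz")
        if f"{seg}_{c}" not in df.columns
    ]
    if missing:
        raise FormatError(f"{path}: missing quaternion columns {missing}")
    n = len(df)
    q = np.empty((n, 3, 4))
    for s, seg in enumerate(SEGMENTS):
        for k, comp in enumerate(("qw", "qx", "qy", "qz")):
            q[:, s, k] = df[f"{seg}_{comp}"]
    norms = np.linalg.norm(q, axis=2)
    if np.any(np.abs(norms - 1.0) > 1e-6):
        raise FormatError(f"{path}: non-unit quaternion (worst norm {norms.max():.6f})")
    return OrientationTrajectory(times=df["time"].to_numpy(), quaternions=q)
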