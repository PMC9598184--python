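"""Shared containers, channel vocabulary and file IO for the gait pipeline.

Lab convention used throughout the package: X anterior (walking direction),
Y pointing left, Z up.  The ground plane is Z = 0 and the sagittal plane is
the X-Z plane.  All angles are in degrees, marker coordinates in millimetres,
forces in newtons.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError

# --------------------------------------------------------------------------
# Channel vocabulary
# --------------------------------------------------------------------------

#: Segment-pair names (proximal_distal) whose relative orientation is tracked.
EULER_PAIRS: tuple[str, ...] = ("Sha_Foot", "Sha_Cal", "Cal_Mid", "Cal_Met", "Mid_Met")

#: Pairs generated independently in marker mode; Cal_Met is derived by
#: composing Cal_Mid with Mid_Met so the rigid chain stays consistent.
FREE_PAIRS: tuple[str, ...] = ("Sha_Foot", "Sha_Cal", "Cal_Mid", "Mid_Met")

#: Multisegment-foot groups (inter-foot-segment pairs) vs the single-segment
#: ankle pair.
MSF_GROUPS: tuple[str, ...] = ("Cal_Met", "Cal_Mid", "Mid_Met", "Sha_Cal")
SSF_GROUP: str = "Sha_Foot"

COMPONENTS: str = "XYZ"

#: Planar projection angle identifiers.
PLANAR_IDS: tuple[str, ...] = ("F2G", "S2G", "S2F", "V2G", "S2V", "F2Ps", "F2Pt", "MLA")

#: Number of samples of a normalized gait cycle (0..100 % inclusive).
N_CYCLE_POINTS: int = 101

LABELS: tuple[str, str] = ("autism", "control")
POSITIVE_LABEL: str = "autism"


def euler_channels(pairs: tuple[str, ...] = EULER_PAIRS) -> list[str]:
    """All Euler channel names, e.g. ``Mid_Met_AngleY``."""
    return [f"{p}_Angle{c}" for p in pairs for c in COMPONENTS]


def split_euler_channel(channel: str) -> tuple[str, int]:
    """Return (pair, component index) for an Euler channel name."""
    if "_Angle" not in channel:
        raise InputError(f"not an Euler channel name: {channel!r}")
    pair, comp = channel.rsplit("_Angle", 1)
    if pair not in EULER_PAIRS or comp not in COMPONENTS:
        raise InputError(f"unknown Euler channel: {channel!r}")
    return pair, COMPONENTS.index(comp)


def normalize_group_name(name: str) -> str:
    """Accept hyphenated group names ('Cal-Met') and return canonical form."""
    return name.replace("-", "_")


# --------------------------------------------------------------------------
# Containers
# --------------------------------------------------------------------------


@dataclass
class MarkerTrajectorySet:
    """Time-indexed 3-D positions (mm) for named markers of one trial."""

    time: np.ndarray                      # (T,) seconds
    positions: dict[str, np.ndarray]      # name -> (T, 3) mm
    fs: float                             # Hz
    trial_id: str = ""

    @property
    def n_frames(self) -> int:
        return len(self.time)

    @property
    def marker_names(self) -> list[str]:
        return list(self.positions)

    def subset(self, names: list[str]) -> "MarkerTrajectorySet":
        return MarkerTrajectorySet(
            self.time, {n: self.positions[n] for n in names}, self.fs, self.trial_id
        )


@dataclass
class AngleCurveSet:
    """Euler curves for each segment pair plus planar projection curves.

    ``euler[pair]`` is a (T, 3) array of X/Y/Z angles in degrees and
    ``planar[pid]`` a (T,) array.  When ``normalized`` is True the time base
    is the 0..100 % gait-cycle grid (T = 101) and ``stance_end`` holds the
    toe-off instant in % of cycle.
    """

    euler: dict[str, np.ndarray]
    planar: dict[str, np.ndarray]
    time: np.ndarray | None = None         # raw seconds; None when normalized
    normalized: bool = False
    stance_end: float | None = None        # % gait cycle

    @property
    def n_samples(self) -> int:
        first = next(iter(self.euler.values()))
        return first.shape[0]

    def channel_names(self) -> list[str]:
        names = [f"{p}_Angle{c}" for p in self.euler for c in COMPONENTS]
        names.extend(self.planar)
        return names

    def get_channel(self, name: str) -> np.ndarray:
        if name in self.planar:
            return self.planar[name]
        pair, ci = split_euler_channel(name)
        return self.euler[pair][:, ci]

    def set_channel(self, name: str, values: np.ndarray) -> None:
        if name in self.planar:
            self.planar[name] = np.asarray(values, dtype=float)
            return
        pair, ci = split_euler_channel(name)
        self.euler[pair][:, ci] = values

    def copy(self) -> "AngleCurveSet":
        return AngleCurveSet(
            {k: v.copy() for k, v in self.euler.items()},
            {k: v.copy() for k, v in self.planar.items()},
            None if self.time is None else self.time.copy(),
            self.normalized,
            self.stance_end,
        )

    def to_tidy_frame(self, trial_id: str = "") -> pd.DataFrame:
        """Long-format frame: trial, channel, t, value."""
        t = (
            np.arange(self.n_samples, dtype=float)
            if self.time is None
            else np.asarray(self.time, dtype=float)
        )
        records = []
        for name in self.channel_names():
            vals = self.get_channel(name)
            records.append(
                pd.DataFrame(
                    {"trial": trial_id, "channel": name, "t": t, "value": vals}
                )
            )
        return pd.concat(records, ignore_index=True)


# --------------------------------------------------------------------------
# TRC / CSV marker file IO
# --------------------------------------------------------------------------


def write_trc(path: str | Path, markers: MarkerTrajectorySet) -> None:
    """Write a TRC (Track Row Column) marker file, coordinates in mm."""
    path = Path(path)
    names = markers.marker_names
    n = markers.n_frames
    fs = markers.fs
    with open(path, "w") as fh:
        fh.write(f"PathFileType\t4\t(X/Y/Z)\t{path.name}\n")
        fh.write(
            "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\t"
            "OrigDataRate\tOrigDataStartFrame\tOrigNumFrames\n"
        )
        fh.write(f"{fs:g}\t{fs:g}\t{n}\t{len(names)}\tmm\t{fs:g}\t1\t{n}\n")
        head = "Frame#\tTime\t" + "\t\t\t".join(names)
        fh.write(head + "\n")
        sub = "\t\t" + "\t".join(
            f"X{i}\tY{i}\tZ{i}" for i in range(1, len(names) + 1)
        )
        fh.write(sub + "\n\n")
        cols = np.column_stack([markers.positions[nm] for nm in names])
        for i in range(n):
            row = "\t".join(f"{v:.6f}" for v in cols[i])
            fh.write(f"{i + 1}\t{markers.time[i]:.6f}\t{row}\n")


def read_trc(path: str | Path) -> MarkerTrajectorySet:
    """Read a TRC marker file written by :func:`write_trc` (or Vicon export)."""
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    meta = lines[2].split("\t")
    fs = float(meta[0])
    names = [n for n in lines[3].split("\t")[2:] if n]
    data_lines = [ln for ln in lines[5:] if ln.strip()]
    raw = np.array([[float(v) if v else np.nan for v in ln.split("\t")]
                    for ln in data_lines])
    time = raw[:, 1]
    positions = {
        nm: raw[:, 2 + 3 * i : 5 + 3 * i] for i, nm in enumerate(names)
    }
    return MarkerTrajectorySet(time, positions, fs, trial_id=path.stem)


def write_markers_csv(path: str | Path, markers: MarkerTrajectorySet) -> None:
    """Wide CSV: time + <marker>_X/_Y/_Z columns in mm."""
    data = {"time": markers.time}
    for nm in markers.marker_names:
        for j, ax in enumerate("XYZ"):
            data[f"{nm}_{ax}"] = markers.positions[nm][:, j]
    pd.DataFrame(data).to_csv(path, index=False)


def read_markers_csv(path: str | Path, fs: float | None = None) -> MarkerTrajectorySet:
    df = pd.read_csv(path)
    time = df["time"].to_numpy(float)
    if fs is None:
        fs = 1.0 / float(np.median(np.diff(time)))
    names: list[str] = []
    for col in df.columns:
        if col.endswith("_X"):
            names.append(col[:-2])
    positions = {
        nm: df[[f"{nm}_X", f"{nm}_Y", f"{nm}_Z"]].to_numpy(float) for nm in names
    }
    return MarkerTrajectorySet(time, positions, fs, trial_id=Path(path).stem)


def write_grf_csv(path: str | Path, time: np.ndarray, fz: np.ndarray) -> None:
    pd.DataFrame({"time_s": time, "Fz_N": fz}).to_csv(path, index=False)


def read_grf_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    return df["time_s"].to_numpy(float), df["Fz_N"].to_numpy(float)


def write_json(path: str | Path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
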