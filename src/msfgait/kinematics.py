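"""Marker trajectories -> segment frames -> relative Euler and planar angles.

The foot is modelled as five rigid segments: shank (Sha), total/single-segment
foot (Foot), calcaneus (Cal), midfoot (Mid) and forefoot/metatarsus (Met).
Relative orientation of each tracked pair (Sha-Foot, Sha-Cal, Cal-Mid,
Cal-Met, Mid-Met) is decomposed as intrinsic x-y-z Euler angles:
X = flexion/extension (dorsi/plantarflexion), Y = adduction/abduction or
inversion/eversion, Z = internal/external rotation.

Each segment frame is built from a marker triad: the frame origin is the
triad centroid, the provisional x axis runs between two roughly
anterior-posterior markers projected orthogonal to the triad-plane normal,
z is the triad normal (winding chosen so z points up/proximal at the
reference pose) and y = z x x.  The reported rotation is expressed relative
to the frame computed at the segment's stored reference pose, so a segment
sitting exactly at its reference pose has identity orientation.  Because the
construction uses only differences and cross products of marker positions it
co-rotates exactly with any rigid motion applied to the whole marker set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .core import (
    EULER_PAIRS,
    PLANAR_IDS,
    AngleCurveSet,
    MarkerTrajectorySet,
)
from .errors import (
    ConfigurationError,
    DegenerateGeometryError,
    InputError,
    MarkerGapError,
)

logger = logging.getLogger(__name__)

GIMBAL_MARGIN_DEG = 0.5  # |angleY| closer than this to 90 deg logs a warning


# --------------------------------------------------------------------------
# Reference marker geometry (mm) — right foot at neutral, lab X anterior,
# Y left, Z up.  Synthetic marker clouds and the default frame recipes share
# this table; real captures supply their own via the marker-map config.
# --------------------------------------------------------------------------

REFERENCE_GEOMETRY: dict[str, list[float]] = {
    # shank
    "SHA1": [30.0, 35.0, 320.0],
    "SHA2": [25.0, -35.0, 315.0],
    "SHA3": [-5.0, 0.0, 160.0],
    # total foot (single-segment model)
    "FOOT1": [55.0, 0.0, 62.0],
    "FOOT2": [140.0, 32.0, 45.0],
    "FOOT3": [138.0, -30.0, 44.0],
    # calcaneus
    "CAL1": [0.0, 0.0, 40.0],
    "CAL2": [18.0, 26.0, 58.0],
    "CAL3": [16.0, -24.0, 56.0],
    # midfoot
    "NAV": [92.0, 26.0, 46.0],
    "CUB": [86.0, -30.0, 34.0],
    "MID3": [110.0, -2.0, 52.0],
    # metatarsus; M<n>B/M<n>H = base/head of metatarsal n
    "M1B": [120.0, 30.0, 30.0],
    "M1H": [185.0, 32.0, 12.0],
    "M2B": [125.0, 8.0, 32.0],
    "M2H": [190.0, 8.0, 15.0],
    "M5B": [115.0, -35.0, 25.0],
    "M5H": [175.0, -40.0, 10.0],
    # hallux proximal phalanx tip (modelled as a line from M1H)
    "HLX": [225.0, 30.0, 6.0],
}

SEGMENT_MARKERS: dict[str, list[str]] = {
    "Sha": ["SHA1", "SHA2", "SHA3"],
    "Foot": ["FOOT1", "FOOT2", "FOOT3"],
    "Cal": ["CAL1", "CAL2", "CAL3"],
    "Mid": ["NAV", "CUB", "MID3"],
    "Met": ["M1B", "M1H", "M2B", "M2H", "M5B", "M5H", "HLX"],
}

#: Planar projection angle definitions.  kind: 'sag_ground' = sagittal-plane
#: angle between the directed marker line and the anterior ground axis;
#: 'transverse' = transverse-plane angle between two marker lines;
#: 'mla' = sagittal interior angle at the apex (medial longitudinal arch).
PLANAR_DEFS: dict[str, dict] = {
    "F2G": {"kind": "sag_ground", "line": ("M1B", "M1H")},
    "S2G": {"kind": "sag_ground", "line": ("M2B", "M2H")},
    "V2G": {"kind": "sag_ground", "line": ("M5B", "M5H")},
    "S2F": {"kind": "transverse", "line": ("M1B", "M1H"), "line2": ("M2B", "M2H")},
    "S2V": {"kind": "transverse", "line": ("M5B", "M5H"), "line2": ("M2B", "M2H")},
    "F2Ps": {"kind": "sagittal_pair", "line": ("M1B", "M1H"), "line2": ("M1H", "HLX")},
    "F2Pt": {"kind": "transverse", "line": ("M1B", "M1H"), "line2": ("M1H", "HLX")},
    "MLA": {"kind": "mla", "points": ("CAL1", "NAV", "M1H")},
}


@dataclass
class SegmentRecipe:
    """How to build one segment's coordinate frame from its markers."""

    name: str
    markers: list[str]
    triad: tuple[str, str, str]
    ap_axis: tuple[str, str]                 # posterior, anterior marker
    reference: dict[str, np.ndarray]         # marker -> (3,) reference position
    _ref_frame: np.ndarray | None = field(default=None, repr=False)

    def reference_frame(self) -> np.ndarray:
        if self._ref_frame is None:
            pos = {m: np.asarray(self.reference[m], float) for m in self.markers}
            self._ref_frame = _frame_axes(pos, self.triad, self.ap_axis)
        return self._ref_frame


def default_recipes(
    geometry: dict[str, list[float]] | None = None,
) -> dict[str, SegmentRecipe]:
    """Default frame recipe per segment, based on the reference geometry."""
    geo = geometry or REFERENCE_GEOMETRY
    spec = {
        "Sha": (("SHA1", "SHA2", "SHA3"), ("SHA3", "SHA1")),
        "Foot": (("FOOT1", "FOOT2", "FOOT3"), ("FOOT1", "FOOT2")),
        "Cal": (("CAL1", "CAL2", "CAL3"), ("CAL1", "CAL2")),
        "Mid": (("NAV", "CUB", "MID3"), ("CUB", "NAV")),
        "Met": (("M1B", "M5B", "M2H"), ("M2B", "M2H")),
    }
    out = {}
    for seg, (triad, ap) in spec.items():
        out[seg] = SegmentRecipe(
            name=seg,
            markers=SEGMENT_MARKERS[seg],
            triad=triad,
            ap_axis=ap,
            reference={m: np.asarray(geo[m], float) for m in SEGMENT_MARKERS[seg]},
        )
    return out


# --------------------------------------------------------------------------
# Filtering
# --------------------------------------------------------------------------


def butterworth_lowpass(
    x: np.ndarray, fs: float, fc: float = 8.0, order: int = 2
) -> np.ndarray:
    """Zero-phase low-pass Butterworth filter (forward-backward pass).

    The dual pass doubles the effective order and removes phase lag; DC gain
    is exactly 1.  ``x`` may be (T,) or (T, k); filtering is along axis 0.
    """
    if fc >= fs / 2:
        raise InputError(f"cut-off {fc} Hz must be below Nyquist ({fs / 2} Hz)")
    x = np.asarray(x, float)
    if x.shape[0] <= 3 * order:
        raise InputError("signal too short for the requested filter order")
    sos = signal.butter(order, fc, btype="low", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x, axis=0)


def filter_markers(
    markers: MarkerTrajectorySet, fc: float = 8.0, order: int = 2
) -> MarkerTrajectorySet:
    """Apply the zero-phase Butterworth filter to every marker coordinate."""
    out = {
        nm: butterworth_lowpass(p, markers.fs, fc, order)
        for nm, p in markers.positions.items()
    }
    return MarkerTrajectorySet(markers.time, out, markers.fs, markers.trial_id)


# --------------------------------------------------------------------------
# Segment frames
# --------------------------------------------------------------------------


def _frame_axes(
    pos: dict[str, np.ndarray],
    triad: tuple[str, str, str],
    ap_axis: tuple[str, str],
) -> np.ndarray:
    """Orthonormal frame [x y z] from one segment's marker positions (one frame)."""
    p1, p2, p3 = (pos[m] for m in triad)
    n = np.cross(p2 - p1, p3 - p1)
    n_norm = np.linalg.norm(n)
    scale = max(np.linalg.norm(p2 - p1), np.linalg.norm(p3 - p1), 1e-12)
    if n_norm < 1e-9 * scale**2:
        raise DegenerateGeometryError(
            f"collinear triad {triad}: cannot define a plane normal"
        )
    z = n / n_norm
    a = pos[ap_axis[1]] - pos[ap_axis[0]]
    x = a - (a @ z) * z
    x_norm = np.linalg.norm(x)
    if x_norm < 1e-9 * max(np.linalg.norm(a), 1e-12):
        raise DegenerateGeometryError(
            f"anterior-posterior axis {ap_axis} is parallel to the triad normal"
        )
    x = x / x_norm
    y = np.cross(z, x)
    return np.column_stack([x, y, z])


def build_segment_frame(
    positions: dict[str, np.ndarray], recipe: SegmentRecipe
) -> tuple[np.ndarray, np.ndarray]:
    """Rotation (relative to the recipe's reference pose) and origin for one frame.

    Returns ``(R, origin)`` with R proper orthogonal: R maps reference-pose
    directions onto current directions, so at the reference pose R = I.
    """
    frame = _frame_axes(positions, recipe.triad, recipe.ap_axis)
    R = frame @ recipe.reference_frame().T
    origin = np.mean([positions[m] for m in recipe.triad], axis=0)
    return R, origin


def segment_frame_series(
    markers: MarkerTrajectorySet, recipe: SegmentRecipe
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame rotations (T,3,3) and origins (T,3) for one segment."""
    T = markers.n_frames
    for m in recipe.markers:
        if m not in markers.positions:
            raise MarkerGapError(m, 0, markers.trial_id)
        bad = np.flatnonzero(~np.isfinite(markers.positions[m]).all(axis=1))
        if bad.size:
            raise MarkerGapError(m, int(bad[0]), markers.trial_id)
    rotations = np.empty((T, 3, 3))
    origins = np.empty((T, 3))
    for t in range(T):
        pos = {m: markers.positions[m][t] for m in recipe.markers}
        rotations[t], origins[t] = build_segment_frame(pos, recipe)
    return rotations, origins


# --------------------------------------------------------------------------
# Euler decomposition
# --------------------------------------------------------------------------


def euler_xyz_from_matrix(R: np.ndarray) -> np.ndarray:
    """Intrinsic x-y-z Euler angles (degrees) of rotation matrices.

    Decomposes R = Rx(a) @ Ry(b) @ Rz(c) with b in [-90, 90].  Accepts a
    single (3,3) matrix or a stack (..., 3, 3); returns (..., 3).
    """
    R = np.asarray(R, float)
    b = np.arcsin(np.clip(R[..., 0, 2], -1.0, 1.0))
    a = np.arctan2(-R[..., 1, 2], R[..., 2, 2])
    c = np.arctan2(-R[..., 0, 1], R[..., 0, 0])
    return np.degrees(np.stack([a, b, c], axis=-1))


def matrix_from_euler_xyz(angles_deg: np.ndarray) -> np.ndarray:
    """Compose Rx(a) @ Ry(b) @ Rz(c) from intrinsic x-y-z angles in degrees."""
    a, b, c = np.moveaxis(np.radians(np.asarray(angles_deg, float)), -1, 0)
    ca, sa = np.cos(a), np.sin(a)
    cb, sb = np.cos(b), np.sin(b)
    cc, sc = np.cos(c), np.sin(c)
    row0 = np.stack([cb * cc, -cb * sc, sb], axis=-1)
    row1 = np.stack([sa * sb * cc + ca * sc, -sa * sb * sc + ca * cc, -sa * cb], axis=-1)
    row2 = np.stack([-ca * sb * cc + sa * sc, ca * sb * sc + sa * cc, ca * cb], axis=-1)
    return np.stack([row0, row1, row2], axis=-2)


def relative_euler_xyz(
    R_proximal: np.ndarray, R_distal: np.ndarray, trial: str = ""
) -> np.ndarray:
    """Euler x-y-z angles of the distal segment expressed in the proximal frame.

    R_rel = R_proximal^T @ R_distal.  Angles within ``GIMBAL_MARGIN_DEG`` of
    the gimbal singularity (|angleY| = 90) are logged, never clipped.
    """
    Rp = np.asarray(R_proximal, float)
    Rd = np.asarray(R_distal, float)
    R_rel = np.swapaxes(Rp, -1, -2) @ Rd
    ang = euler_xyz_from_matrix(R_rel)
    near = np.abs(np.abs(np.atleast_2d(ang)[..., 1]) - 90.0) < GIMBAL_MARGIN_DEG
    if np.any(near):
        logger.warning(
            "gimbal proximity (|angleY| near 90 deg) in %d frame(s)%s",
            int(np.sum(near)),
            f" of trial {trial!r}" if trial else "",
        )
    return ang


# --------------------------------------------------------------------------
# Planar projection angles
# --------------------------------------------------------------------------


def _proj_angle_to_ground(v: np.ndarray, plane: str) -> np.ndarray:
    """Directed angle [0, 180] deg between projected vector and +X ground line."""
    if plane == "sagittal":
        u = np.stack([v[..., 0], v[..., 2]], axis=-1)   # X-Z
    else:
        u = np.stack([v[..., 0], v[..., 1]], axis=-1)   # X-Y
    norm = np.linalg.norm(u, axis=-1)
    if np.any(norm < 1e-9):
        raise DegenerateGeometryError("zero-length projected segment")
    return np.degrees(np.arccos(np.clip(u[..., 0] / norm, -1.0, 1.0)))


def _proj_angle_between(v1: np.ndarray, v2: np.ndarray, plane: str) -> np.ndarray:
    """Directed angle [0, 180] deg between two projected vectors."""
    idx = (0, 2) if plane == "sagittal" else (0, 1)
    u1 = np.stack([v1[..., idx[0]], v1[..., idx[1]]], axis=-1)
    u2 = np.stack([v2[..., idx[0]], v2[..., idx[1]]], axis=-1)
    n1 = np.linalg.norm(u1, axis=-1)
    n2 = np.linalg.norm(u2, axis=-1)
    if np.any(n1 < 1e-9) or np.any(n2 < 1e-9):
        raise DegenerateGeometryError("zero-length projected segment")
    cosang = np.sum(u1 * u2, axis=-1) / (n1 * n2)
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def planar_angle(angle_id: str, positions: dict[str, np.ndarray]) -> np.ndarray:
    """One planar projection angle (degrees) from marker positions.

    Works frame-wise: position arrays may be (3,) or (T, 3).
    """
    if angle_id not in PLANAR_DEFS:
        raise InputError(f"unknown planar angle id: {angle_id!r}")
    d = PLANAR_DEFS[angle_id]
    if d["kind"] == "mla":
        a, apex, b = (np.asarray(positions[m], float) for m in d["points"])
        return _proj_angle_between(a - apex, b - apex, "sagittal")
    v1 = np.asarray(positions[d["line"][1]], float) - np.asarray(
        positions[d["line"][0]], float
    )
    if d["kind"] == "sag_ground":
        return _proj_angle_to_ground(v1, "sagittal")
    v2 = np.asarray(positions[d["line2"][1]], float) - np.asarray(
        positions[d["line2"][0]], float
    )
    plane = "sagittal" if d["kind"] == "sagittal_pair" else "transverse"
    return _proj_angle_between(v1, v2, plane)


# --------------------------------------------------------------------------
# Pipeline assembly
# --------------------------------------------------------------------------

#: (proximal, distal) segments for every tracked pair.
PAIR_SEGMENTS: dict[str, tuple[str, str]] = {
    "Sha_Foot": ("Sha", "Foot"),
    "Sha_Cal": ("Sha", "Cal"),
    "Cal_Mid": ("Cal", "Mid"),
    "Cal_Met": ("Cal", "Met"),
    "Mid_Met": ("Mid", "Met"),
}


def compute_angles(
    markers: MarkerTrajectorySet,
    recipes: dict[str, SegmentRecipe] | None = None,
    prefiltered: bool = True,
    fc: float = 8.0,
) -> AngleCurveSet:
    """All Euler pair curves + planar curves on the raw marker time base.

    Set ``prefiltered=False`` to apply the 8 Hz zero-phase Butterworth filter
    first (the planar angles are then computed from filtered markers too).
    """
    recipes = recipes or default_recipes()
    if not prefiltered:
        markers = filter_markers(markers, fc=fc)
    missing = [r for r in ("Sha", "Foot", "Cal", "Mid", "Met") if r not in recipes]
    if missing:
        raise ConfigurationError(f"missing frame recipes for segments: {missing}")
    rot = {}
    for seg, recipe in recipes.items():
        rot[seg], _ = segment_frame_series(markers, recipe)
    euler = {}
    for pair, (prox, dist) in PAIR_SEGMENTS.items():
        euler[pair] = relative_euler_xyz(rot[prox], rot[dist], markers.trial_id)
    planar = {}
    for pid in PLANAR_IDS:
        d = PLANAR_DEFS[pid]
        needed = d.get("points", ()) or (d["line"] + d.get("line2", ()))
        pos = {m: markers.positions[m] for m in needed}
        planar[pid] = planar_angle(pid, pos)
    return AngleCurveSet(euler, planar, time=markers.time.copy(), normalized=False)
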