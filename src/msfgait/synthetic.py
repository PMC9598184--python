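"""Seeded synthetic gait cohorts: angle curves, rigid-marker clouds, GRF traces.

The generator emulates a two-group walking cohort (autism vs control, default
19/21 participants, one selected gait cycle each) with group differences
concentrated where the clinical literature places them: midfoot-forefoot
(Mid-Met) eversion and internal rotation, and the sagittal pitch of the first
metatarsal against the ground (F2G).

Every angle channel is a smooth periodic base curve — an order-6 truncated
Fourier series fitted to hand-drawn keypoint templates of typical gait
shapes — plus per-participant variation (relative jitter of the Fourier
coefficients, a constant offset, and a global phase shift of at most 2 % of
the cycle).  Group effects from ``effect_map`` are applied as offsets (and
optional scalings) to the autism group only.

Two cohort modes exist:

``angles``
    Every Euler and planar channel is an independent Fourier curve sampled
    straight onto the normalized 101-point gait-cycle grid.  Fast; used for
    classification and attribution studies where an effect configured on one
    channel must stay confined to that channel.

``markers``
    A rigid-body forward model: relative segment rotations are composed into
    a kinematic chain, marker clouds ride on the segments, and a vertical
    GRF trace gates stance.  The Cal-Met Euler truth is *derived* by
    composing Cal-Mid with Mid-Met, and planar truths are computed from the
    noise-free marker geometry, so the kinematics module can round-trip the
    generator exactly at zero noise.

The F2G calibration mode shifts each participant's foot pitch so that the
cohort's F2G maxima during stance are draws from the reported group
distributions (autism 84.15 +/- 15.29 deg, control 91.38 +/- 10.47 deg).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.interpolate import CubicSpline

from . import core
from .core import (
    EULER_PAIRS,
    FREE_PAIRS,
    N_CYCLE_POINTS,
    PLANAR_IDS,
    AngleCurveSet,
    MarkerTrajectorySet,
    euler_channels,
    write_grf_csv,
    write_json,
    write_markers_csv,
    write_trc,
)
from .errors import ConfigurationError, DegenerateGeometryError
from .kinematics import (
    PLANAR_DEFS,
    REFERENCE_GEOMETRY,
    SEGMENT_MARKERS,
    matrix_from_euler_xyz,
    euler_xyz_from_matrix,
    planar_angle,
)

GRAVITY = 9.81

#: F2G max-in-stance calibration targets, degrees (mean, sd) per group.
F2G_TARGETS: dict[str, tuple[float, float]] = {
    "autism": (84.15, 15.29),
    "control": (91.38, 10.47),
}

# --------------------------------------------------------------------------
# Base-curve templates: keypoints (% gait cycle, degrees), fitted once to an
# order-6 periodic Fourier series.
# --------------------------------------------------------------------------

TEMPLATE_KEYPOINTS: dict[str, list[tuple[float, float]]] = {
    # ankle (shank vs total foot): dorsi(+)/plantar(-) flexion X, inv/ev Y,
    # int/ext rotation Z
    "Sha_Foot_AngleX": [(0, 0), (8, -5), (45, 10), (62, -18), (75, -5), (90, 2)],
    "Sha_Foot_AngleY": [(0, 2), (30, -2), (60, 3), (80, 0), (95, 2)],
    "Sha_Foot_AngleZ": [(0, -3), (50, 3), (62, 5), (85, -2), (95, -3)],
    "Sha_Cal_AngleX": [(0, 0), (10, -4), (45, 6), (62, -12), (80, -2), (95, 0)],
    "Sha_Cal_AngleY": [(0, 1), (15, -3), (50, 2), (62, 4), (90, 1)],
    "Sha_Cal_AngleZ": [(0, -2), (40, 2), (62, 4), (90, -1)],
    "Cal_Mid_AngleX": [(0, 0), (30, 3), (62, -6), (80, -1), (95, 0)],
    "Cal_Mid_AngleY": [(0, -1), (40, 2), (62, -3), (90, -1)],
    "Cal_Mid_AngleZ": [(0, 1), (50, -2), (62, 2), (90, 1)],
    "Mid_Met_AngleX": [(0, 0), (30, 2), (62, -8), (85, -1), (95, 0)],
    "Mid_Met_AngleY": [(0, -2), (30, -4), (62, 2), (90, -2)],
    "Mid_Met_AngleZ": [(0, 1), (45, -2), (62, 3), (90, 1)],
    # Cal_Met used only in angle mode (derived from the chain in marker mode)
    "Cal_Met_AngleX": [(0, 0), (30, 5), (62, -13), (85, -2), (95, 0)],
    "Cal_Met_AngleY": [(0, -3), (30, -6), (62, 3), (90, -3)],
    "Cal_Met_AngleZ": [(0, 2), (45, -4), (62, 5), (90, 2)],
    # planar projection angles (angle mode)
    "F2G": [(0, 18), (10, 16), (45, 22), (62, 88), (75, 40), (90, 20)],
    "S2G": [(0, 16), (45, 20), (62, 80), (75, 36), (90, 18)],
    "V2G": [(0, 14), (45, 18), (62, 70), (75, 32), (90, 16)],
    "S2F": [(0, 12), (30, 11), (62, 15), (90, 12)],
    "S2V": [(0, 22), (30, 21), (62, 26), (90, 22)],
    "F2Ps": [(0, 12), (40, 14), (62, 25), (80, 15), (95, 12)],
    "F2Pt": [(0, 8), (40, 7), (62, 11), (90, 8)],
    "MLA": [(0, 140), (30, 138), (62, 148), (85, 142), (95, 140)],
    # whole-foot sagittal pitch (marker mode): drives heel rise and F2G
    "_foot_pitch": [(0, -3), (8, 0), (45, 5), (62, 72), (72, 25), (82, 3), (95, -3)],
}

FOURIER_ORDER = 6


def _fit_fourier(keypoints: list[tuple[float, float]], order: int = FOURIER_ORDER):
    """Fit (a0, a[1..order], b[1..order]) to periodic keypoints.

    Keypoints are interpolated with a periodic cubic spline, densely sampled,
    and truncated in the Fourier domain — guaranteeing a smooth periodic
    curve through approximately the drawn shape.
    """
    pct = np.array([k[0] for k in keypoints], float) / 100.0
    val = np.array([k[1] for k in keypoints], float)
    pct = np.append(pct, 1.0)
    val = np.append(val, val[0])
    spline = CubicSpline(pct, val, bc_type="periodic")
    grid = np.linspace(0.0, 1.0, 128, endpoint=False)
    coeffs = np.fft.rfft(spline(grid)) / 128
    a0 = coeffs[0].real
    a = 2 * coeffs[1 : order + 1].real
    b = -2 * coeffs[1 : order + 1].imag
    return a0, a, b


class FourierCurve:
    """Order-6 truncated Fourier series over one gait cycle (phase in [0,1))."""

    __slots__ = ("a0", "a", "b")

    def __init__(self, a0: float, a: np.ndarray, b: np.ndarray):
        self.a0 = float(a0)
        self.a = np.asarray(a, float)
        self.b = np.asarray(b, float)

    def __call__(self, phase: np.ndarray, shift: float = 0.0) -> np.ndarray:
        phase = np.asarray(phase, float) - shift
        k = np.arange(1, len(self.a) + 1)
        arg = 2 * np.pi * np.outer(phase, k)
        return self.a0 + np.cos(arg) @ self.a + np.sin(arg) @ self.b

    def jittered(self, rng: np.random.Generator, coef_rel: float, offset_sd: float):
        a = self.a * (1 + rng.normal(0, coef_rel, self.a.shape))
        b = self.b * (1 + rng.normal(0, coef_rel, self.b.shape))
        return FourierCurve(self.a0 + rng.normal(0, offset_sd), a, b)

    def shifted(self, offset: float = 0.0, scale: float = 1.0):
        return FourierCurve(self.a0 + offset, self.a * scale, self.b * scale)


def base_curves() -> dict[str, FourierCurve]:
    """The fitted template curve for every channel (cached)."""
    global _BASE_CACHE
    if _BASE_CACHE is None:
        _BASE_CACHE = {
            name: FourierCurve(*_fit_fourier(kp))
            for name, kp in TEMPLATE_KEYPOINTS.items()
        }
    return _BASE_CACHE


_BASE_CACHE: dict[str, FourierCurve] | None = None


# --------------------------------------------------------------------------
# Cohort configuration
# --------------------------------------------------------------------------


def _default_effect_map() -> dict[str, float]:
    # decreased eversion (Y offset up, toward inversion is +; eversion is -)
    # and increased internal rotation on the midfoot-forefoot pair
    return {"Mid_Met_AngleY": -5.0, "Mid_Met_AngleZ": 5.0}


def _default_speeds() -> dict[str, tuple[float, float]]:
    return {"autism": (1.25, 0.28), "control": (1.21, 0.16)}


@dataclass
class CohortConfig:
    """Study conditions of a synthetic two-group cohort."""

    n_autism: int = 19
    n_control: int = 21
    marker_fs: float = 100.0
    grf_fs: float = 1000.0
    stance_fraction: float = 0.60
    effect_map: dict[str, float | dict] = field(default_factory=_default_effect_map)
    marker_noise_sd: float = 0.5          # mm
    angle_noise_sd: float = 0.5           # degrees (angle mode measurement noise)
    walking_speed: dict[str, tuple[float, float]] = field(default_factory=_default_speeds)
    coef_jitter_rel: float = 0.10         # relative SD on Fourier harmonics
    offset_jitter_sd: float = 1.5         # degrees, per-participant offset
    phase_jitter_max: float = 0.02        # max |global phase shift|, cycle fraction
    f2g_calibration: bool = True
    stride_length_m: float = 1.20
    body_mass: tuple[float, float] = (42.5, 16.0)   # kg (mean, sd)
    sides: str = "single"                 # 'single' or 'both'
    seed: int = 0

    def __post_init__(self):
        if self.n_autism + self.n_control < 4:
            raise ConfigurationError("cohort must have at least 4 participants")
        if not 0 < self.stance_fraction < 1:
            raise ConfigurationError("stance_fraction must lie in (0, 1)")
        for nm, v in (
            ("marker_noise_sd", self.marker_noise_sd),
            ("angle_noise_sd", self.angle_noise_sd),
            ("coef_jitter_rel", self.coef_jitter_rel),
            ("offset_jitter_sd", self.offset_jitter_sd),
        ):
            if v < 0:
                raise ConfigurationError(f"{nm} must be >= 0")
        if self.sides not in ("single", "both"):
            raise ConfigurationError("sides must be 'single' or 'both'")

    def validate_effect_map(self, mode: str) -> None:
        allowed = set(euler_channels(FREE_PAIRS)) | {"F2G"}
        if mode == "angles":
            allowed = set(euler_channels()) | set(PLANAR_IDS)
        for ch in self.effect_map:
            if ch in ("Cal_Met_AngleX", "Cal_Met_AngleY", "Cal_Met_AngleZ") and mode == "markers":
                raise ConfigurationError(
                    f"effect channel {ch!r} is derived from Cal_Mid and Mid_Met "
                    "in marker mode and cannot carry an independent effect"
                )
            if ch not in allowed:
                raise ConfigurationError(f"unknown effect channel: {ch!r}")


@dataclass
class GroundTruthTrial:
    """One participant-side gait cycle with its generating truth attached."""

    participant_id: str
    label: str                             # 'autism' | 'control'
    side: str                              # 'left' | 'right'
    true_angle_curves: AngleCurveSet       # normalized, noise-free
    observed_angle_curves: AngleCurveSet | None = None   # normalized + noise
    true_raw_curves: AngleCurveSet | None = None         # marker time base
    marker_set: MarkerTrajectorySet | None = None
    grf_time: np.ndarray | None = None
    grf_z: np.ndarray | None = None
    event_times: tuple[float, float, float] | None = None  # (HS, TO, next HS)
    walking_speed: float = float("nan")
    body_weight: float = float("nan")      # N

    def __post_init__(self):
        if self.event_times is not None:
            hs, to, hs2 = self.event_times
            if not hs < to < hs2:
                raise ConfigurationError("event_times must be strictly increasing")
        if self.grf_z is not None and np.any(self.grf_z < 0):
            raise ConfigurationError("grf_z must be non-negative")


# --------------------------------------------------------------------------
# Per-participant curve generation
# --------------------------------------------------------------------------


def _participant_curves(
    channels: list[str],
    label: str,
    config: CohortConfig,
    rng: np.random.Generator,
) -> dict[str, FourierCurve]:
    """Jittered per-participant curves with group effects applied."""
    base = base_curves()
    phase = rng.uniform(-config.phase_jitter_max, config.phase_jitter_max)
    out: dict[str, FourierCurve] = {}
    for ch in channels:
        curve = base[ch].jittered(rng, config.coef_jitter_rel, config.offset_jitter_sd)
        if label == "autism" and ch in config.effect_map:
            eff = config.effect_map[ch]
            if isinstance(eff, dict):
                curve = curve.shifted(eff.get("offset", 0.0), eff.get("scale", 1.0))
            else:
                curve = curve.shifted(float(eff))
        # bake the global phase shift into the curve
        out[ch] = _rephase(curve, phase)
    return out


def _rephase(curve: FourierCurve, shift: float) -> FourierCurve:
    """Absorb a phase shift into the Fourier coefficients."""
    k = np.arange(1, len(curve.a) + 1)
    th = 2 * np.pi * k * shift
    a = curve.a * np.cos(th) + curve.b * np.sin(th)
    b = -curve.a * np.sin(th) + curve.b * np.cos(th)
    return FourierCurve(curve.a0, a, b)


def generate_angle_templates(
    config: CohortConfig, rng: np.random.Generator
) -> list[tuple[str, str, AngleCurveSet]]:
    """Per-participant noise-free normalized angle curves (angle mode).

    Returns (participant_id, label, AngleCurveSet) triples; every Euler and
    planar channel is generated independently, so configured effects stay on
    their channel.
    """
    config.validate_effect_map("angles")
    phase_grid = np.linspace(0.0, 1.0, N_CYCLE_POINTS)
    stance_end = config.stance_fraction * 100.0
    channels = euler_channels() + list(PLANAR_IDS)
    out = []
    labels = ["autism"] * config.n_autism + ["control"] * config.n_control
    for i, label in enumerate(labels):
        pid = f"{'A' if label == 'autism' else 'C'}{i + 1:02d}"
        curves = _participant_curves(channels, label, config, rng)
        euler = {
            pair: np.column_stack(
                [curves[f"{pair}_Angle{c}"](phase_grid) for c in "XYZ"]
            )
            for pair in EULER_PAIRS
        }
        planar = {pid_: curves[pid_](phase_grid) for pid_ in PLANAR_IDS}
        acs = AngleCurveSet(euler, planar, normalized=True, stance_end=stance_end)
        if config.f2g_calibration:
            _calibrate_f2g_curve(acs, label, config, rng)
        out.append((pid, label, acs))
    return out


def _calibrate_f2g_curve(
    acs: AngleCurveSet, label: str, config: CohortConfig, rng: np.random.Generator
) -> None:
    """Shift the F2G curve so its max-in-stance hits a group-distribution draw."""
    mu, sd = F2G_TARGETS[label]
    target = rng.normal(mu, sd)
    stance_n = int(np.floor(config.stance_fraction * 100)) + 1
    current = float(np.max(acs.planar["F2G"][:stance_n]))
    acs.planar["F2G"] = acs.planar["F2G"] + (target - current)


# --------------------------------------------------------------------------
# Marker synthesis (rigid forward model)
# --------------------------------------------------------------------------


def _rot_y(deg: np.ndarray) -> np.ndarray:
    """Stack of rotations about the lab Y axis."""
    r = np.radians(np.asarray(deg, float))
    c, s = np.cos(r), np.sin(r)
    out = np.zeros(r.shape + (3, 3))
    out[..., 0, 0] = c
    out[..., 0, 2] = s
    out[..., 1, 1] = 1.0
    out[..., 2, 0] = -s
    out[..., 2, 2] = c
    return out


def _pose_series(
    phases: np.ndarray,
    curves: dict[str, FourierCurve],
    pitch_offset: float,
) -> dict[str, np.ndarray]:
    """Segment rotations (T,3,3) for the five-segment chain at given phases.

    The calcaneus carries the whole-foot sagittal pitch; Mid and Met hang off
    it through the free relative-angle curves; the shank and total foot are
    back-solved so that every tracked pair matches its configured truth.
    """
    pitch = curves["_foot_pitch"](phases) + pitch_offset
    R_cal = _rot_y(pitch)

    def rel(pair: str) -> np.ndarray:
        ang = np.column_stack([curves[f"{pair}_Angle{c}"](phases) for c in "XYZ"])
        return matrix_from_euler_xyz(ang)

    E_sha_cal = rel("Sha_Cal")
    E_sha_foot = rel("Sha_Foot")
    E_cal_mid = rel("Cal_Mid")
    E_mid_met = rel("Mid_Met")
    R_sha = R_cal @ np.swapaxes(E_sha_cal, -1, -2)
    return {
        "Sha": R_sha,
        "Foot": R_sha @ E_sha_foot,
        "Cal": R_cal,
        "Mid": R_cal @ E_cal_mid,
        "Met": R_cal @ E_cal_mid @ E_mid_met,
    }


def synthesize_markers(
    poses: dict[str, np.ndarray],
    time: np.ndarray,
    fs: float,
    marker_noise_sd: float,
    rng: np.random.Generator,
    geometry: dict[str, list[float]] | None = None,
    progression: np.ndarray | None = None,
    trial_id: str = "",
) -> MarkerTrajectorySet:
    """Rigid marker clouds riding on the segment pose series.

    Each marker position is (segment rotation @ reference offset) +
    progression + isotropic Gaussian noise; with zero noise the transform is
    exact, enabling round-trip testing of the kinematics module.
    """
    geo = geometry or REFERENCE_GEOMETRY
    T = len(time)
    if progression is None:
        progression = np.zeros((T, 3))
    positions: dict[str, np.ndarray] = {}
    for seg, names in SEGMENT_MARKERS.items():
        R = poses[seg]
        ref = np.array([geo[m] for m in names], float)      # (M, 3)
        if len(names) >= 3:
            spread = np.linalg.norm(
                np.cross(ref[1] - ref[0], ref[2] - ref[0])
            )
            if spread < 1e-6:
                raise DegenerateGeometryError(
                    f"reference markers of segment {seg!r} are collinear"
                )
        pts = np.einsum("tij,mj->tmi", R, ref) + progression[:, None, :]
        if marker_noise_sd > 0:
            pts = pts + rng.normal(0, marker_noise_sd, pts.shape)
        for k, m in enumerate(names):
            positions[m] = pts[:, k, :]
    return MarkerTrajectorySet(np.asarray(time, float), positions, fs, trial_id)


def synthesize_grf(
    event_times: list[tuple[float, float]],
    grf_fs: float,
    body_weight: float,
    duration: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Vertical GRF trace: double-bump support between each (HS, TO), zero elsewhere.

    The waveform is a constant plateau plus two raised-cosine bumps (loading
    and push-off), strictly positive on the open stance interval and zero
    outside, with a small vertical step at the boundaries so threshold
    crossings are recovered to within one force sample.
    """
    t = np.arange(0.0, duration, 1.0 / grf_fs)
    fz = np.zeros_like(t)
    for hs, to in event_times:
        s = (t - hs) / (to - hs)
        mask = (s > 0) & (s < 1)
        sv = s[mask]
        fz[mask] = body_weight * (
            0.15 + _raised_cos(sv, 0.28, 0.56) + 0.95 * _raised_cos(sv, 0.72, 0.56)
        )
    return t, fz


def _raised_cos(s: np.ndarray, center: float, width: float) -> np.ndarray:
    out = np.zeros_like(s)
    inside = np.abs(s - center) < width / 2
    out[inside] = 0.5 * (1 + np.cos(2 * np.pi * (s[inside] - center) / width))
    return out


# --------------------------------------------------------------------------
# Cohort assembly
# --------------------------------------------------------------------------


def simulate_cohort(config: CohortConfig, mode: str = "angles") -> list[GroundTruthTrial]:
    """Generate a full seeded cohort in the requested mode."""
    if mode == "angles":
        return _simulate_angle_cohort(config)
    if mode == "markers":
        return _simulate_marker_cohort(config)
    raise ConfigurationError(f"unknown cohort mode: {mode!r}")


def _simulate_angle_cohort(config: CohortConfig) -> list[GroundTruthTrial]:
    rng = np.random.default_rng(config.seed)
    trials = []
    sides = ("left",) if config.sides == "single" else ("left", "right")
    templates = generate_angle_templates(config, rng)
    speed_rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    for pid, label, truth in templates:
        mu, sd = config.walking_speed[label]
        for side in sides:
            observed = truth.copy()
            if side == "right":
                # small independent side-to-side wobble around the same truth
                for ch in observed.channel_names():
                    observed.set_channel(
                        ch, observed.get_channel(ch) + rng.normal(0, 0.3)
                    )
            if config.angle_noise_sd > 0:
                for ch in observed.channel_names():
                    observed.set_channel(
                        ch,
                        observed.get_channel(ch)
                        + rng.normal(0, config.angle_noise_sd, N_CYCLE_POINTS),
                    )
            speed = max(0.5, speed_rng.normal(mu, sd))
            T = config.stride_length_m / speed
            hs = 0.12
            trials.append(
                GroundTruthTrial(
                    participant_id=pid,
                    label=label,
                    side=side,
                    true_angle_curves=truth,
                    observed_angle_curves=observed,
                    event_times=(hs, hs + config.stance_fraction * T, hs + T),
                    walking_speed=speed,
                )
            )
    return trials


def _simulate_marker_cohort(config: CohortConfig) -> list[GroundTruthTrial]:
    config.validate_effect_map("markers")
    root = np.random.SeedSequence(config.seed)
    labels = ["autism"] * config.n_autism + ["control"] * config.n_control
    children = root.spawn(len(labels))
    sides = ("left",) if config.sides == "single" else ("left", "right")
    trials = []
    for i, (label, ss) in enumerate(zip(labels, children)):
        pid = f"{'A' if label == 'autism' else 'C'}{i + 1:02d}"
        rng = np.random.default_rng(ss)
        for side in sides:
            trials.append(_simulate_marker_trial(pid, label, side, config, rng))
    return trials


def _simulate_marker_trial(
    pid: str, label: str, side: str, config: CohortConfig, rng: np.random.Generator
) -> GroundTruthTrial:
    channels = [f"{p}_Angle{c}" for p in FREE_PAIRS for c in "XYZ"] + ["_foot_pitch"]
    curves = _participant_curves(channels, label, config, rng)

    # timing
    mu, sd = config.walking_speed[label]
    speed = max(0.5, rng.normal(mu, sd))
    T = config.stride_length_m / speed
    hs1 = 0.12
    to1 = hs1 + config.stance_fraction * T
    hs2 = hs1 + T
    duration = hs2 + config.stance_fraction * T + 0.1

    # F2G handling: effect offset and/or calibration via whole-foot pitch
    pitch_offset = 0.0
    if label == "autism" and "F2G" in config.effect_map:
        eff = config.effect_map["F2G"]
        pitch_offset += eff.get("offset", 0.0) if isinstance(eff, dict) else float(eff)
    if config.f2g_calibration:
        stance_phases = np.linspace(0.0, config.stance_fraction, 241)
        poses0 = _pose_series(stance_phases, curves, pitch_offset)
        f2g0 = _f2g_from_poses(poses0)
        target = rng.normal(*F2G_TARGETS[label])
        pitch_offset += target - float(np.max(f2g0))

    # marker time base and poses
    time = np.arange(0.0, duration, 1.0 / config.marker_fs)
    phases = ((time - hs1) / T) % 1.0
    poses = _pose_series(phases, curves, pitch_offset)
    progression = np.column_stack(
        [speed * 1000.0 * time, np.zeros_like(time), np.zeros_like(time)]
    )
    markers = synthesize_markers(
        poses, time, config.marker_fs, config.marker_noise_sd, rng,
        progression=progression, trial_id=f"{pid}_{side}",
    )

    # GRF
    mass = float(np.clip(rng.normal(*config.body_mass), 18.0, 90.0))
    bw = mass * GRAVITY
    grf_t, grf_z = synthesize_grf(
        [(hs1, to1), (hs2, hs2 + config.stance_fraction * T)],
        config.grf_fs, bw, duration,
    )

    # ground truth on the raw marker time base (for exact round-trip tests)
    raw_truth = _truth_curves(phases, curves, pitch_offset, time=time)
    # and on the normalized 101-point grid
    grid = np.linspace(0.0, 1.0, N_CYCLE_POINTS)
    norm_truth = _truth_curves(grid, curves, pitch_offset)
    norm_truth.normalized = True
    norm_truth.stance_end = config.stance_fraction * 100.0

    return GroundTruthTrial(
        participant_id=pid,
        label=label,
        side=side,
        true_angle_curves=norm_truth,
        true_raw_curves=raw_truth,
        marker_set=markers,
        grf_time=grf_t,
        grf_z=grf_z,
        event_times=(hs1, to1, hs2),
        walking_speed=speed,
        body_weight=bw,
    )


def _f2g_from_poses(poses: dict[str, np.ndarray]) -> np.ndarray:
    geo = REFERENCE_GEOMETRY
    pos = {
        m: np.einsum("tij,j->ti", poses["Met"], np.asarray(geo[m], float))
        for m in ("M1B", "M1H")
    }
    return planar_angle("F2G", pos)


def _truth_curves(
    phases: np.ndarray,
    curves: dict[str, FourierCurve],
    pitch_offset: float,
    time: np.ndarray | None = None,
) -> AngleCurveSet:
    """Noise-free angle curves at arbitrary phases, consistent with the chain."""
    euler = {
        pair: np.column_stack([curves[f"{pair}_Angle{c}"](phases) for c in "XYZ"])
        for pair in FREE_PAIRS
    }
    # Cal_Met is the composition of Cal_Mid and Mid_Met
    R = matrix_from_euler_xyz(euler["Cal_Mid"]) @ matrix_from_euler_xyz(
        euler["Mid_Met"]
    )
    euler["Cal_Met"] = euler_xyz_from_matrix(R)
    euler = {p: euler[p] for p in EULER_PAIRS}

    poses = _pose_series(phases, curves, pitch_offset)
    geo = REFERENCE_GEOMETRY
    planar = {}
    for pid_ in PLANAR_IDS:
        d = PLANAR_DEFS[pid_]
        needed = d.get("points", ()) or (d["line"] + d.get("line2", ()))
        pos = {}
        for m in needed:
            seg = next(s for s, ms in SEGMENT_MARKERS.items() if m in ms)
            pos[m] = np.einsum("tij,j->ti", poses[seg], np.asarray(geo[m], float))
        planar[pid_] = planar_angle(pid_, pos)
    return AngleCurveSet(euler, planar, time=time, normalized=False)


# --------------------------------------------------------------------------
# Cohort export
# --------------------------------------------------------------------------


def write_cohort(trials: list[GroundTruthTrial], out_dir: str | Path) -> None:
    """Write markers (TRC + wide CSV), GRF CSVs and a JSON ground-truth sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sidecar = []
    for tr in trials:
        stem = f"{tr.participant_id}_{tr.side}"
        if tr.marker_set is not None:
            write_trc(out / f"{stem}.trc", tr.marker_set)
            write_markers_csv(out / f"{stem}_markers.csv", tr.marker_set)
        if tr.grf_z is not None:
            write_grf_csv(out / f"{stem}_grf.csv", tr.grf_time, tr.grf_z)
        sidecar.append(
            {
                "participant_id": tr.participant_id,
                "label": tr.label,
                "side": tr.side,
                "event_times": tr.event_times,
                "walking_speed": tr.walking_speed,
                "body_weight": tr.body_weight,
            }
        )
    write_json(out / "cohort.json", sidecar)
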