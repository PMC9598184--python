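"""Gait events from vertical GRF, trial selection, cycle normalization, pooling.

Heel-strike (HS) and toe-off (TO) gate the stance phase: HS is an upward
crossing of a force threshold (default 20 N), TO a downward crossing, with a
10 ms debounce and linear interpolation of the crossing instant between force
samples.  One gait cycle runs HS to ipsilateral HS; curves are resampled onto
a 0..100 % grid of 101 points and stance_percent marks the TO instant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import N_CYCLE_POINTS, AngleCurveSet
from .errors import CoverageError, InputError, InsufficientDataError, NoContactError

DEFAULT_THRESHOLD_N = 20.0
DEBOUNCE_S = 0.010


@dataclass
class GaitEvents:
    """Heel-strike / toe-off times (seconds) and stance share of the cycle."""

    hs_times: list[float]
    to_times: list[float]
    stance_percent: float | None = None

    def __post_init__(self):
        hs = np.asarray(self.hs_times, float)
        if len(hs) and np.any(np.diff(hs) <= 0):
            raise InputError("hs_times must be strictly increasing")
        for to in self.to_times:
            i = np.searchsorted(hs, to)
            if i == 0 or (i < len(hs) and not hs[i - 1] < to < hs[i]):
                if i == 0 or to <= hs[i - 1]:
                    raise InputError(
                        f"toe-off at {to:.4f}s does not lie between heel strikes"
                    )


def detect_events(
    grf_z: np.ndarray,
    fs: float,
    threshold: float = DEFAULT_THRESHOLD_N,
    time: np.ndarray | None = None,
) -> GaitEvents:
    """Detect HS/TO from a uniformly sampled vertical GRF trace.

    Crossing times are linearly interpolated between the samples bracketing
    the threshold; crossings closer than 10 ms to the previous one are
    discarded as bounce.
    """
    if threshold <= 0:
        raise InputError("threshold must be positive")
    fz = np.asarray(grf_z, float)
    t = np.arange(len(fz)) / fs if time is None else np.asarray(time, float)
    above = fz >= threshold
    if not np.any(above):
        raise NoContactError(
            f"no samples above {threshold} N: no foot contact detected"
        )
    rises = np.flatnonzero(~above[:-1] & above[1:])
    falls = np.flatnonzero(above[:-1] & ~above[1:])

    def _cross(i: int) -> float:
        f0, f1 = fz[i], fz[i + 1]
        if f1 == f0:
            return t[i]
        return t[i] + (threshold - f0) / (f1 - f0) * (t[i + 1] - t[i])

    hs = _debounce([_cross(i) for i in rises])
    to = _debounce([_cross(i) for i in falls])
    stance = None
    if hs and to:
        first_to = next((x for x in to if x > hs[0]), None)
        if first_to is not None and len(hs) > 1:
            stance = 100.0 * (first_to - hs[0]) / (hs[1] - hs[0])
    return GaitEvents(hs, [x for x in to if x > (hs[0] if hs else -np.inf)], stance)


def _debounce(times: list[float], min_gap: float = DEBOUNCE_S) -> list[float]:
    out: list[float] = []
    for x in times:
        if not out or x - out[-1] >= min_gap:
            out.append(x)
    return out


def select_trial(speeds: list[float]) -> int:
    """Index of the cycle whose walking speed is closest to the mean speed.

    Ties resolve to the earliest cycle.
    """
    sp = np.asarray(speeds, float)
    sp = sp[np.isfinite(sp)] if len(sp) else sp
    if len(sp) == 0:
        raise InputError("no cycles with finite walking speed")
    mean = float(np.mean(np.asarray(speeds, float)[np.isfinite(speeds)]))
    dev = np.abs(np.asarray(speeds, float) - mean)
    dev[~np.isfinite(dev)] = np.inf
    return int(np.argmin(dev))


def normalize_cycle(
    values: np.ndarray,
    time: np.ndarray,
    hs_start: float,
    hs_next: float,
    to_time: float,
) -> tuple[np.ndarray, float]:
    """Resample one curve onto the 101-point 0..100 % gait-cycle grid.

    Linear interpolation; exact for curves that are piecewise linear between
    samples.  Returns (curve_101, stance_percent).
    """
    if not hs_start < to_time < hs_next:
        raise InputError("events must satisfy hs_start < to_time < hs_next")
    t = np.asarray(time, float)
    if hs_start < t[0] or hs_next > t[-1]:
        raise CoverageError(
            f"cycle [{hs_start:.4f}, {hs_next:.4f}]s not covered by curve span "
            f"[{t[0]:.4f}, {t[-1]:.4f}]s"
        )
    grid = hs_start + np.linspace(0.0, 1.0, N_CYCLE_POINTS) * (hs_next - hs_start)
    out = np.interp(grid, t, np.asarray(values, float))
    stance_percent = 100.0 * (to_time - hs_start) / (hs_next - hs_start)
    return out, stance_percent


def normalize_curve_set(
    curves: AngleCurveSet, hs_start: float, hs_next: float, to_time: float
) -> AngleCurveSet:
    """Normalize every channel of a raw-time AngleCurveSet to the cycle grid."""
    if curves.time is None:
        raise InputError("curve set has no raw time base")
    euler = {}
    stance = None
    for pair, arr in curves.euler.items():
        cols = []
        for j in range(3):
            col, stance = normalize_cycle(arr[:, j], curves.time, hs_start, hs_next, to_time)
            cols.append(col)
        euler[pair] = np.column_stack(cols)
    planar = {}
    for pid, arr in curves.planar.items():
        planar[pid], stance = normalize_cycle(arr, curves.time, hs_start, hs_next, to_time)
    return AngleCurveSet(euler, planar, normalized=True, stance_end=stance)


def symmetry_test_and_pool(
    left: pd.DataFrame,
    right: pd.DataFrame,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired t-test per feature between sides, then pool.

    ``left``/``right`` are feature tables indexed by participant with
    identical feature columns.  Features with p < alpha are flagged (and
    logged), but pooling proceeds regardless — mirroring the observed
    non-significance of limb asymmetry.  Pooled value = mean of the two
    sides per participant.  Identical sides give a zero-variance paired
    difference; by convention p = 1 (no evidence of asymmetry).

    Returns (pooled_table, report) where report has columns t, p, flagged.
    """
    common = left.index.intersection(right.index)
    if len(common) < 2:
        raise InsufficientDataError("need at least 2 paired participants")
    features = [c for c in left.columns if c in right.columns]
    lt, rt = left.loc[common, features], right.loc[common, features]
    rows = []
    for f in features:
        d = lt[f].to_numpy(float) - rt[f].to_numpy(float)
        if np.allclose(d, 0) or np.std(d, ddof=1) == 0:
            t_stat, p = 0.0, 1.0
        else:
            t_stat, p = stats.ttest_rel(lt[f], rt[f])
        rows.append({"feature": f, "t": float(t_stat), "p": float(p),
                     "flagged": bool(p < alpha)})
    report = pd.DataFrame(rows).set_index("feature")
    pooled = (lt + rt) / 2.0
    return pooled, report
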