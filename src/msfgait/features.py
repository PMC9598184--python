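"""Scalar features from normalized angle curves, and the cohort feature table.

Per Euler channel the default schema takes: value at heel-strike (HS, the
0 % sample), value at toe-off (TO, linearly interpolated at stance_end),
range of motion over the full cycle (ROM), max/min during stance and swing,
and the times (% gait cycle) of those extrema — 11 items per channel, hence
5 pairs x 3 components x 11 = 165 rotational features.  Per planar channel
the default takes max and min during stance (8 x 2 = 16).  The schema is
extensible (planar HS/ROM/extremum times) and the realized counts are
reported, since published feature counts for this kind of pipeline vary
with exactly these toggles.

Ties at equal extrema resolve to the earliest sample; stance covers grid
points 0..floor(stance_end), swing the remainder.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    COMPONENTS,
    EULER_PAIRS,
    MSF_GROUPS,
    PLANAR_IDS,
    SSF_GROUP,
    AngleCurveSet,
    write_json,
)
from .errors import ConfigurationError, InputError

logger = logging.getLogger(__name__)

EULER_ITEMS: tuple[str, ...] = (
    "HS", "TO", "ROM",
    "Max_ST", "Min_ST", "Max_SW", "Min_SW",
    "Time_Max_ST", "Time_Min_ST", "Time_Max_SW", "Time_Min_SW",
)
PLANAR_ITEMS: tuple[str, ...] = ("Max_ST", "Min_ST")
PLANAR_EXTRA_ITEMS: tuple[str, ...] = ("HS", "ROM", "Time_Max_ST", "Time_Min_ST")


@dataclass
class FeatureSchema:
    """Which scalar items to extract per channel kind."""

    euler_items: tuple[str, ...] = EULER_ITEMS
    planar_items: tuple[str, ...] = PLANAR_ITEMS
    pairs: tuple[str, ...] = EULER_PAIRS
    planar_ids: tuple[str, ...] = PLANAR_IDS

    def __post_init__(self):
        bad = set(self.euler_items) - set(EULER_ITEMS)
        if bad:
            raise ConfigurationError(f"unknown Euler feature items: {sorted(bad)}")
        bad = set(self.planar_items) - set(PLANAR_ITEMS) - set(PLANAR_EXTRA_ITEMS)
        if bad:
            raise ConfigurationError(f"unknown planar feature items: {sorted(bad)}")

    def feature_names(self) -> list[str]:
        names = [
            f"{pair}_Angle{c}_{item}"
            for pair in self.pairs
            for c in COMPONENTS
            for item in self.euler_items
        ]
        names += [
            f"{pid}_{item}" for pid in self.planar_ids for item in self.planar_items
        ]
        return names

    def group_map(self) -> dict[str, str]:
        """Feature -> feature-group (segment pair or planar id)."""
        gm = {}
        for name in self.feature_names():
            if "_Angle" in name:
                gm[name] = name.split("_Angle")[0]
            else:
                gm[name] = name.split("_")[0]
        return gm

    @property
    def n_rotational(self) -> int:
        return len(self.pairs) * 3 * len(self.euler_items)

    @property
    def n_planar(self) -> int:
        return len(self.planar_ids) * len(self.planar_items)


def _curve_items(
    curve: np.ndarray, stance_end: float, items: tuple[str, ...]
) -> dict[str, float]:
    n = len(curve)
    grid = np.linspace(0.0, 100.0, n)
    st_last = int(np.floor(stance_end * (n - 1) / 100.0))
    stance = curve[: st_last + 1]
    swing = curve[st_last + 1 :]
    out: dict[str, float] = {}
    for item in items:
        if item == "HS":
            out[item] = float(curve[0])
        elif item == "TO":
            out[item] = float(np.interp(stance_end, grid, curve))
        elif item == "ROM":
            out[item] = float(np.max(curve) - np.min(curve))
        elif item == "Max_ST":
            out[item] = float(np.max(stance))
        elif item == "Min_ST":
            out[item] = float(np.min(stance))
        elif item == "Max_SW":
            out[item] = float(np.max(swing))
        elif item == "Min_SW":
            out[item] = float(np.min(swing))
        elif item == "Time_Max_ST":
            out[item] = float(grid[int(np.argmax(stance))])
        elif item == "Time_Min_ST":
            out[item] = float(grid[int(np.argmin(stance))])
        elif item == "Time_Max_SW":
            out[item] = float(grid[st_last + 1 + int(np.argmax(swing))])
        elif item == "Time_Min_SW":
            out[item] = float(grid[st_last + 1 + int(np.argmin(swing))])
    return out


def extract_features(
    curves: AngleCurveSet, schema: FeatureSchema | None = None
) -> dict[str, float]:
    """One row of named scalar features from a normalized curve set."""
    schema = schema or FeatureSchema()
    if not curves.normalized or curves.stance_end is None:
        raise ConfigurationError(
            "feature extraction requires normalized curves with a stance boundary"
        )
    row: dict[str, float] = {}
    for pair in schema.pairs:
        for ci, c in enumerate(COMPONENTS):
            vals = _curve_items(
                curves.euler[pair][:, ci], curves.stance_end, schema.euler_items
            )
            for item, v in vals.items():
                row[f"{pair}_Angle{c}_{item}"] = v
    for pid in schema.planar_ids:
        vals = _curve_items(curves.planar[pid], curves.stance_end, schema.planar_items)
        for item, v in vals.items():
            row[f"{pid}_{item}"] = v
    return row


@dataclass
class FeatureTable:
    """Participants x features with labels and the feature-group map."""

    data: pd.DataFrame                   # numeric feature columns only
    labels: pd.Series                    # 'autism' | 'control', same index
    group_map: dict[str, str]
    sides: pd.Series | None = None

    def __post_init__(self):
        if self.data.columns.duplicated().any():
            raise ConfigurationError("duplicate feature names in table")
        unmapped = set(self.data.columns) - set(self.group_map)
        if unmapped:
            raise ConfigurationError(f"features without a group: {sorted(unmapped)}")
        if self.data.isna().any().any():
            raise ConfigurationError("feature table contains missing values")

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return len(self.data)

    def features_in_groups(self, groups: list[str]) -> list[str]:
        gs = set(groups)
        return [f for f in self.data.columns if self.group_map[f] in gs]

    def subset(self, features: list[str]) -> "FeatureTable":
        return FeatureTable(
            self.data[features].copy(),
            self.labels.copy(),
            {f: self.group_map[f] for f in features},
            None if self.sides is None else self.sides.copy(),
        )

    def grouping(self) -> dict[str, list[str]]:
        """Group name -> member features (partition of the active set)."""
        out: dict[str, list[str]] = {}
        for f in self.data.columns:
            out.setdefault(self.group_map[f], []).append(f)
        return out

    def to_csv(self, path: str | Path, group_map_path: str | Path | None = None):
        df = self.data.copy()
        df["label"] = self.labels
        df["participant"] = self.data.index
        if self.sides is not None:
            df["side"] = self.sides
        df.to_csv(path, index=False)
        if group_map_path is not None:
            write_json(group_map_path, self.group_map)

    @classmethod
    def from_csv(cls, path: str | Path, group_map: dict[str, str] | None = None):
        df = pd.read_csv(path)
        meta = [c for c in ("label", "participant", "side") if c in df.columns]
        feats = [c for c in df.columns if c not in meta]
        data = df[feats].copy()
        if "participant" in df.columns:
            data.index = df["participant"]
        labels = df["label"]
        labels.index = data.index
        sides = None
        if "side" in df.columns:
            sides = df["side"]
            sides.index = data.index
        if group_map is None:
            group_map = FeatureSchema().group_map()
            group_map = {f: group_map.get(f, _infer_group(f)) for f in feats}
        return cls(data, labels, group_map, sides)


def _infer_group(feature: str) -> str:
    if "_Angle" in feature:
        return feature.split("_Angle")[0]
    return feature.split("_")[0]


def build_feature_table(
    cohort: list[tuple[str, str, str, AngleCurveSet]],
    schema: FeatureSchema | None = None,
) -> FeatureTable:
    """Feature table for a cohort of (participant_id, label, side, curves).

    All participants must share the schema's channels; the realized feature
    counts per kind are logged.
    """
    schema = schema or FeatureSchema()
    rows, index, labels, sides = [], [], [], []
    for pid, label, side, curves in cohort:
        missing = [p for p in schema.pairs if p not in curves.euler] + [
            q for q in schema.planar_ids if q not in curves.planar
        ]
        if missing:
            raise ConfigurationError(
                f"participant {pid!r} lacks channels {missing}: inconsistent cohort"
            )
        rows.append(extract_features(curves, schema))
        index.append(pid)
        labels.append(label)
        sides.append(side)
    if not rows:
        raise InputError("empty cohort")
    data = pd.DataFrame(rows, index=index)
    logger.info(
        "feature table: %d samples, %d rotational + %d planar features",
        len(rows), schema.n_rotational, schema.n_planar,
    )
    return FeatureTable(
        data,
        pd.Series(labels, index=index, name="label"),
        schema.group_map(),
        pd.Series(sides, index=index, name="side"),
    )


def table_from_trials(trials, schema: FeatureSchema | None = None,
                      source: str = "observed") -> FeatureTable:
    """Feature table straight from synthetic trials.

    ``source`` chooses ``observed_angle_curves`` (with measurement noise) or
    ``true_angle_curves``.
    """
    cohort = []
    for tr in trials:
        curves = (
            tr.observed_angle_curves if source == "observed" else tr.true_angle_curves
        )
        if curves is None:
            curves = tr.true_angle_curves
        cohort.append((tr.participant_id, tr.label, tr.side, curves))
    return build_feature_table(cohort, schema)
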