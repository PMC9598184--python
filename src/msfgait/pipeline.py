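"""Configuration-driven end-to-end orchestration with seeding and provenance.

Stages: simulate -> (kinematics -> events -> normalize) -> features ->
classify (per feature-group combination x kernel) -> summed rank + mean ROC
-> Shapley explanation.  Every stage's artifacts land in the run directory
and a manifest records the configuration hash, seeds and stage log, so a
rerun with the same config and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import MSF_GROUPS, PLANAR_IDS, SSF_GROUP, write_json
from .errors import InputError
from .features import FeatureSchema, FeatureTable, table_from_trials, build_feature_table
from .gait_cycle import detect_events, normalize_curve_set, symmetry_test_and_pool
from .kinematics import compute_angles, default_recipes
from .model_eval import (
    ModelSpec,
    forward_select,
    loocv_evaluate,
    mean_roc,
    roc_and_auc,
    summed_rank,
    tune_hyperparameters,
    _encode,
    _fit_svm,
)
from .shapley import (
    group_attribution_global,
    group_attribution_local,
    rank_groups,
)
from .synthetic import CohortConfig, simulate_cohort, write_cohort

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# Combination enumeration
# --------------------------------------------------------------------------


def enumerate_combinations(
    groups: list[str],
    levels: list[int],
    include_msf_combined: bool = False,
    include_msf_ssf: bool = False,
) -> list[tuple[str, ...]]:
    """All feature-group subsets of the requested sizes, deterministic order.

    Optionally appends the four-group MSF-combined set and the all-combined
    MSF + SSF set.
    """
    if not groups:
        raise InputError("no feature groups given")
    for lv in levels:
        if lv < 1 or lv > len(groups):
            raise InputError(f"level {lv} out of range for {len(groups)} groups")
    out: list[tuple[str, ...]] = []
    for lv in sorted(set(levels)):
        out.extend(itertools.combinations(groups, lv))
    if include_msf_combined:
        out.append(tuple(MSF_GROUPS))
    if include_msf_ssf:
        out.append(tuple(MSF_GROUPS) + (SSF_GROUP,))
    return out


def combo_name(combo: tuple[str, ...]) -> str:
    if set(combo) == set(MSF_GROUPS):
        return "MSF (combined)"
    if set(combo) == set(MSF_GROUPS) | {SSF_GROUP}:
        return "MSF + SSF"
    if set(combo) == set(PLANAR_IDS):
        return "Planar_All"
    return " + ".join(g.replace("_", "-") for g in combo)


# --------------------------------------------------------------------------
# Pipeline configuration
# --------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    cohort_mode: str = "angles"            # 'angles' | 'markers'
    write_raw_cohort: bool = False
    kernels: tuple[str, ...] = ("linear", "rbf")
    msf_levels: tuple[int, ...] = (1, 2)
    include_higher_levels: bool = True      # level 3-4 + MSF-combined + MSF+SSF
    include_planar: bool = True
    mode: str = "paper"                    # selection on full table vs nested
    select_features: bool = False          # wrapper forward selection per model
    tune: bool = False                     # hyper-parameter grid per model
    svm_C: float = 1.0
    svm_gamma: float | str = "scale"
    explain: bool = True
    shapley_draws: int = 16
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("paper", "nested"):
            raise InputError("mode must be 'paper' or 'nested'")
        if self.cohort_mode not in ("angles", "markers"):
            raise InputError("cohort_mode must be 'angles' or 'markers'")
        for k in self.kernels:
            if k not in ("linear", "rbf"):
                raise InputError(f"unsupported kernel: {k!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cohort = CohortConfig(**raw.pop("cohort", {}))
        for key in ("kernels", "msf_levels"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(cohort=cohort, **raw)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# --------------------------------------------------------------------------
# Stage helpers
# --------------------------------------------------------------------------


def curves_from_markers(trial, recipes=None):
    """Kinematics + events + normalization for one marker-mode trial."""
    recipes = recipes or default_recipes()
    raw = compute_angles(trial.marker_set, recipes, prefiltered=True)
    grf_fs = 1.0 / float(np.median(np.diff(trial.grf_time)))
    events = detect_events(trial.grf_z, grf_fs, time=trial.grf_time)
    if len(events.hs_times) < 2:
        raise InputError(
            f"trial {trial.participant_id}: need two heel strikes, "
            f"got {len(events.hs_times)}"
        )
    hs1, hs2 = events.hs_times[0], events.hs_times[1]
    to = next(t for t in events.to_times if hs1 < t < hs2)
    return normalize_curve_set(raw, hs1, hs2, to)


def cohort_feature_table(
    config: PipelineConfig, schema: FeatureSchema | None = None
) -> FeatureTable:
    """simulate -> angles -> events -> features, per the configured mode."""
    trials = simulate_cohort(config.cohort, mode=config.cohort_mode)
    if config.cohort_mode == "angles":
        table = table_from_trials(trials, schema, source="observed")
    else:
        recipes = default_recipes()
        cohort = [
            (tr.participant_id, tr.label, tr.side, curves_from_markers(tr, recipes))
            for tr in trials
        ]
        table = build_feature_table(cohort, schema)
    if config.cohort.sides == "both":
        left = table.data[table.sides == "left"]
        right = table.data[table.sides == "right"]
        pooled, report = symmetry_test_and_pool(left, right)
        flagged = report.index[report["flagged"]].tolist()
        if flagged:
            logger.warning("asymmetric features pooled anyway: %s", flagged)
        labels = table.labels[table.sides == "left"]
        table = FeatureTable(pooled, labels.loc[pooled.index], table.group_map)
    return table


def evaluate_combination(
    table: FeatureTable,
    combo: tuple[str, ...],
    kernel: str,
    config: PipelineConfig,
) -> dict:
    """One model: optional selection/tuning, then LOOCV metrics + scores."""
    feats = table.features_in_groups(list(combo))
    if not feats:
        raise InputError(f"no features for groups {combo}")
    spec = ModelSpec(
        kernel=kernel, C=config.svm_C, gamma=config.svm_gamma,
        features=feats, name=f"{combo_name(combo)} [{kernel}]",
    )
    trajectory: list[float] = []
    if config.tune:
        tuned = tune_hyperparameters(table, kernel, feats, seed=config.seed)
        spec = dataclasses.replace(spec, C=tuned.C, gamma=tuned.gamma)
    if config.select_features and config.mode == "paper":
        selected, trajectory = forward_select(
            table, feats, spec, seed=config.seed
        )
        spec = dataclasses.replace(spec, features=selected)
    metrics, scores, counts = loocv_evaluate(table, spec)
    return {
        "name": spec.name,
        "combo": combo,
        "kernel": kernel,
        "spec": spec,
        "metrics": metrics,
        "scores": scores,
        "counts": counts,
        "trajectory": trajectory,
    }


# --------------------------------------------------------------------------
# Full run
# --------------------------------------------------------------------------


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute every enabled stage; returns the run directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": [],
    }
    t0 = _time.perf_counter()

    def stage_done(name: str):
        manifest["stages"].append(
            {"stage": name, "elapsed_s": round(_time.perf_counter() - t0, 3)}
        )

    if config.write_raw_cohort:
        trials = simulate_cohort(config.cohort, mode=config.cohort_mode)
        write_cohort(trials, out / "cohort")
        stage_done("simulate")

    schema = FeatureSchema()
    table = cohort_feature_table(config, schema)
    table.to_csv(out / "features.csv", out / "group_map.json")
    manifest["n_samples"] = table.n_samples
    manifest["n_features"] = len(table.feature_names)
    stage_done("features")

    results: dict[str, dict] = {}
    categories: dict[str, list[str]] = {}

    def run_category(name: str, combos: list[tuple[str, ...]]):
        names = []
        for combo in combos:
            for kernel in config.kernels:
                res = evaluate_combination(table, combo, kernel, config)
                results[res["name"]] = res
                names.append(res["name"])
        categories[name] = names

    msf_and_ssf = list(MSF_GROUPS) + [SSF_GROUP]
    run_category(
        "level_1_2",
        enumerate_combinations(msf_and_ssf, list(config.msf_levels)),
    )
    if config.include_higher_levels:
        run_category(
            "level_3_4_5",
            enumerate_combinations(
                msf_and_ssf, [3, 4],
                include_msf_combined=False, include_msf_ssf=True,
            ),
        )
    if config.include_planar:
        planar_combos = [(p,) for p in PLANAR_IDS] + [tuple(PLANAR_IDS)]
        run_category("planar", planar_combos)
    stage_done("classify")

    y = _encode(table.labels)
    summary = {}
    for cat, names in categories.items():
        ranked = summed_rank({n: results[n]["metrics"] for n in names})
        ranked.to_csv(out / f"rank_{cat}.csv")
        rocs = [roc_and_auc(results[n]["scores"], y)[:2] for n in names]
        grid, tpr, auc = mean_roc(rocs)
        pd.DataFrame({"fpr": grid, "mean_tpr": tpr}).to_csv(
            out / f"mean_roc_{cat}.csv", index=False
        )
        summary[cat] = {
            "best_model": ranked.index[0],
            "best_accuracy": float(ranked["accuracy"].iloc[0]),
            "mean_roc_auc": auc,
        }
    write_json(out / "model_results.json", {
        n: {
            "kernel": r["kernel"],
            "combo": list(r["combo"]),
            "C": r["spec"].C,
            "gamma": r["spec"].gamma,
            "n_features": len(r["spec"].features),
            "metrics": r["metrics"].as_dict(),
            "score_trajectory": r["trajectory"],
            "confusion": dataclasses.asdict(r["counts"]),
        }
        for n, r in results.items()
    })
    manifest["summary"] = summary
    stage_done("rank")

    if config.explain:
        best_cat = categories.get("level_3_4_5") or next(iter(categories.values()))
        best_name = summed_rank(
            {n: results[n]["metrics"] for n in best_cat}
        ).index[0]
        spec = results[best_name]["spec"]
        X = table.data[spec.features].to_numpy(float)
        scaler, clf = _fit_svm(X, y, spec)
        predict = lambda M: clf.decision_function(scaler.transform(M))
        grouping_names = table.subset(spec.features).grouping()
        col_idx = {f: i for i, f in enumerate(spec.features)}
        grouping = {
            g: [col_idx[f] for f in fs] for g, fs in grouping_names.items()
        }
        rng = np.random.default_rng(config.seed + 1)
        glob = group_attribution_global(predict, X, y, grouping, rng,
                                        n_draws=config.shapley_draws)
        rank_groups(glob).to_csv(out / "sage_groups.csv", index=False)
        autism_idx = int(np.flatnonzero(y == 1)[0])
        loc = group_attribution_local(
            predict, X[autism_idx], str(table.data.index[autism_idx]),
            grouping, X, rng, n_draws=config.shapley_draws * 4,
        )
        rank_groups(loc).to_csv(out / "shap_waterfall.csv", index=False)
        manifest["explained_model"] = best_name
        stage_done("explain")

    write_json(out / "manifest.json", manifest)
    return out
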