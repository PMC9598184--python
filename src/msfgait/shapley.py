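"""Local and global Shapley attributions over features and feature groups.

Players are features or whole feature groups.  The coalition value function
uses *marginal* feature removal: features outside the coalition are replaced
by draws from a background set (default: the training table) and the model
output is averaged over draws.

Local scope attributes the model's decision value for one sample (positive
values push toward 'autism', negative toward 'control').  Global scope is a
loss decomposition: v(S) = loss with no features known minus loss with the
coalition's features known, averaged over the whole table — the value of the
full set is the model's total explainable loss reduction.

Exact Shapley values enumerate all 2^p coalitions (p <= 15); beyond that a
seeded permutation-sampling estimator with standard errors is provided.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import factorial

import numpy as np
import pandas as pd

from .errors import InputError

EXACT_PLAYER_LIMIT = 15


@dataclass
class Attribution:
    """Per-player Shapley values with the empty-coalition base value."""

    players: list[str]
    values: np.ndarray
    base_value: float
    scope: str                              # 'local:<sample_id>' or 'global'
    standard_errors: np.ndarray | None = None

    def efficiency_gap(self, grand_value: float) -> float:
        """|sum(values) + base - v(all players)| — zero for exact attribution."""
        return float(abs(np.sum(self.values) + self.base_value - grand_value))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"player": self.players, "value": self.values})
        if self.standard_errors is not None:
            df["se"] = self.standard_errors
        return df


# --------------------------------------------------------------------------
# Coalition value functions
# --------------------------------------------------------------------------


def _mixed_matrix(
    x: np.ndarray, background: np.ndarray, keep: np.ndarray
) -> np.ndarray:
    """Background rows with the kept coordinates overwritten by ``x``."""
    out = background.copy()
    out[:, keep] = x[keep]
    return out


def coalition_value_local(
    predict, x: np.ndarray, coalition: list[int],
    background: np.ndarray, rng: np.random.Generator, n_draws: int = 64,
) -> float:
    """Expected model output for ``x`` with features outside S marginalized.

    ``predict`` maps an (n, d) matrix to (n,) outputs (e.g. an SVM decision
    function).  S = all features returns exactly the model output for x;
    S = empty set the background-mean prediction.
    """
    background = np.atleast_2d(np.asarray(background, float))
    if background.shape[0] == 0:
        raise InputError("background set must be non-empty")
    d = background.shape[1]
    keep = np.zeros(d, bool)
    keep[list(coalition)] = True
    if keep.all():
        return float(predict(np.atleast_2d(x))[0])
    draws = background[rng.integers(0, background.shape[0], size=n_draws)]
    return float(np.mean(predict(_mixed_matrix(np.asarray(x, float), draws, keep))))


def coalition_value_global(
    predict, X: np.ndarray, y: np.ndarray, coalition: list[int],
    rng: np.random.Generator, n_draws: int = 16, loss: str = "cross_entropy",
) -> float:
    """Expected loss reduction from knowing the coalition's features.

    v(S) = L(marginal prediction) - L(prediction with S present, rest
    marginalized), averaged over the table; v(empty) = 0 by construction.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, d = X.shape
    keep = np.zeros(d, bool)
    keep[list(coalition)] = True

    base_pred = np.full(n, float(np.mean(predict(X))))
    if keep.all():
        pred = predict(X)
    elif not keep.any():
        pred = base_pred
    else:
        idx = rng.integers(0, n, size=(n, n_draws))
        preds = np.empty((n, n_draws))
        # batch all mixed rows into one model call
        stacked = np.empty((n * n_draws, d))
        for i in range(n):
            mixed = X[idx[i]]
            mixed[:, keep] = X[i, keep]
            stacked[i * n_draws : (i + 1) * n_draws] = mixed
        preds = predict(stacked).reshape(n, n_draws)
        pred = preds.mean(axis=1)
    return float(_loss(base_pred, y, loss) - _loss(pred, y, loss))


def _loss(scores: np.ndarray, y: np.ndarray, kind: str) -> float:
    if kind == "cross_entropy":
        p = 1.0 / (1.0 + np.exp(-scores))
        p = np.clip(p, 1e-9, 1 - 1e-9)
        return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))
    if kind == "squared":
        return float(np.mean((scores - (2 * y - 1)) ** 2))
    raise InputError(f"unknown loss: {kind!r}")


# --------------------------------------------------------------------------
# Shapley estimators
# --------------------------------------------------------------------------


def exact_shapley(players: list[str], value_fn) -> Attribution:
    """Exact Shapley values by full 2^p coalition enumeration.

    ``value_fn`` maps a tuple of player names to the coalition value.
    Efficiency holds exactly up to the value function's own sampling noise.
    """
    p = len(players)
    if p > EXACT_PLAYER_LIMIT:
        raise InputError(
            f"{p} players exceed the exact-enumeration limit "
            f"({EXACT_PLAYER_LIMIT}); use sampled_shapley"
        )
    cache: dict[frozenset, float] = {}

    def v(coal: frozenset) -> float:
        if coal not in cache:
            cache[coal] = float(value_fn(tuple(sorted(coal))))
        return cache[coal]

    base = v(frozenset())
    phi = np.zeros(p)
    others = list(range(p))
    fact = [factorial(k) for k in range(p + 1)]
    for i in range(p):
        rest = [j for j in others if j != i]
        for size in range(p):
            w = fact[size] * fact[p - size - 1] / fact[p]
            for combo in itertools.combinations(rest, size):
                S = frozenset(players[j] for j in combo)
                phi[i] += w * (v(S | {players[i]}) - v(S))
    return Attribution(list(players), phi, base, scope="global")


def sampled_shapley(
    players: list[str], value_fn, n_permutations: int,
    rng: np.random.Generator,
) -> Attribution:
    """Permutation-sampling Shapley estimator with standard errors.

    Unbiased for any n_permutations >= 1; converges to the exact values as
    permutations grow.  Coalition values are cached across permutations.
    """
    if n_permutations < 1:
        raise InputError("need at least one permutation")
    p = len(players)
    cache: dict[frozenset, float] = {}

    def v(coal: frozenset) -> float:
        if coal not in cache:
            cache[coal] = float(value_fn(tuple(sorted(coal))))
        return cache[coal]

    base = v(frozenset())
    contribs = np.zeros((n_permutations, p))
    for m in range(n_permutations):
        order = rng.permutation(p)
        running: frozenset = frozenset()
        prev = base
        for j in order:
            nxt = running | {players[j]}
            val = v(nxt)
            contribs[m, j] = val - prev
            running, prev = nxt, val
    phi = contribs.mean(axis=0)
    se = (
        contribs.std(axis=0, ddof=1) / np.sqrt(n_permutations)
        if n_permutations > 1
        else np.full(p, np.nan)
    )
    return Attribution(list(players), phi, base, scope="global", standard_errors=se)


# --------------------------------------------------------------------------
# Feature-group attribution for fitted models
# --------------------------------------------------------------------------


def group_attribution_local(
    predict, x: np.ndarray, sample_id: str,
    grouping: dict[str, list[int]], background: np.ndarray,
    rng: np.random.Generator, n_draws: int = 64,
) -> Attribution:
    """Exact group-level Shapley attribution of one prediction."""
    names = list(grouping)

    def value_fn(coal: tuple[str, ...]) -> float:
        idx = [i for g in coal for i in grouping[g]]
        return coalition_value_local(predict, x, idx, background, rng, n_draws)

    att = exact_shapley(names, value_fn)
    att.scope = f"local:{sample_id}"
    return att


def group_attribution_global(
    predict, X: np.ndarray, y: np.ndarray,
    grouping: dict[str, list[int]],
    rng: np.random.Generator, n_draws: int = 16, loss: str = "cross_entropy",
) -> Attribution:
    """Exact group-level loss-decomposition attribution over a dataset."""
    names = list(grouping)

    def value_fn(coal: tuple[str, ...]) -> float:
        idx = [i for g in coal for i in grouping[g]]
        return coalition_value_global(predict, X, y, idx, rng, n_draws, loss)

    return exact_shapley(names, value_fn)


def rank_groups(attribution: Attribution) -> pd.DataFrame:
    """Ordered group report: bar-plot data (global) or waterfall rows (local).

    Global scope sorts by value descending; local scope by |value|.  Local
    rows carry the signed direction (positive -> autism, negative ->
    control) and sum to (prediction - base value).
    """
    df = attribution.to_frame()
    if attribution.scope.startswith("local"):
        df["direction"] = np.where(df["value"] >= 0, "autism", "control")
        df = df.reindex(df["value"].abs().sort_values(ascending=False).index)
    else:
        df = df.sort_values("value", ascending=False)
    df = df.reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df
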