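"""Stochastic gradient-boosted regression trees for presence/background data.

This is a from-scratch implementation of binomial gradient boosting in the
tradition of ecological species-distribution workflows: small regression
trees (the *tree complexity* ``tc`` is the number of splits per tree, which
bounds the interaction order) are fitted stagewise to the Bernoulli gradient
on random bags of the training rows, with Newton terminal-node updates and a
small learning rate.  The module also provides the standard diagnostics of
that workflow: ten-fold cross-validated selection of the number of trees,
predictive deviance and AUC, per-predictor relative influence, partial
dependence, pairwise interaction strength, and a bootstrap ensemble with
withheld-data performance per member.

Flow and channel-size predictors that span orders of magnitude (``MeanFlow``,
``WidthQ50``, ``segSinuosity``) are log-transformed as part of the model
schema, so the same transform is applied at prediction time automatically.
"""

from __future__ import annotations

import heapq
import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import rankdata

from .errors import InvalidArgumentError, SchemaError, UndefinedMetricError
from .sampling import TrainingSet

__all__ = [
    "FeatureSchema",
    "RegressionTree",
    "BRTFit",
    "CVTrace",
    "EnsembleMember",
    "BRTEnsemble",
    "fit_tree",
    "fit_brt",
    "cv_optimal_ntrees",
    "predict_rlo",
    "bernoulli_deviance",
    "deviance_explained_pct",
    "auc",
    "relative_influence",
    "ensemble_relative_influence",
    "partial_dependence",
    "interaction_strength",
    "fit_ensemble",
    "DEFAULT_LOG_FEATURES",
]

#: Predictors log-transformed before fitting (part of the model schema).
DEFAULT_LOG_FEATURES: tuple[str, ...] = ("MeanFlow", "WidthQ50", "segSinuosity")

_EPS = 1e-12
_LOG_FLOOR = 1e-6  # floor before log-transforming non-negative predictors
_MAX_LEAF_VALUE = 1e3


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered feature names plus the subset that is log-transformed."""

    names: tuple[str, ...]
    log_features: tuple[str, ...] = ()

    @classmethod
    def for_columns(cls, columns) -> "FeatureSchema":
        names = tuple(columns)
        return cls(names=names, log_features=tuple(c for c in DEFAULT_LOG_FEATURES if c in names))

    def transform(self, df: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.names if c not in df.columns]
        if missing:
            raise SchemaError(f"missing predictor column(s): {', '.join(missing)}")
        M = df[list(self.names)].to_numpy(dtype=float, copy=True)
        return self.transform_matrix(M)

    def transform_matrix(self, M: np.ndarray) -> np.ndarray:
        """Apply the log transforms to a raw matrix already in schema order."""
        M = np.array(M, dtype=float, copy=True)
        for j, name in enumerate(self.names):
            if name in self.log_features:
                M[:, j] = np.log(np.maximum(M[:, j], _LOG_FLOOR))
        return M


@dataclass
class RegressionTree:
    """A small regression tree stored as flat node arrays.

    ``feature[k] == -1`` marks a terminal node whose fitted value (on the
    link scale, before the learning rate) is ``value[k]``.  ``gains`` holds
    the squared-error reduction accumulated per predictor, used for relative
    influence.
    """

    feature: np.ndarray
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    value: np.ndarray
    gains: np.ndarray

    @property
    def n_leaves(self) -> int:
        return int((self.feature < 0).sum())

    @property
    def n_splits(self) -> int:
        return int((self.feature >= 0).sum())

    def predict(self, X: np.ndarray) -> np.ndarray:
        node = np.zeros(len(X), dtype=np.int64)
        while True:
            f = self.feature[node]
            active = np.flatnonzero(f >= 0)
            if len(active) == 0:
                break
            nd = node[active]
            go_left = X[active, self.feature[nd]] <= self.threshold[nd]
            node[active] = np.where(go_left, self.left[nd], self.right[nd])
        return self.value[node]


def _newton_value(z_sum: float, w_sum: float) -> float:
    v = z_sum / max(w_sum, _EPS)
    return float(np.clip(v, -_MAX_LEAF_VALUE, _MAX_LEAF_VALUE))


def _best_split(
    X: np.ndarray,
    z: np.ndarray,
    member: np.ndarray,
    sorted_idx: np.ndarray,
    min_node: int,
):
    """Best (gain, feature, threshold) for the rows flagged in ``member``.

    The split criterion is the reduction in (unweighted) squared error of the
    working response.  Ties are broken by lowest feature index, then lowest
    threshold, so fitting is fully deterministic.
    """
    nm = int(member.sum())
    if nm < 2 * min_node:
        return None
    S = float(z[member].sum())
    base = S * S / nm
    best_gain = 1e-12
    best = None
    n_left = np.arange(1, nm)
    for j in range(X.shape[1]):
        idx = sorted_idx[:, j]
        idx = idx[member[idx]]
        xs = X[idx, j]
        valid = (xs[:-1] != xs[1:]) & (n_left >= min_node) & (nm - n_left >= min_node)
        if not valid.any():
            continue
        cs = np.cumsum(z[idx])[:-1]
        with np.errstate(invalid="ignore"):
            gains = cs**2 / n_left + (S - cs) ** 2 / (nm - n_left) - base
        gains[~valid] = -np.inf
        k = int(np.argmax(gains))
        if gains[k] > best_gain:
            best_gain = float(gains[k])
            best = (best_gain, j, float(0.5 * (xs[k] + xs[k + 1])))
    return best


def fit_tree(
    X: np.ndarray,
    working_response: np.ndarray,
    weights: np.ndarray,
    tc: int,
    min_node: int = 10,
    member: np.ndarray | None = None,
    sorted_idx: np.ndarray | None = None,
) -> RegressionTree:
    """Grow one regression tree, best-first, up to ``tc`` splits.

    At every step the leaf whose best admissible split yields the largest
    squared-error reduction of the working response is split; terminal-node
    values are the Newton step for Bernoulli deviance,
    ``sum(working_response) / sum(weights)`` over the leaf.  A constant
    working response (or no admissible split) yields a single-leaf tree.
    """
    X = np.asarray(X, dtype=float)
    z = np.asarray(working_response, dtype=float)
    w = np.asarray(weights, dtype=float)
    if member is None:
        member = np.ones(len(X), dtype=bool)
    if sorted_idx is None:
        sorted_idx = np.argsort(X, axis=0, kind="stable")

    feature = [-1]
    threshold = [math.nan]
    left = [-1]
    right = [-1]
    value = [_newton_value(z[member].sum(), w[member].sum())]
    gains = np.zeros(X.shape[1])

    heap: list = []
    counter = 0
    cand = _best_split(X, z, member, sorted_idx, min_node)
    if cand is not None:
        heapq.heappush(heap, (-cand[0], counter, 0, member, cand))
        counter += 1

    n_splits = 0
    while heap and n_splits < tc:
        _, _, node_id, node_member, (gain, j, thr) = heapq.heappop(heap)
        left_member = node_member & (X[:, j] <= thr)
        right_member = node_member & ~(X[:, j] <= thr)
        kl = len(feature)
        kr = kl + 1
        for m in (left_member, right_member):
            feature.append(-1)
            threshold.append(math.nan)
            left.append(-1)
            right.append(-1)
            value.append(_newton_value(z[m].sum(), w[m].sum()))
        feature[node_id] = j
        threshold[node_id] = thr
        left[node_id] = kl
        right[node_id] = kr
        gains[j] += gain
        n_splits += 1
        for child_id, m in ((kl, left_member), (kr, right_member)):
            c = _best_split(X, z, m, sorted_idx, min_node)
            if c is not None:
                heapq.heappush(heap, (-c[0], counter, child_id, m, c))
                counter += 1

    return RegressionTree(
        feature=np.array(feature, dtype=np.int64),
        threshold=np.array(threshold, dtype=float),
        left=np.array(left, dtype=np.int64),
        right=np.array(right, dtype=np.int64),
        value=np.array(value, dtype=float),
        gains=gains,
    )


class _Booster:
    """Incremental boosting state (supports staged growth for CV)."""

    def __init__(self, X, y, tc, lr, bag_fraction, min_node, rng):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=float)
        if not (0 < bag_fraction <= 1):
            raise InvalidArgumentError(f"bag_fraction must be in (0, 1], got {bag_fraction}")
        if lr <= 0:
            raise InvalidArgumentError(f"learning rate must be > 0, got {lr}")
        classes = np.unique(self.y)
        if len(classes) < 2:
            raise InvalidArgumentError("response contains a single class")
        self.tc = int(tc)
        self.lr = float(lr)
        self.bag_fraction = float(bag_fraction)
        self.min_node = int(min_node)
        self.rng = rng
        self.sorted_idx = np.argsort(self.X, axis=0, kind="stable")
        ybar = float(np.clip(self.y.mean(), _EPS, 1 - _EPS))
        self.intercept = float(logit(ybar))
        self.F = np.full(len(self.y), self.intercept)
        self.trees: list[RegressionTree] = []
        self._evals: list[tuple[np.ndarray, np.ndarray]] = []

    def register_eval(self, Xe: np.ndarray) -> int:
        Xe = np.asarray(Xe, dtype=float)
        self._evals.append((Xe, np.full(len(Xe), self.intercept)))
        return len(self._evals) - 1

    def eval_probs(self, k: int) -> np.ndarray:
        return expit(self._evals[k][1])

    def grow(self, n_trees: int) -> None:
        n = len(self.y)
        n_bag = max(2 * self.min_node, math.ceil(self.bag_fraction * n))
        n_bag = min(n_bag, n)
        for _ in range(n_trees):
            member = np.zeros(n, dtype=bool)
            member[self.rng.permutation(n)[:n_bag]] = True
            p = expit(self.F)
            z = self.y - p
            w = p * (1.0 - p)
            tree = fit_tree(
                self.X, z, w, self.tc, self.min_node,
                member=member, sorted_idx=self.sorted_idx,
            )
            self.F += self.lr * tree.predict(self.X)
            for Xe, Fe in self._evals:
                Fe += self.lr * tree.predict(Xe)
            self.trees.append(tree)


class BRTFit:
    """A fitted boosted-tree model: intercept plus an ordered list of trees.

    Predictions are ``expit(intercept + lr * sum of tree contributions)`` and
    therefore always lie strictly inside (0, 1).
    """

    def __init__(self, schema, intercept, trees, lr, tc, bag_fraction, min_node,
                 seed, train_X=None, train_y=None):
        self.schema = schema
        self.intercept = float(intercept)
        self.trees = list(trees)
        self.lr = float(lr)
        self.tc = int(tc)
        self.bag_fraction = float(bag_fraction)
        self.min_node = int(min_node)
        self.seed = seed
        self.train_X = train_X  # raw (untransformed) training predictors
        self.train_y = train_y

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def predict_link_matrix(self, M: np.ndarray) -> np.ndarray:
        F = np.full(len(M), self.intercept)
        for tree in self.trees:
            F += self.lr * tree.predict(M)
        return F

    def predict_link(self, X: pd.DataFrame) -> pd.Series:
        M = self.schema.transform(X)
        return pd.Series(self.predict_link_matrix(M), index=X.index)

    def predict(self, X: pd.DataFrame) -> pd.Series:
        return self.predict_link(X).map(expit).astype(float)

    # -- serialisation (self-contained text format) ------------------------
    def to_dict(self) -> dict:
        return {
            "schema": {"names": list(self.schema.names),
                       "log_features": list(self.schema.log_features)},
            "intercept": self.intercept,
            "lr": self.lr,
            "tc": self.tc,
            "bag_fraction": self.bag_fraction,
            "min_node": self.min_node,
            "seed": self.seed,
            "trees": [
                {
                    "feature": t.feature.tolist(),
                    "threshold": t.threshold.tolist(),
                    "left": t.left.tolist(),
                    "right": t.right.tolist(),
                    "value": t.value.tolist(),
                    "gains": t.gains.tolist(),
                }
                for t in self.trees
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BRTFit":
        schema = FeatureSchema(
            names=tuple(d["schema"]["names"]),
            log_features=tuple(d["schema"]["log_features"]),
        )
        trees = [
            RegressionTree(
                feature=np.array(t["feature"], dtype=np.int64),
                threshold=np.array(t["threshold"], dtype=float),
                left=np.array(t["left"], dtype=np.int64),
                right=np.array(t["right"], dtype=np.int64),
                value=np.array(t["value"], dtype=float),
                gains=np.array(t["gains"], dtype=float),
            )
            for t in d["trees"]
        ]
        return cls(schema, d["intercept"], trees, d["lr"], d["tc"],
                   d["bag_fraction"], d["min_node"], d["seed"])


def _as_xy(train: TrainingSet, schema: FeatureSchema | None):
    schema = schema or FeatureSchema.for_columns(train.X.columns)
    return schema, schema.transform(train.X), np.asarray(train.response, dtype=float)


def fit_brt(
    train: TrainingSet,
    tc: int = 5,
    lr: float = 0.01,
    bag_fraction: float = 0.75,
    n_trees: int = 1000,
    min_node: int = 10,
    seed: int = 0,
    schema: FeatureSchema | None = None,
) -> BRTFit:
    """Fit a stagewise additive logistic model of ``n_trees`` boosted trees."""
    schema, X, y = _as_xy(train, schema)
    rng = np.random.default_rng(seed)
    booster = _Booster(X, y, tc, lr, bag_fraction, min_node, rng)
    booster.grow(int(n_trees))
    return BRTFit(
        schema=schema, intercept=booster.intercept, trees=booster.trees,
        lr=lr, tc=tc, bag_fraction=bag_fraction, min_node=min_node, seed=seed,
        train_X=train.X.copy(), train_y=y.copy(),
    )


@dataclass
class CVTrace:
    """Cross-validation trace over a grid of tree counts."""

    grid: np.ndarray
    mean_deviance: np.ndarray
    fold_deviance: np.ndarray  # (folds, grid)
    fold_auc: np.ndarray  # (folds, grid)
    optimal_ntrees: int
    cv_auc: float
    cv_deviance_explained_pct: float


def _stratified_folds(y: np.ndarray, folds: int, rng) -> np.ndarray:
    assignment = np.empty(len(y), dtype=np.int64)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if len(idx) < folds:
            raise InvalidArgumentError(
                f"class {cls:g} has {len(idx)} rows, fewer than {folds} folds; "
                "stratification impossible"
            )
        perm = rng.permutation(idx)
        assignment[perm] = np.arange(len(perm)) % folds
    return assignment


def cv_optimal_ntrees(
    train: TrainingSet,
    tc: int = 5,
    lr: float = 0.01,
    bag_fraction: float = 0.75,
    min_node: int = 10,
    folds: int = 10,
    step: int = 50,
    max_trees: int = 10_000,
    patience: int = 5,
    seed: int = 0,
    schema: FeatureSchema | None = None,
) -> CVTrace:
    """Select the number of trees by stratified k-fold cross-validation.

    Trees are added in increments of ``step``; after each increment the mean
    withheld-fold Bernoulli deviance is recorded.  Growth stops at
    ``max_trees`` or after ``patience`` consecutive non-improving increments;
    the selected optimum is the grid argmin.
    """
    if folds < 2:
        raise InvalidArgumentError(f"folds must be >= 2, got {folds}")
    schema, X, y = _as_xy(train, schema)
    return _cv_on_arrays(X, y, tc, lr, bag_fraction, min_node, folds, step,
                         max_trees, patience, seed)


def _cv_on_arrays(X, y, tc, lr, bag_fraction, min_node, folds, step,
                  max_trees, patience, seed) -> CVTrace:
    rng = np.random.default_rng(seed)
    assignment = _stratified_folds(y, folds, rng)

    boosters = []
    val_sets = []
    for f in range(folds):
        val = assignment == f
        b = _Booster(X[~val], y[~val], tc, lr, bag_fraction, min_node,
                     np.random.default_rng(rng.integers(2**31)))
        b.register_eval(X[val])
        boosters.append(b)
        val_sets.append(y[val])

    grid: list[int] = []
    mean_dev: list[float] = []
    fold_dev: list[list[float]] = []
    fold_auc: list[list[float]] = []
    best = math.inf
    stall = 0
    n_grown = 0
    while n_grown < max_trees:
        k = min(step, max_trees - n_grown)
        devs, aucs = [], []
        for b, yv in zip(boosters, val_sets):
            b.grow(k)
            pv = b.eval_probs(0)
            devs.append(bernoulli_deviance(yv, pv))
            aucs.append(auc(yv, pv))
        n_grown += k
        grid.append(n_grown)
        fold_dev.append(devs)
        fold_auc.append(aucs)
        m = float(np.mean(devs))
        mean_dev.append(m)
        if m < best - 1e-9:
            best = m
            stall = 0
        else:
            stall += 1
            if stall >= patience:
                break

    grid_arr = np.array(grid, dtype=np.int64)
    mean_arr = np.array(mean_dev)
    opt_idx = int(np.argmin(mean_arr))
    null_devs = [
        bernoulli_deviance(yv, np.full(len(yv), y[assignment != f].mean()))
        for f, yv in enumerate(val_sets)
    ]
    dev_expl = 100.0 * (1.0 - mean_arr[opt_idx] / float(np.mean(null_devs)))
    return CVTrace(
        grid=grid_arr,
        mean_deviance=mean_arr,
        fold_deviance=np.array(fold_dev).T,
        fold_auc=np.array(fold_auc).T,
        optimal_ntrees=int(grid_arr[opt_idx]),
        cv_auc=float(np.mean(np.array(fold_auc)[opt_idx])),
        cv_deviance_explained_pct=float(dev_expl),
    )


def predict_rlo(model: BRTFit, X: pd.DataFrame) -> pd.Series:
    """Per-reach relative likelihood of occurrence, in (0, 1)."""
    return model.predict(X)


def bernoulli_deviance(y: np.ndarray, p: np.ndarray) -> float:
    """Mean Bernoulli deviance, ``-2 * [y ln p + (1-y) ln(1-p)]``."""
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    if y.shape != p.shape:
        raise InvalidArgumentError(
            f"length mismatch: y has {y.shape}, p has {p.shape}"
        )
    p = np.clip(p, _EPS, 1.0 - _EPS)
    return float(np.mean(-2.0 * (y * np.log(p) + (1.0 - y) * np.log(1.0 - p))))


def deviance_explained_pct(y: np.ndarray, p: np.ndarray, null_p: float | None = None) -> float:
    """Percentage of null-model deviance explained by the predictions."""
    y = np.asarray(y, dtype=float)
    if null_p is None:
        null_p = float(y.mean())
    null_dev = bernoulli_deviance(y, np.full(len(y), null_p))
    return 100.0 * (1.0 - bernoulli_deviance(y, p) / max(null_dev, _EPS))


def auc(y: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve via the tie-aware Mann-Whitney statistic."""
    y = np.asarray(y)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise InvalidArgumentError("y and scores must have the same length")
    pos = y == 1
    n_pos = int(pos.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUC is undefined with a single class")
    ranks = rankdata(s)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def relative_influence(model: BRTFit) -> pd.Series:
    """Per-predictor influence (%), from split-gain sums, normalised to 100."""
    total = np.zeros(len(model.schema.names))
    for tree in model.trees:
        total += tree.gains
    if total.sum() <= 0:
        warnings.warn("model has no splits; relative influence is all-zero")
        return pd.Series(total, index=list(model.schema.names))
    return pd.Series(100.0 * total / total.sum(), index=list(model.schema.names))


def ensemble_relative_influence(ensemble: "BRTEnsemble") -> pd.DataFrame:
    """Mean and sd of relative influence across ensemble members."""
    mat = pd.concat([relative_influence(m.model) for m in ensemble.members], axis=1)
    return pd.DataFrame({"mean": mat.mean(axis=1), "sd": mat.std(axis=1, ddof=1)})


def _resolve_grid(x: np.ndarray, grid, grid_size: int) -> np.ndarray:
    if grid is not None:
        return np.asarray(grid, dtype=float)
    qs = np.linspace(0.02, 0.98, grid_size)
    return np.unique(np.quantile(x, qs))


def partial_dependence(
    model: BRTFit,
    var_names,
    grid=None,
    grid_size: int = 25,
    data: pd.DataFrame | None = None,
    at_means: bool = False,
    link: bool = False,
):
    """Partial dependence of the model on one or two predictors.

    For every grid point the target predictor(s) are overwritten across the
    reference ``data`` rows (default: the training set) and predictions
    averaged — the direct, exact definition.  ``at_means=True`` instead holds
    all other predictors at their means, the convention used for interaction
    surface plots.  Returns ``(grid, values)`` for one variable and
    ``(grid_a, grid_b, values[a, b])`` for two.
    """
    if isinstance(var_names, str):
        var_names = (var_names,)
    var_names = tuple(var_names)
    if len(var_names) not in (1, 2):
        raise InvalidArgumentError("partial dependence supports 1 or 2 variables")
    for v in var_names:
        if v not in model.schema.names:
            raise SchemaError(f"unknown predictor {v!r}")
    if data is None:
        if model.train_X is None:
            raise InvalidArgumentError("no reference data: pass data= explicitly")
        data = model.train_X
    raw = data[list(model.schema.names)].to_numpy(dtype=float)
    if at_means:
        raw = raw.mean(axis=0, keepdims=True)
    cols = [model.schema.names.index(v) for v in var_names]
    grids = []
    if len(var_names) == 1:
        grids.append(_resolve_grid(data[var_names[0]].to_numpy(dtype=float), grid, grid_size))
    else:
        if grid is not None and len(grid) == 2:
            ga, gb = grid
            grids = [np.asarray(ga, dtype=float), np.asarray(gb, dtype=float)]
        else:
            grids = [
                _resolve_grid(data[v].to_numpy(dtype=float), None, grid_size)
                for v in var_names
            ]

    if len(var_names) == 1:
        cells = grids[0][:, None]
    else:
        a, b = np.meshgrid(grids[0], grids[1], indexing="ij")
        cells = np.column_stack([a.ravel(), b.ravel()])

    n_rows = len(raw)
    stacked = np.tile(raw, (len(cells), 1))
    for ci, col in enumerate(cols):
        stacked[:, col] = np.repeat(cells[:, ci], n_rows)
    M = model.schema.transform_matrix(stacked)
    F = model.predict_link_matrix(M)
    per_row = F if link else expit(F)
    vals = per_row.reshape(len(cells), n_rows).mean(axis=1)
    if len(var_names) == 1:
        return grids[0], vals
    return grids[0], grids[1], vals.reshape(len(grids[0]), len(grids[1]))


def interaction_strength(
    model: BRTFit,
    pair,
    grid_size: int = 20,
    data: pd.DataFrame | None = None,
) -> float:
    """Departure of the joint partial-dependence surface from additivity.

    The joint surface is built on a quantile grid on the link scale; the best
    additive approximation (row + column effects, least squares) is removed
    and the statistic is ``1000 x`` the mean squared residual.  Zero means a
    purely additive (no-interaction) pair; the statistic is symmetric in the
    pair order.
    """
    a, b = pair
    ref = data if data is not None else model.train_X
    if ref is None:
        raise InvalidArgumentError("no reference data: pass data= explicitly")
    for v in (a, b):
        if v not in model.schema.names:
            raise SchemaError(f"unknown predictor {v!r}")
        if np.ptp(ref[v].to_numpy(dtype=float)) == 0:
            warnings.warn(f"predictor {v!r} is constant; interaction strength is 0")
            return 0.0
    # evaluate on a canonical (sorted-name) order so the statistic is
    # symmetric by construction
    first, second = sorted((a, b))
    ga, gb, Z = partial_dependence(
        model, (first, second), grid_size=grid_size, data=ref, link=True
    )
    grand = Z.mean()
    rows = Z.mean(axis=1, keepdims=True) - grand
    colz = Z.mean(axis=0, keepdims=True) - grand
    resid = Z - grand - rows - colz
    return float(1000.0 * np.mean(resid**2))


@dataclass
class EnsembleMember:
    """One bootstrap simulation: a fit plus withheld-data diagnostics."""

    model: BRTFit
    withheld_ids: np.ndarray
    auc: float
    deviance_explained_pct: float


@dataclass
class BRTEnsemble:
    """Independently fitted boosted-tree models sharing one structure."""

    members: list[EnsembleMember]
    settings: dict = field(default_factory=dict)

    @property
    def n_members(self) -> int:
        return len(self.members)

    def predict_matrix(self, X: pd.DataFrame) -> pd.DataFrame:
        """Reaches x members matrix of predictions."""
        M = self.members[0].model.schema.transform(X)
        cols = {
            k: expit(m.model.predict_link_matrix(M))
            for k, m in enumerate(self.members)
        }
        return pd.DataFrame(cols, index=X.index)

    def to_dict(self) -> dict:
        return {
            "settings": self.settings,
            "members": [
                {
                    "model": m.model.to_dict(),
                    "withheld_ids": np.asarray(m.withheld_ids).tolist(),
                    "auc": m.auc,
                    "deviance_explained_pct": m.deviance_explained_pct,
                }
                for m in self.members
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BRTEnsemble":
        members = [
            EnsembleMember(
                model=BRTFit.from_dict(m["model"]),
                withheld_ids=np.array(m["withheld_ids"]),
                auc=float(m["auc"]),
                deviance_explained_pct=float(m["deviance_explained_pct"]),
            )
            for m in d["members"]
        ]
        return cls(members=members, settings=dict(d["settings"]))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "BRTEnsemble":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _stratified_holdout(y: np.ndarray, holdout: float, rng) -> np.ndarray:
    n = len(y)
    total_k = math.ceil(holdout * n)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    k_pos = int(round(total_k * len(pos) / n))
    k_pos = min(max(k_pos, 1), total_k - 1)
    k_neg = total_k - k_pos
    if k_pos >= len(pos) or k_neg >= len(neg) or k_neg < 1:
        raise InvalidArgumentError(
            f"holdout={holdout} would exhaust a class "
            f"({len(pos)} presences, {len(neg)} background)"
        )
    withheld = np.concatenate([
        rng.permutation(pos)[:k_pos],
        rng.permutation(neg)[:k_neg],
    ])
    mask = np.zeros(n, dtype=bool)
    mask[withheld] = True
    return mask


def fit_ensemble(
    train: TrainingSet,
    n_sims: int = 200,
    holdout: float = 0.2,
    tc: int = 5,
    lr: float = 0.01,
    bag_fraction: float = 0.75,
    n_trees: int = 1000,
    min_node: int = 10,
    seed: int = 0,
    bootstrap: bool = False,
    reselect_trees: bool = False,
    reselect_folds: int = 5,
    reselect_step: int = 50,
    schema: FeatureSchema | None = None,
) -> BRTEnsemble:
    """Fit ``n_sims`` bootstrapped simulations of the model structure.

    Each member withholds a stratified ``holdout`` fraction of the rows, fits
    on the remainder (or, with ``bootstrap=True``, on a same-size resample
    with replacement of the remainder) using the shared tree count, and
    records withheld-data AUC and deviance explained.  Member seeds derive
    deterministically from the master seed.  With ``reselect_trees=True``
    every member re-runs cross-validation on its own fitting rows to choose
    its tree count instead of reusing the shared one.
    """
    if n_sims < 2:
        raise InvalidArgumentError(f"n_sims must be >= 2, got {n_sims}")
    if not 0 < holdout < 1:
        raise InvalidArgumentError(f"holdout must be in (0, 1), got {holdout}")
    schema, X, y = _as_xy(train, schema)
    ss = np.random.SeedSequence(seed)
    members = []
    for child in ss.spawn(n_sims):
        rng = np.random.default_rng(child)
        withheld = _stratified_holdout(y, holdout, rng)
        fit_idx = np.flatnonzero(~withheld)
        if bootstrap:
            fit_idx = rng.choice(fit_idx, size=len(fit_idx), replace=True)
        member_trees = int(n_trees)
        if reselect_trees:
            trace = _cv_on_arrays(
                X[fit_idx], y[fit_idx], tc, lr, bag_fraction, min_node,
                reselect_folds, reselect_step, max_trees=n_trees * 2,
                patience=5, seed=int(child.generate_state(1)[0] % (2**31)),
            )
            member_trees = trace.optimal_ntrees
        booster = _Booster(X[fit_idx], y[fit_idx], tc, lr, bag_fraction, min_node, rng)
        k = booster.register_eval(X[withheld])
        booster.grow(member_trees)
        model = BRTFit(
            schema=schema, intercept=booster.intercept, trees=booster.trees,
            lr=lr, tc=tc, bag_fraction=bag_fraction, min_node=min_node,
            seed=int(child.generate_state(1)[0] % (2**31)),
        )
        pv = booster.eval_probs(k)
        yv = y[withheld]
        members.append(
            EnsembleMember(
                model=model,
                withheld_ids=np.asarray(train.reach_ids)[withheld],
                auc=auc(yv, pv),
                deviance_explained_pct=deviance_explained_pct(
                    yv, pv, null_p=float(y[fit_idx].mean())
                ),
            )
        )
    settings = {
        "n_sims": n_sims, "holdout": holdout, "tc": tc, "lr": lr,
        "bag_fraction": bag_fraction, "n_trees": n_trees,
        "min_node": min_node, "seed": seed, "bootstrap": bootstrap,
    }
    return BRTEnsemble(members=members, settings=settings)
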