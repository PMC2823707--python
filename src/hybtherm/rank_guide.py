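"""GUIDE-style regression trees and predictor-importance ranking.

The tree partitions probe data by recursive splits; at each node the split
variable is selected by unbiased chi-square tests rather than exhaustive
impurity search, which avoids the selection bias toward variables with many
distinct values:

* curvature test: residual signs of the node's least-squares fit are
  cross-tabulated against quartile bins of each predictor;
* interaction test: residual signs against the four cells of the
  median-half grid of each predictor pair.

The winning variable (smallest test p-value; ties resolved toward column
order) is split at the exhaustive least-squares-optimal point. Leaves carry
linear least-squares models on all predictors. Optional cost-complexity
pruning selects, by k-fold cross-validation, the smallest tree whose mean
prediction error is within one standard error of the minimum.

Importance of a predictor is the sum over split nodes of the selection-test
chi-square statistic weighted by sqrt(node size); bootstrap replication
yields means, standard deviations and relative scores (scaled by the top
predictor's mean).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError, NumericalDomainError, StateError


@dataclass(frozen=True)
class TreeConfig:
    min_node_size: int = 50
    max_depth: int = 12
    cv_folds: int = 10
    prune: bool = True
    interaction_tests: bool = True
    losing_vars_score: bool = False  # credit losing variables their own curvature stat
    seed: int = 0  # CV fold shuffling only

    def __post_init__(self) -> None:
        if self.min_node_size < 2:
            raise InputError("min_node_size must be >= 2")
        if self.cv_folds < 2:
            raise InputError("cv_folds must be >= 2")


@dataclass
class FeatureTable:
    """Numeric predictor matrix plus the intensity response."""

    X: pd.DataFrame
    y: np.ndarray
    response_scale: str = "linear"  # or "log2"

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if self.X.isna().any().any() or np.isnan(self.y).any():
            raise InputError("FeatureTable must not contain missing values")
        if len(self.X) != len(self.y):
            raise InputError(
                f"predictor rows ({len(self.X)}) != response length ({len(self.y)})"
            )
        if self.response_scale not in ("linear", "log2"):
            raise InputError(f"unknown response scale {self.response_scale!r}")

    @property
    def predictors(self) -> list:
        return list(self.X.columns)

    def subset(self, idx: np.ndarray) -> "FeatureTable":
        return FeatureTable(
            X=self.X.iloc[idx].reset_index(drop=True),
            y=self.y[idx],
            response_scale=self.response_scale,
        )


class _Node:
    __slots__ = (
        "size", "depth", "beta", "sse", "split_var", "threshold", "chi2",
        "curv_stats", "left", "right", "collapse_alpha",
    )

    def __init__(self, size: int, depth: int):
        self.size = size
        self.depth = depth
        self.beta = None
        self.sse = 0.0
        self.split_var = None  # column index, None for leaves
        self.threshold = math.nan
        self.chi2 = 0.0
        self.curv_stats = None
        self.left = None
        self.right = None
        self.collapse_alpha = math.inf

    @property
    def is_leaf(self) -> bool:
        return self.split_var is None


def _fit_linear(Xn: np.ndarray, yn: np.ndarray) -> tuple:
    design = np.column_stack([np.ones(len(yn)), Xn])
    beta, *_ = np.linalg.lstsq(design, yn, rcond=None)
    resid = yn - design @ beta
    return beta, resid, float(resid @ resid)


def _chi2_of_table(table: np.ndarray) -> tuple:
    """(statistic, p) for an r x c contingency table, zero margins dropped."""
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        return 0.0, 1.0
    rows = table.sum(axis=1, keepdims=True)
    cols = table.sum(axis=0, keepdims=True)
    expected = rows * cols / table.sum()
    stat = float(((table - expected) ** 2 / expected).sum())
    df = (table.shape[0] - 1) * (table.shape[1] - 1)
    return stat, float(stats.chi2.sf(stat, df))


def _sign_bins_table(bins: np.ndarray, n_cells: int, pos: np.ndarray) -> np.ndarray:
    table = np.zeros((n_cells, 2))
    np.add.at(table, (bins, pos.astype(int)), 1.0)
    return table


def _curvature_test(x: np.ndarray, pos: np.ndarray) -> tuple:
    edges = np.quantile(x, [0.25, 0.5, 0.75])
    bins = np.searchsorted(edges, x, side="right")
    return _chi2_of_table(_sign_bins_table(bins, 4, pos))


def _interaction_test(x1: np.ndarray, x2: np.ndarray, pos: np.ndarray) -> tuple:
    cells = (x1 >= np.median(x1)).astype(int) * 2 + (x2 >= np.median(x2)).astype(int)
    return _chi2_of_table(_sign_bins_table(cells, 4, pos))


def _best_split_point(x: np.ndarray, y: np.ndarray, min_size: int) -> tuple:
    """Exhaustive least-squares split of a single predictor.

    Returns (threshold, gain) maximizing the between-children sum-of-squares
    of the piecewise-constant model, or (nan, -inf) when no valid cut
    respects the minimum child size. Ties resolve to the smaller threshold.
    """
    n = len(x)
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    csum = np.cumsum(ys)
    total = csum[-1]
    ks = np.arange(min_size, n - min_size + 1)
    if len(ks) == 0:
        return math.nan, -math.inf
    valid = xs[ks - 1] < xs[ks]
    ks = ks[valid]
    if len(ks) == 0:
        return math.nan, -math.inf
    s_left = csum[ks - 1]
    crit = s_left**2 / ks + (total - s_left) ** 2 / (n - ks)
    best = int(np.argmax(crit))  # first max -> smallest threshold
    k = int(ks[best])
    return float((xs[k - 1] + xs[k]) / 2.0), float(crit[best])


class RegressionTree:
    """Fitted GUIDE-style tree with piecewise-linear leaf models."""

    def __init__(self, feature_names: list, config: TreeConfig):
        self.feature_names = list(feature_names)
        self.config = config
        self.root: _Node | None = None
        self.fitted = False
        self.constant_response = False
        self.pruning_trace: dict | None = None

    # -- prediction --

    def _predict_row(self, node: _Node, row: np.ndarray, alpha: float = -math.inf) -> float:
        while not node.is_leaf and node.collapse_alpha > alpha:
            node = node.left if row[node.split_var] <= node.threshold else node.right
        design = np.concatenate([[1.0], row])
        return float(design @ node.beta)

    def predict(self, X, alpha: float = -math.inf) -> np.ndarray:
        if not self.fitted:
            raise StateError("tree is not fitted")
        Xv = X[self.feature_names].to_numpy(float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
        return np.array([self._predict_row(self.root, row, alpha) for row in Xv])

    def split_nodes(self, alpha: float = -math.inf) -> list:
        out, stack = [], [self.root] if self.root else []
        while stack:
            node = stack.pop()
            if not node.is_leaf and node.collapse_alpha > alpha:
                out.append(node)
                stack.extend([node.left, node.right])
        return out

    def n_leaves(self, alpha: float = -math.inf) -> int:
        return len(self.split_nodes(alpha)) + 1


def _grow(Xv: np.ndarray, y: np.ndarray, idx: np.ndarray, depth: int, config: TreeConfig) -> _Node:
    node = _Node(size=len(idx), depth=depth)
    Xn, yn = Xv[idx], y[idx]
    node.beta, resid, node.sse = _fit_linear(Xn, yn)
    n_var = Xv.shape[1]
    node.curv_stats = np.zeros(n_var)
    if (
        len(idx) < 2 * config.min_node_size
        or depth >= config.max_depth
        or np.ptp(yn) == 0.0
    ):
        return node
    pos = resid >= 0
    curv = [_curvature_test(Xn[:, v], pos) for v in range(n_var)]
    node.curv_stats = np.array([c[0] for c in curv])
    best_p, best_kind, best_arg, best_stat = math.inf, None, None, 0.0
    for v in range(n_var):
        stat, p = curv[v]
        if p < best_p:
            best_p, best_kind, best_arg, best_stat = p, "curv", v, stat
    if config.interaction_tests:
        for v, w in itertools.combinations(range(n_var), 2):
            stat, p = _interaction_test(Xn[:, v], Xn[:, w], pos)
            if p < best_p:
                best_p, best_kind, best_arg, best_stat = p, "inter", (v, w), stat
    if best_kind is None:
        return node
    if best_kind == "curv":
        var = best_arg
    else:
        v, w = best_arg
        var = v if curv[v][1] <= curv[w][1] else w
    # fall back to any splittable variable if the winner is constant here
    if np.ptp(Xn[:, var]) == 0.0:
        usable = [v for v in range(n_var) if np.ptp(Xn[:, v]) > 0.0]
        if not usable:
            return node
        var = min(usable, key=lambda v: curv[v][1])
        best_stat = curv[var][0]
    threshold, gain = _best_split_point(Xn[:, var], yn, config.min_node_size)
    if not math.isfinite(gain):
        return node
    node.split_var = var
    node.threshold = threshold
    node.chi2 = best_stat
    mask = Xn[:, var] <= threshold
    node.left = _grow(Xv, y, idx[mask], depth + 1, config)
    node.right = _grow(Xv, y, idx[~mask], depth + 1, config)
    return node


def _assign_collapse_alphas(root: _Node) -> list:
    """Weakest-link cost-complexity sequence; tags nodes with collapse alpha.

    Node error is the SSE of its linear model; the subtree error is the sum
    over current leaves. Returns the increasing list of critical alphas.
    """
    alphas = []
    collapsed: set = set()

    def leaves_and_sse(node: _Node) -> tuple:
        if node.is_leaf or id(node) in collapsed:
            return 1, node.sse
        nl, sl = leaves_and_sse(node.left)
        nr, sr = leaves_and_sse(node.right)
        return nl + nr, sl + sr

    def internal_nodes(node: _Node, acc: list) -> list:
        if not node.is_leaf and id(node) not in collapsed:
            acc.append(node)
            internal_nodes(node.left, acc)
            internal_nodes(node.right, acc)
        return acc

    prev = 0.0
    while not (root.is_leaf or id(root) in collapsed):
        candidates = internal_nodes(root, [])
        gs = []
        for node in candidates:
            n_leaves, sub_sse = leaves_and_sse(node)
            g = (node.sse - sub_sse) / max(n_leaves - 1, 1)
            gs.append(g)
        g_min = max(min(gs), prev)
        for node, g in zip(candidates, gs):
            if g <= g_min + 1e-12:
                node.collapse_alpha = g_min
                collapsed.add(id(node))
        alphas.append(g_min)
        prev = g_min
    return alphas


def fit_tree(data: FeatureTable, config: TreeConfig | None = None) -> RegressionTree:
    """Grow (and optionally CV-prune) a GUIDE-style regression tree."""
    config = config or TreeConfig()
    tree = RegressionTree(data.predictors, config)
    Xv = data.X.to_numpy(float)
    y = data.y
    if len(y) < config.min_node_size:
        raise InputError(
            f"need at least min_node_size={config.min_node_size} rows, got {len(y)}"
        )
    tree.root = _grow(Xv, y, np.arange(len(y)), 0, config)
    tree.fitted = True
    tree.constant_response = np.ptp(y) == 0.0
    if config.prune and not tree.root.is_leaf:
        _prune_cv(tree, Xv, y, config)
    return tree


def _prune_cv(tree: RegressionTree, Xv: np.ndarray, y: np.ndarray, config: TreeConfig) -> None:
    alphas = _assign_collapse_alphas_clone(tree.root)
    if not alphas:
        return
    cand = [0.0]
    for a, b in zip(alphas, alphas[1:]):
        cand.append(math.sqrt(max(a, 1e-300) * max(b, 1e-300)))
    cand.append(alphas[-1] * 1.001 + 1e-12)
    rng = np.random.default_rng(config.seed)
    folds = np.array_split(rng.permutation(len(y)), config.cv_folds)
    grow_cfg = replace(config, prune=False)
    fold_err = np.full((config.cv_folds, len(cand)), np.nan)
    for f, test_idx in enumerate(folds):
        if len(test_idx) == 0:
            continue
        train_idx = np.setdiff1d(np.arange(len(y)), test_idx)
        sub = RegressionTree(tree.feature_names, grow_cfg)
        sub.root = _grow(Xv, y, train_idx, 0, grow_cfg)
        sub.fitted = True
        _assign_collapse_alphas(sub.root)
        for c, alpha in enumerate(cand):
            pred = np.array([sub._predict_row(sub.root, Xv[i], alpha) for i in test_idx])
            fold_err[f, c] = float(np.mean((y[test_idx] - pred) ** 2))
    errs = np.nanmean(fold_err, axis=0)
    ses = np.nanstd(fold_err, axis=0, ddof=1) / math.sqrt(config.cv_folds)
    best = int(np.argmin(errs))
    threshold = errs[best] + ses[best]
    chosen = max((a for a, e in zip(cand, errs) if e <= threshold), default=cand[best])
    _collapse_at(tree.root, chosen)
    tree.pruning_trace = {
        "alphas": cand,
        "cv_error": errs.tolist(),
        "cv_se": ses.tolist(),
        "chosen_alpha": chosen,
        "min_error": float(errs[best]),
        "one_se_threshold": float(threshold),
        "final_error": float(errs[cand.index(chosen)]),
    }


def _assign_collapse_alphas_clone(root: _Node) -> list:
    # alphas computed on the real tree; collapse_alpha tags are reused later
    return _assign_collapse_alphas(root)


def _collapse_at(node: _Node, alpha: float) -> None:
    if node.is_leaf:
        return
    if node.collapse_alpha <= alpha:
        node.split_var = None
        node.left = None
        node.right = None
        return
    _collapse_at(node.left, alpha)
    _collapse_at(node.right, alpha)


@dataclass
class ImportanceTable:
    """Per-predictor importance scores with optional bootstrap spread."""

    table: pd.DataFrame  # index: predictor; columns: mean, sd, relative
    reps: np.ndarray | None = None  # n_rep x n_predictors raw scores
    top_counts: pd.Series | None = None  # times each predictor ranked first

    @property
    def ranking(self) -> list:
        return list(self.table.sort_values("mean", ascending=False).index)


def _raw_scores(tree: RegressionTree) -> np.ndarray:
    scores = np.zeros(len(tree.feature_names))
    for node in tree.split_nodes():
        w = math.sqrt(node.size)
        if tree.config.losing_vars_score:
            scores += node.curv_stats * w
        else:
            scores[node.split_var] += node.chi2 * w
    return scores


def importance(tree: RegressionTree) -> ImportanceTable:
    """Raw importance: sum over split nodes of chi-square * sqrt(node size)."""
    if not tree.fitted:
        raise StateError("importance requires a fitted tree")
    raw = _raw_scores(tree)
    top = raw.max()
    rel = raw / top if top > 0 else np.zeros_like(raw)
    table = pd.DataFrame(
        {"mean": raw, "sd": np.zeros_like(raw), "relative": rel},
        index=tree.feature_names,
    )
    return ImportanceTable(table=table)


def bootstrap_importance(
    data: FeatureTable,
    protocol=("subsample", 0.9),
    n_rep: int = 100,
    seed: int = 0,
    config: TreeConfig | None = None,
) -> ImportanceTable:
    """Importance means/SDs over bootstrap or subsample replicates.

    ``protocol`` is ``("resample", size)`` for sampling with replacement or
    ``("subsample", fraction)`` for sampling 90% (say) without replacement.
    Deterministic for a fixed seed. Unpruned trees by default: pruning
    controls prediction overfit, while the deep noise nodes it removes carry
    near-zero chi-square weight in the importance sum.
    """
    if n_rep < 2:
        raise InputError(f"n_rep must be >= 2, got {n_rep}")
    if isinstance(protocol, str):
        kind, _, value = protocol.partition(":")
        protocol = (kind, float(value))
    kind, value = protocol
    n = len(data.y)
    if kind == "resample":
        size = int(value)
        if size < 1:
            raise InputError(f"resample size must be >= 1, got {size}")
    elif kind == "subsample":
        if not 0 < value <= 1:
            raise InputError(f"subsample fraction must be in (0, 1], got {value}")
        size = max(1, int(round(value * n)))
    else:
        raise InputError(f"unknown protocol kind {kind!r}")
    config = config or TreeConfig(prune=False)
    names = data.predictors
    reps = np.zeros((n_rep, len(names)))
    children = np.random.SeedSequence(seed).spawn(n_rep)
    Xv = data.X.to_numpy(float)
    for r in range(n_rep):
        rng = np.random.default_rng(children[r])
        if kind == "resample":
            idx = rng.integers(0, n, size=size)
        else:
            idx = rng.permutation(n)[:size]
        sub_tree = RegressionTree(names, config)
        sub_tree.root = _grow(Xv, data.y, np.asarray(idx), 0, config)
        sub_tree.fitted = True
        reps[r] = _raw_scores(sub_tree)
    means = reps.mean(axis=0)
    sds = reps.std(axis=0, ddof=1)
    top = means.max()
    rel = means / top if top > 0 else np.zeros_like(means)
    table = pd.DataFrame({"mean": means, "sd": sds, "relative": rel}, index=names)
    top_counts = pd.Series(
        np.bincount(reps.argmax(axis=1), minlength=len(names)), index=names
    )
    return ImportanceTable(table=table, reps=reps, top_counts=top_counts)


def spearman(x, y) -> tuple:
    """Spearman rank correlation with average ranks; exact p for n <= 8.

    Returns (rho, two-sided p). For n > 8 the t-approximation is used; for
    tiny samples the p-value is the exact permutation tail probability.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise InputError(f"length mismatch: {len(x)} vs {len(y)}")
    if len(x) < 3:
        raise InputError(f"need at least 3 observations, got {len(x)}")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise NumericalDomainError("Spearman correlation undefined for a constant vector")
    if len(x) > 8:
        rho, p = stats.spearmanr(x, y)
        return float(rho), float(p)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)

    def _rho(a, b):
        return float(np.corrcoef(a, b)[0, 1])

    obs = _rho(rx, ry)
    count, total = 0, 0
    for perm in itertools.permutations(ry):
        total += 1
        if abs(_rho(rx, np.array(perm))) >= abs(obs) - 1e-12:
            count += 1
    return obs, count / total
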