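"""Prognostic features, ROC analysis, cost-weighted cut-points and CART.

Per-cow candidate classifiers are built from the raw concentration series
(never log-transformed at this stage): the ante-partum median (baseline) and
maximum, the value at parturition (t0), daily values on days 1..10 post
partum (t1 grid) obtained by nearest-neighbour linear interpolation, the
increases from baseline and from parturition to day 10, and the parity
class.  Each feature is scored by the area under its ROC curve; a cut-point
is then selected by a generalized Youden criterion

    J(c) = Se(c) + r * Sp(c) - 1,      r = (1 - p) * CFP / (p * CFN),

which weights specificity by prevalence ``p`` and the misclassification
costs.  ``CFN = 4`` reflects that a missed future ketosis case costs about
four times an unnecessary propylene-glycol supplementation.  Higher
biomarker means sicker, so the classification rule is ``score >= cutoff =>
positive``; ties among maximizing cut-points break toward the lower cutoff
(favouring sensitivity, consistent with CFN > CFP).

A small CART learner (Gini impurity, minimum node size for splitting,
cost-complexity pruning selected by cross-validation with the 1-SE rule)
provides the multivariate cross-check on the single-feature ranking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import BIOMARKERS, CaseLabels, ObservationTable

__all__ = [
    "interpolate_at",
    "extract_features",
    "strict_prognostic_labels",
    "RocCurve",
    "roc_auc",
    "CutpointResult",
    "optimal_cutpoint",
    "ConfusionMetrics",
    "confusion_metrics",
    "rank_classifiers",
    "CartNode",
    "CartFit",
    "fit_cart",
]

T1_DAYS: tuple[int, ...] = tuple(range(1, 11))
HEADLINE_T1: int = 10


# ---------------------------------------------------------------------------
# feature construction
# ---------------------------------------------------------------------------

def interpolate_at(days: Sequence[float], values: Sequence[float], day: float) -> float | None:
    """Value at ``day`` by nearest-neighbour linear interpolation.

    Exact observation wins; otherwise linear interpolation between the
    nearest flanking observations.  Outside the observed range the value is
    missing (``None``) — never extrapolated.
    """
    d = np.asarray(days, dtype=float)
    v = np.asarray(values, dtype=float)
    if len(d) == 0:
        return None
    hit = np.nonzero(d == day)[0]
    if len(hit):
        return float(v[hit[0]])
    if day < d.min() or day > d.max():
        return None
    right = int(np.searchsorted(d, day))
    left = right - 1
    frac = (day - d[left]) / (d[right] - d[left])
    return float(v[left] + frac * (v[right] - v[left]))


def _cow_features(g: pd.DataFrame) -> dict[str, float]:
    out: dict[str, float] = {}
    for bm in BIOMARKERS:
        gg = g[g[bm].notna()]
        days = gg["day"].to_numpy(dtype=float)
        vals = gg[bm].to_numpy(dtype=float)
        ap = vals[days < 0]
        out[f"{bm}_median_ap"] = float(np.median(ap)) if len(ap) else np.nan
        out[f"{bm}_max_ap"] = float(np.max(ap)) if len(ap) else np.nan
        t0 = interpolate_at(days, vals, 0)
        out[f"{bm}_t0"] = np.nan if t0 is None else t0
        for d in T1_DAYS:
            td = interpolate_at(days, vals, d)
            out[f"{bm}_t1_d{d}"] = np.nan if td is None else td
        t1 = out[f"{bm}_t1_d{HEADLINE_T1}"]
        base = out[f"{bm}_median_ap"]
        out[f"{bm}_inc_baseline_t1"] = t1 - base
        out[f"{bm}_inc_partum_t1"] = t1 - out[f"{bm}_t0"]
    return out


def extract_features(table: ObservationTable, labels: CaseLabels | None = None) -> pd.DataFrame:
    """One row per cow with the full candidate-classifier panel.

    Increases are arithmetic differences on the natural concentration scale,
    taken at the headline t1 day (day 10 post partum).  A cow missing the
    neighbours needed for an interpolation has that feature missing (NaN),
    never zero.  ``parity_multiparous`` encodes the lactation-class feature.
    """
    rows = {}
    for cow_id, g in table.groupby_cow():
        if labels is not None and cow_id not in labels.is_case:
            continue
        feats = _cow_features(g)
        feats["parity_multiparous"] = float(g["parity"].iloc[0] == "multiparous")
        rows[cow_id] = feats
    fm = pd.DataFrame.from_dict(rows, orient="index")
    fm.index.name = "cow_id"
    return fm[_feature_order(fm.columns)]


def _feature_order(columns) -> list[str]:
    """Family order (baseline, max a.p., t0, t1 grid, increases, parity)."""
    def key(c: str):
        for rank, tag in enumerate(
            ("_median_ap", "_max_ap", "_t0", "_t1_d", "_inc_baseline", "_inc_partum")
        ):
            if tag in c:
                day = int(c.rsplit("_d", 1)[1]) if tag == "_t1_d" else 0
                return (rank, BIOMARKERS.index(c.split("_")[0]), day)
        return (9, 0, 0)
    return sorted(columns, key=key)


def strict_prognostic_labels(labels: CaseLabels, after_day: int = HEADLINE_T1) -> CaseLabels:
    """Leakage-guarded labels: drop cases whose onset is on or before ``after_day``.

    The day-10 feature can contain the very sample that labels a cow; this
    variant keeps only cases whose first exceedance falls strictly after the
    feature day, so the evaluation is genuinely prognostic.
    """
    keep_case = {c: d for c, d in labels.onset_day.items() if d > after_day}
    is_case = {
        c: (c in keep_case)
        for c, v in labels.is_case.items()
        if (not v) or c in keep_case
    }
    return CaseLabels(threshold=labels.threshold, is_case=is_case, onset_day=keep_case)


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RocCurve:
    """ROC curve for the rule ``score >= threshold => positive``."""

    thresholds: np.ndarray   # descending; aligned with fpr/tpr[1:-1]... see note
    fpr: np.ndarray          # starts at 0, ends at 1
    tpr: np.ndarray
    auc: float
    n_pos: int
    n_neg: int
    n_dropped: int = 0       # cows with missing scores

    @property
    def points(self) -> np.ndarray:
        return np.column_stack([self.fpr, self.tpr])


def roc_auc(scores: Sequence[float], labels: Sequence[bool]) -> RocCurve:
    """ROC curve and trapezoidal AUC.

    Tied scores collapse to one threshold (a diagonal ROC segment), so the
    trapezoidal AUC equals the Mann–Whitney estimator with half credit for
    ties.  Cows with missing scores are dropped and counted.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    ok = np.isfinite(s)
    n_dropped = int((~ok).sum())
    s, y = s[ok], y[ok]
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative score")

    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    # cumulative counts at each distinct threshold
    distinct = np.nonzero(np.diff(s_sorted))[0]
    cut_idx = np.append(distinct, len(s_sorted) - 1)
    tps = np.cumsum(y_sorted)[cut_idx]
    fps = np.cumsum(~y_sorted)[cut_idx]
    tpr = np.concatenate([[0.0], tps / n_pos])
    fpr = np.concatenate([[0.0], fps / n_neg])
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(
        thresholds=s_sorted[cut_idx],
        fpr=fpr,
        tpr=tpr,
        auc=auc,
        n_pos=n_pos,
        n_neg=n_neg,
        n_dropped=n_dropped,
    )


# ---------------------------------------------------------------------------
# cut-point selection and confusion metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionMetrics:
    """Se/Sp/PPV/NPV with Clopper–Pearson 95% intervals."""

    se: float | None
    sp: float | None
    ppv: float | None
    npv: float | None
    ci: dict[str, tuple[float, float]]
    tp: int
    fp: int
    fn: int
    tn: int


def _clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    alpha = 1.0 - level
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def confusion_metrics(tp: int, fp: int, fn: int, tn: int) -> ConfusionMetrics:
    """Sensitivity, specificity and predictive values from confusion counts.

    A metric whose denominator is zero is reported missing rather than
    raised; all-zero counts are fatal.
    """
    counts = dict(tp=tp, fp=fp, fn=fn, tn=tn)
    if any(v < 0 for v in counts.values()):
        raise ValueError(f"counts must be non-negative, got {counts}")
    if sum(counts.values()) == 0:
        raise ValueError("all confusion counts are zero")
    pairs = {
        "se": (tp, tp + fn),
        "sp": (tn, tn + fp),
        "ppv": (tp, tp + fp),
        "npv": (tn, tn + fn),
    }
    vals: dict[str, float | None] = {}
    cis: dict[str, tuple[float, float]] = {}
    for name, (k, n) in pairs.items():
        if n == 0:
            vals[name] = None
            continue
        vals[name] = k / n
        cis[name] = _clopper_pearson(k, n)
    return ConfusionMetrics(**vals, ci=cis, tp=tp, fp=fp, fn=fn, tn=tn)


@dataclass(frozen=True)
class CutpointResult:
    """Selected threshold and its operating characteristics."""

    cutoff: float
    youden: float
    metrics: ConfusionMetrics
    prevalence: float
    cfn: float
    cfp: float
    roc: RocCurve = field(repr=False)


def _counts_at(s: np.ndarray, y: np.ndarray, cutoff: float) -> tuple[int, int, int, int]:
    pred = s >= cutoff
    tp = int(np.sum(pred & y))
    fp = int(np.sum(pred & ~y))
    fn = int(np.sum(~pred & y))
    tn = int(np.sum(~pred & ~y))
    return tp, fp, fn, tn


def optimal_cutpoint(
    scores: Sequence[float],
    labels: Sequence[bool],
    prevalence: float | None = None,
    cfn: float = 4.0,
    cfp: float = 1.0,
) -> CutpointResult:
    """Cut-point maximizing the cost- and prevalence-weighted Youden index.

    With ``cfn = cfp = 1`` and ``prevalence = 0.5`` this reduces to the
    classical Youden criterion (maximize Se + Sp - 1).  ``prevalence``
    defaults to the sample prevalence.  Candidate cut-points are the
    midpoints between adjacent distinct scores plus one below and one above
    all scores; ties break toward the lower cutoff.
    """
    if cfn <= 0 or cfp <= 0:
        raise ValueError("costs must be > 0")
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    ok = np.isfinite(s)
    s, y = s[ok], y[ok]
    roc = roc_auc(s, y)
    p = roc.n_pos / (roc.n_pos + roc.n_neg) if prevalence is None else float(prevalence)
    if not 0 < p < 1:
        raise ValueError(f"prevalence must be in (0, 1), got {p}")
    r = (1.0 - p) * cfp / (p * cfn)

    uniq = np.unique(s)
    candidates = np.concatenate([
        [uniq[0] - 1.0],
        (uniq[:-1] + uniq[1:]) / 2.0,
        [uniq[-1] + 1.0],
    ])
    best_c, best_j = None, -np.inf
    for c in candidates:  # ascending, so ties keep the lower cutoff
        tp, fp, fn, tn = _counts_at(s, y, c)
        j = tp / (tp + fn) + r * (tn / (tn + fp)) - 1.0
        if j > best_j + 1e-12:
            best_j, best_c = j, float(c)
    tp, fp, fn, tn = _counts_at(s, y, best_c)
    return CutpointResult(
        cutoff=best_c,
        youden=best_j,
        metrics=confusion_metrics(tp, fp, fn, tn),
        prevalence=p,
        cfn=cfn,
        cfp=cfp,
        roc=roc,
    )


def rank_classifiers(features: pd.DataFrame, labels: CaseLabels) -> pd.DataFrame:
    """Score every feature column by AUC and sort descending.

    Ties break by feature-family order (column position).  Columns where the
    usable cows collapse to a single class are skipped.
    """
    y = features.index.map(labels.is_case).to_numpy(dtype=bool)
    rows = []
    for pos, col in enumerate(features.columns):
        s = features[col].to_numpy(dtype=float)
        ok = np.isfinite(s)
        if ok.sum() == 0 or y[ok].all() or not y[ok].any():
            continue
        curve = roc_auc(s[ok], y[ok])
        rows.append({
            "feature": col,
            "auc": curve.auc,
            "n_used": int(ok.sum()),
            "n_dropped": int((~ok).sum()),
            "_pos": pos,
        })
    if not rows:
        raise ValueError("no usable feature columns")
    out = pd.DataFrame(rows).sort_values(
        ["auc", "_pos"], ascending=[False, True], kind="stable"
    )
    return out.drop(columns="_pos").reset_index(drop=True)


# ---------------------------------------------------------------------------
# CART with cost-complexity pruning
# ---------------------------------------------------------------------------

@dataclass
class CartNode:
    n: int
    counts: tuple[int, int]           # (negatives, positives)
    prediction: bool
    gini: float
    feature: str | None = None
    threshold: float | None = None
    left: "CartNode | None" = None    # rows with value <= threshold
    right: "CartNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    def predict_row(self, row: dict[str, float]) -> bool:
        node = self
        while not node.is_leaf:
            node = node.left if row[node.feature] <= node.threshold else node.right
        return node.prediction

    def leaves(self) -> list["CartNode"]:
        if self.is_leaf:
            return [self]
        return self.left.leaves() + self.right.leaves()

    def depth(self) -> int:
        if self.is_leaf:
            return 0
        return 1 + max(self.left.depth(), self.right.depth())


def _gini(counts: tuple[int, int]) -> float:
    n = sum(counts)
    if n == 0:
        return 0.0
    p = counts[1] / n
    return 2.0 * p * (1.0 - p)


def _best_split(X: np.ndarray, y: np.ndarray, feature_names: list[str], min_leaf: int):
    """Exhaustive (feature, threshold) search by weighted-Gini decrease.

    Ties break toward the earlier feature, then the lower threshold.
    """
    n = len(y)
    parent = _gini((int(n - y.sum()), int(y.sum())))
    best = None  # (gain, feat_idx, threshold)
    for j in range(X.shape[1]):
        order = np.argsort(X[:, j], kind="stable")
        xs, ys = X[order, j], y[order]
        cum_pos = np.cumsum(ys)
        for i in range(min_leaf - 1, n - min_leaf):
            if xs[i] == xs[i + 1]:
                continue
            nl = i + 1
            pl = int(cum_pos[i])
            left = _gini((nl - pl, pl))
            right = _gini((n - nl - (int(cum_pos[-1]) - pl), int(cum_pos[-1]) - pl))
            gain = parent - (nl * left + (n - nl) * right) / n
            thr = (xs[i] + xs[i + 1]) / 2.0
            if gain > 1e-12 and (best is None or gain > best[0] + 1e-12):
                best = (gain, j, thr)
    if best is None:
        return None
    return feature_names[best[1]], best[2]


def _grow(X: np.ndarray, y: np.ndarray, names: list[str], min_node: int, min_leaf: int) -> CartNode:
    counts = (int(len(y) - y.sum()), int(y.sum()))
    node = CartNode(
        n=len(y), counts=counts,
        prediction=bool(counts[1] >= counts[0]),  # ties -> positive
        gini=_gini(counts),
    )
    if len(y) < min_node or node.gini == 0.0:
        return node
    split = _best_split(X, y, names, min_leaf)
    if split is None:
        return node
    feat, thr = split
    j = names.index(feat)
    mask = X[:, j] <= thr
    node.feature, node.threshold = feat, thr
    node.left = _grow(X[mask], y[mask], names, min_node, min_leaf)
    node.right = _grow(X[~mask], y[~mask], names, min_node, min_leaf)
    return node


def _copy_tree(node: CartNode) -> CartNode:
    new = replace(node)
    if not node.is_leaf:
        new.left = _copy_tree(node.left)
        new.right = _copy_tree(node.right)
    return new


def _leaf_error(node: CartNode, n_total: int) -> float:
    return min(node.counts) / n_total


def _subtree_error(node: CartNode, n_total: int) -> float:
    return sum(_leaf_error(l, n_total) for l in node.leaves())


def _weakest_link(node: CartNode, n_total: int):
    """(g, node) with the smallest cost-complexity ratio in the subtree."""
    best = None
    if not node.is_leaf:
        n_leaves = len(node.leaves())
        g = (_leaf_error(node, n_total) - _subtree_error(node, n_total)) / (n_leaves - 1)
        best = (g, node)
        for child in (node.left, node.right):
            sub = _weakest_link(child, n_total)
            if sub is not None and sub[0] < best[0] - 1e-15:
                best = sub
    return best


def _prune_path(root: CartNode) -> list[tuple[float, CartNode]]:
    """Nested subtree sequence from the full tree to the root stump.

    Returns ``[(alpha_k, T_k), ...]`` where ``T_k`` is optimal for complexity
    penalties in ``[alpha_k, alpha_{k+1})``; ``alpha_0 = 0``.
    """
    n_total = root.n
    tree = _copy_tree(root)
    path = [(0.0, _copy_tree(tree))]
    while not tree.is_leaf:
        g, node = _weakest_link(tree, n_total)
        node.left = node.right = None
        node.feature = node.threshold = None
        path.append((max(g, 0.0), _copy_tree(tree)))
    return path


def _prune_at(root: CartNode, alpha: float) -> CartNode:
    path = _prune_path(root)
    chosen = path[0][1]
    for a, t in path:
        if a <= alpha + 1e-15:
            chosen = t
    return chosen


@dataclass
class CartFit:
    """Pruned classification tree with its cross-validation trace."""

    root: CartNode
    feature_names: list[str]
    alpha: float
    cv_table: pd.DataFrame            # alpha, cv_error, se
    training_error: float
    n_used: int
    min_node: int
    cv_folds: int
    seed: int

    def predict(self, features: pd.DataFrame) -> pd.Series:
        rows = features[self.feature_names].to_dict(orient="index")
        return pd.Series(
            {k: self.root.predict_row(v) for k, v in rows.items()}, dtype=bool
        )


def fit_cart(
    features: pd.DataFrame,
    labels: CaseLabels,
    min_node: int = 10,
    min_leaf: int = 1,
    cv_folds: int = 5,
    seed: int = 0,
) -> CartFit:
    """Greedy Gini CART with cost-complexity pruning chosen by CV (1-SE rule).

    ``min_node`` is the minimum number of rows a node must have for a split
    to be attempted (leaves may be smaller, down to ``min_leaf``).  Rows with
    any missing feature are dropped; at least ``min_node`` complete rows are
    required so the root split is attemptable.  Deterministic given ``seed``
    (fold assignment).
    """
    y_full = features.index.map(labels.is_case)
    fm = features[y_full.notna()] if y_full.isna().any() else features
    complete = fm.dropna()
    if len(complete) < min_node:
        raise ValueError(
            f"need >= {min_node} complete-case rows, got {len(complete)}"
        )
    names = list(complete.columns)
    X = complete.to_numpy(dtype=float)
    y = complete.index.map(labels.is_case).to_numpy(dtype=bool)

    full = _grow(X, y, names, min_node, min_leaf)
    path = _prune_path(full)
    alphas = np.array([a for a, _ in path])
    # rpart-style candidate penalties: geometric means of successive alphas
    if len(alphas) > 1:
        inner = np.sqrt(np.maximum(alphas[:-1], 1e-12) * np.maximum(alphas[1:], 1e-12))
        cand = np.concatenate([[0.0], inner, [alphas[-1] + 1.0]])
    else:
        cand = np.array([0.0])

    rng = np.random.default_rng(seed)
    folds = rng.permutation(len(y)) % cv_folds
    errors = np.zeros((len(cand), len(y)))
    for k in range(cv_folds):
        tr, te = folds != k, folds == k
        if te.sum() == 0 or len(np.unique(y[tr])) < 2:
            continue
        fold_tree = _grow(X[tr], y[tr], names, min_node, min_leaf)
        for ci, a in enumerate(cand):
            pruned = _prune_at(fold_tree, a)
            pred = np.array([
                pruned.predict_row(dict(zip(names, row))) for row in X[te]
            ])
            errors[ci, te] = pred != y[te]
    cv_err = errors.mean(axis=1)
    cv_se = errors.std(axis=1, ddof=1) / math.sqrt(len(y))
    best_i = int(np.argmin(cv_err))
    # 1-SE rule: simplest tree within one SE of the minimum
    ok = cv_err <= cv_err[best_i] + cv_se[best_i]
    chosen_alpha = float(cand[np.nonzero(ok)[0].max()])

    final = _prune_at(full, chosen_alpha)
    train_pred = np.array([final.predict_row(dict(zip(names, row))) for row in X])
    return CartFit(
        root=final,
        feature_names=names,
        alpha=chosen_alpha,
        cv_table=pd.DataFrame({"alpha": cand, "cv_error": cv_err, "se": cv_se}),
        training_error=float(np.mean(train_pred != y)),
        n_used=len(y),
        min_node=min_node,
        cv_folds=cv_folds,
        seed=seed,
    )
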