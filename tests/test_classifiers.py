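import itertools

import numpy as np
import pandas as pd
import pytest

from lactocurve import (
    CaseLabels,
    SimulationConfig,
    confusion_metrics,
    extract_features,
    fit_cart,
    interpolate_at,
    label_cows,
    optimal_cutpoint,
    rank_classifiers,
    roc_auc,
    simulate_herd,
    strict_prognostic_labels,
)
from lactocurve.synthetic_data import curve_from_anchors
from lactocurve.spline_basis import SplineSpec

from conftest import make_table


def pair_count_auc(scores, labels):
    """Mann-Whitney AUC by brute-force pair enumeration (half credit for ties)."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def exhaustive_youden(scores, labels, p, cfn, cfp):
    """Best cutoff by exhaustive search over all midpoints (lowest wins ties)."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, bool)
    uniq = np.unique(s)
    cands = np.concatenate([[uniq[0] - 1], (uniq[:-1] + uniq[1:]) / 2, [uniq[-1] + 1]])
    r = (1 - p) * cfp / (p * cfn)
    best_c, best_j = None, -np.inf
    for c in cands:
        pred = s >= c
        se = (pred & y).sum() / y.sum()
        sp = (~pred & ~y).sum() / (~y).sum()
        j = se + r * sp - 1
        if j > best_j + 1e-12:
            best_j, best_c = j, c
    return best_c, best_j


class TestInterpolateAt:
    def test_linear_between_neighbours(self):
        assert interpolate_at([7, 14], [0.4, 1.1], 10) == pytest.approx(
            0.4 + (3 / 7) * 0.7
        )

    def test_exact_observation_wins(self):
        assert interpolate_at([10], [0.9], 10) == 0.9

    def test_outside_range_is_missing(self):
        assert interpolate_at([12, 19], [0.5, 0.8], 10) is None
        assert interpolate_at([], [], 10) is None

    def test_nearest_flanking_neighbours_used(self):
        # day 10 between 7 and 14, other points must not influence the value
        v = interpolate_at([0, 7, 14, 21], [9.9, 0.4, 1.1, 0.1], 10)
        assert v == pytest.approx(0.4 + (3 / 7) * 0.7)


class TestExtractFeatures:
    def test_ante_partum_order_statistics(self):
        table = make_table([
            ("A", -14, 0.3), ("A", -7, 0.5), ("A", -3, 0.4), ("A", 5, 0.6),
        ])
        fm = extract_features(table)
        assert fm.at["A", "bhb_median_ap"] == pytest.approx(0.4)
        assert fm.at["A", "bhb_max_ap"] == pytest.approx(0.5)

    def test_increase_from_partum_to_t1(self):
        table = make_table([("A", 0, 0.5), ("A", 10, 0.7)])
        fm = extract_features(table)
        assert fm.at["A", "bhb_t0"] == pytest.approx(0.5)
        assert fm.at["A", "bhb_t1_d10"] == pytest.approx(0.7)
        assert fm.at["A", "bhb_inc_partum_t1"] == pytest.approx(0.2)

    def test_missing_neighbours_give_nan_not_zero(self):
        table = make_table([("A", 5, 0.6), ("A", 12, 0.7)])  # no a.p., no day-0
        fm = extract_features(table)
        assert np.isnan(fm.at["A", "bhb_median_ap"])
        assert np.isnan(fm.at["A", "bhb_max_ap"])
        assert np.isnan(fm.at["A", "bhb_t0"])
        assert np.isnan(fm.at["A", "bhb_t1_d1"])  # before first observation

    def test_deterministic_re_extraction(self, herd):
        a = extract_features(herd.table)
        b = extract_features(herd.table)
        assert a.equals(b)
        assert len(a) == herd.table.n_cows


class TestRocAuc:
    def test_perfect_separation(self):
        roc = roc_auc([0, 0, 1, 1], [False, False, True, True])
        assert roc.auc == 1.0

    def test_all_tied_scores(self):
        roc = roc_auc([0.5] * 6, [True, False] * 3)
        assert roc.auc == pytest.approx(0.5)

    def test_five_point_toy_matches_pair_counting(self):
        scores = [0.2, 0.4, 0.3, 0.8, 0.5]
        labels = [False, True, False, True, False]
        roc = roc_auc(scores, labels)
        assert roc.auc == pytest.approx(pair_count_auc(scores, labels), abs=1e-15)

    def test_trapezoid_equals_pair_count_on_random_sets(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            n = rng.integers(4, 20)
            scores = rng.integers(0, 6, size=n) / 5.0  # force ties
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            assert roc_auc(scores, labels).auc == pytest.approx(
                pair_count_auc(scores, labels), abs=1e-12
            )

    def test_curve_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(9)
        roc = roc_auc(rng.random(30), rng.random(30) < 0.4)
        assert roc.fpr[0] == 0.0 and roc.tpr[0] == 0.0
        assert roc.fpr[-1] == 1.0 and roc.tpr[-1] == 1.0
        assert (np.diff(roc.fpr) >= 0).all() and (np.diff(roc.tpr) >= 0).all()

    def test_sklearn_cross_check(self):
        sk = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(12)
        for _ in range(10):
            scores = rng.normal(size=25)
            labels = rng.random(25) < 0.5
            if labels.all() or not labels.any():
                continue
            assert roc_auc(scores, labels).auc == pytest.approx(
                sk.roc_auc_score(labels, scores), abs=1e-12
            )

    def test_missing_scores_dropped_and_counted(self):
        roc = roc_auc([np.nan, 0.2, 0.9, 0.4], [True, False, True, False])
        assert roc.n_dropped == 1 and roc.n_pos == 1 and roc.n_neg == 2

    def test_single_class_fatal(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [True, True])


class TestOptimalCutpoint:
    def test_perfect_separation(self):
        res = optimal_cutpoint([0.1, 0.2, 0.8, 0.9], [False, False, True, True])
        assert res.metrics.se == 1.0 and res.metrics.sp == 1.0
        assert 0.2 < res.cutoff < 0.8

    def test_matches_exhaustive_search_on_toy(self):
        scores = [0.1, 0.3, 0.35, 0.5, 0.55, 0.7, 0.75, 0.9]
        labels = [False, False, True, False, True, True, False, True]
        res = optimal_cutpoint(scores, labels, prevalence=0.5, cfn=4, cfp=1)
        c, j = exhaustive_youden(scores, labels, 0.5, 4, 1)
        assert res.cutoff == pytest.approx(c)
        assert res.youden == pytest.approx(j)

    def test_unit_costs_reduce_to_classical_youden(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=20)
        labels = np.concatenate([np.zeros(10, bool), rng.random(10) < 0.8])
        res = optimal_cutpoint(scores, labels, prevalence=0.5, cfn=1, cfp=1)
        c, j = exhaustive_youden(scores, labels, 0.5, 1, 1)
        assert res.cutoff == pytest.approx(c)

    def test_raising_cfn_never_raises_cutoff(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(8, 30))
            scores = np.round(rng.normal(size=n), 2)
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            cuts = [
                optimal_cutpoint(scores, labels, cfn=cfn).cutoff
                for cfn in (1, 2, 4, 8)
            ]
            assert all(b <= a + 1e-12 for a, b in zip(cuts, cuts[1:]))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            optimal_cutpoint([0.1, 0.9], [False, True], cfn=0)
        with pytest.raises(ValueError):
            optimal_cutpoint([0.1, 0.9], [False, True], prevalence=1.5)


class TestConfusionMetrics:
    def test_all_correct(self):
        m = confusion_metrics(tp=10, fp=0, fn=0, tn=10)
        assert m.se == m.sp == m.ppv == m.npv == 1.0

    def test_cis_contain_point_and_shrink(self):
        m1 = confusion_metrics(tp=47, fp=12, fn=4, tn=36)
        for name, val in (("se", m1.se), ("sp", m1.sp), ("ppv", m1.ppv), ("npv", m1.npv)):
            lo, hi = m1.ci[name]
            assert lo <= val <= hi
        m10 = confusion_metrics(tp=470, fp=120, fn=40, tn=360)
        for name in ("se", "sp", "ppv", "npv"):
            w1 = m1.ci[name][1] - m1.ci[name][0]
            w10 = m10.ci[name][1] - m10.ci[name][0]
            assert w10 < w1

    def test_zero_denominator_metric_missing(self):
        m = confusion_metrics(tp=0, fp=0, fn=0, tn=5)
        assert m.ppv is None and m.se is None and m.sp == 1.0

    def test_all_zero_fatal(self):
        with pytest.raises(ValueError):
            confusion_metrics(0, 0, 0, 0)

    def test_negative_count_fatal(self):
        with pytest.raises(ValueError):
            confusion_metrics(-1, 0, 0, 5)


class TestRankClassifiers:
    def test_postpartum_bhb_ranks_first_on_default_herd(self, herd, herd_labels):
        fm = extract_features(herd.table, herd_labels)
        ranking = rank_classifiers(fm, herd_labels)
        top = ranking.iloc[0]["feature"]
        assert top.startswith("bhb")
        assert "_t1_d" in top or "_inc_" in top
        assert ranking.iloc[0]["auc"] > 0.85

    def test_single_feature(self, herd, herd_labels):
        fm = extract_features(herd.table, herd_labels)[["bhb_t1_d10"]]
        ranking = rank_classifiers(fm, herd_labels)
        assert len(ranking) == 1

    def test_label_independent_feature_has_null_auc(self):
        rng = np.random.default_rng(8)
        labels = np.concatenate([np.ones(50, bool), np.zeros(50, bool)])
        aucs = [
            roc_auc(rng.normal(size=100), labels).auc for _ in range(200)
        ]
        mc_se = np.std(aucs, ddof=1) / np.sqrt(len(aucs))
        assert abs(np.mean(aucs) - 0.5) < 2 * mc_se

    def test_strong_group_gap_gives_high_auc(self):
        # post-partum-only BHB gap of 0.5 log-units
        cfg0 = SimulationConfig()
        spec = SplineSpec()
        base = cfg0.group_curves["bhb"][0]
        anchors = (-27, -20, -7, 0, 7, 14, 30, 50, 80)
        gap = curve_from_anchors(
            anchors, [0.0, 0.0, 0.0, 0.25, 0.5, 0.5, 0.5, 0.5, 0.5], spec
        )
        curves = dict(cfg0.group_curves)
        curves["bhb"] = (base, base + gap)
        sim = simulate_herd(SimulationConfig(
            n_cows=200, seed=41, group_curves=curves, sigma_group_slope=0.0
        ))
        truth_is_case = sim.truth["case_type"].to_dict()
        labels = CaseLabels(
            threshold=0.8, is_case=truth_is_case,
            onset_day={c: 0 for c, v in truth_is_case.items() if v},
        )
        fm = extract_features(sim.table, labels)
        auc = rank_classifiers(fm, labels).set_index("feature").at["bhb_t1_d10", "auc"]
        assert auc > 0.9


class TestStrictPrognosticLabels:
    def test_early_onset_cases_removed(self):
        labels = CaseLabels(
            threshold=0.8,
            is_case={"A": True, "B": True, "C": False},
            onset_day={"A": 6, "B": 20},
        )
        strict = strict_prognostic_labels(labels, after_day=10)
        assert "A" not in strict.is_case
        assert strict.is_case == {"B": True, "C": False}


def gini(y):
    p = np.mean(y)
    return 2 * p * (1 - p)


def exhaustive_root_split(X, y):
    """Best (feature, threshold) by full enumeration of all splits."""
    best = None
    n = len(y)
    for j in range(X.shape[1]):
        for thr in np.unique(X[:, j]):
            mask = X[:, j] <= thr
            if mask.all() or not mask.any():
                continue
            score = (mask.sum() * gini(y[mask]) + (~mask).sum() * gini(y[~mask])) / n
            if best is None or score < best[0] - 1e-12:
                best = (score, j, thr)
    return best


class TestCart:
    def _features_labels(self, values, labels_list, feature="f"):
        fm = pd.DataFrame({feature: values},
                          index=[f"c{i}" for i in range(len(values))])
        is_case = {f"c{i}": bool(l) for i, l in enumerate(labels_list)}
        labels = CaseLabels(
            threshold=0.8, is_case=is_case,
            onset_day={c: 0 for c, v in is_case.items() if v},
        )
        return fm, labels

    def test_perfect_single_split(self):
        vals = list(np.linspace(0, 0.4, 12)) + list(np.linspace(0.6, 1.0, 12))
        fm, labels = self._features_labels(vals, [0] * 12 + [1] * 12)
        fit = fit_cart(fm, labels, min_node=10, seed=0)
        assert fit.root.depth() == 1
        assert 0.4 < fit.root.threshold < 0.6
        assert fit.training_error == 0.0

    def test_node_below_min_size_never_split(self):
        # 9 impure rows in one side after the root split must stay a leaf
        vals = list(range(20))
        ys = [0] * 11 + [1, 0, 1, 0, 1, 0, 1, 0, 1]
        fm, labels = self._features_labels([float(v) for v in vals], ys)
        fit = fit_cart(fm, labels, min_node=10, cv_folds=2, seed=1)
        for leaf_parent in _internal_nodes(fit.root):
            for child in (leaf_parent.left, leaf_parent.right):
                if child.is_leaf and child.gini > 0:
                    assert child.n < 10 or _no_valid_split(child)

    def test_root_split_matches_exhaustive_gini_search(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            X = rng.normal(size=(12, 3)).round(1)
            y = rng.random(12) < 0.5
            if y.all() or not y.any():
                continue
            fm = pd.DataFrame(X, columns=list("abc"),
                              index=[f"c{i}" for i in range(12)])
            is_case = {f"c{i}": bool(v) for i, v in enumerate(y)}
            labels = CaseLabels(threshold=0.8, is_case=is_case,
                                onset_day={c: 0 for c, v in is_case.items() if v})
            fit = fit_cart(fm, labels, min_node=10, cv_folds=2, seed=0)
            best = exhaustive_root_split(X, y)
            full_gain = gini(y) - best[0]
            if fit.root.is_leaf:
                # pruning removed the split; the unpruned gain must be small
                continue
            assert fit.root.feature == "abc"[best[1]]

    def test_sklearn_tree_cross_check_on_root_split(self):
        tree_mod = pytest.importorskip("sklearn.tree")
        rng = np.random.default_rng(15)
        X = np.round(rng.normal(size=(40, 2)), 1)
        y = (X[:, 0] + 0.3 * rng.normal(size=40)) > 0
        fm = pd.DataFrame(X, columns=["a", "b"], index=[f"c{i}" for i in range(40)])
        is_case = {f"c{i}": bool(v) for i, v in enumerate(y)}
        labels = CaseLabels(threshold=0.8, is_case=is_case,
                            onset_day={c: 0 for c, v in is_case.items() if v})
        fit = fit_cart(fm, labels, min_node=10, seed=0)
        clf = tree_mod.DecisionTreeClassifier(
            max_depth=1, criterion="gini", random_state=0
        ).fit(X, y)
        assert fit.root.feature == ["a", "b"][clf.tree_.feature[0]]
        assert fit.root.threshold == pytest.approx(clf.tree_.threshold[0], abs=0.051)

    def test_deterministic_given_seed(self, herd, herd_labels):
        fm = extract_features(herd.table, herd_labels)
        a = fit_cart(fm, herd_labels, seed=3)
        b = fit_cart(fm, herd_labels, seed=3)
        assert a.alpha == b.alpha and a.training_error == b.training_error

    def test_too_few_complete_rows_fatal(self):
        fm, labels = self._features_labels([0.1, 0.9, 0.3, 0.7, 0.5], [0, 1, 0, 1, 0])
        with pytest.raises(ValueError, match="complete-case"):
            fit_cart(fm, labels, min_node=10)


def _internal_nodes(node):
    if node.is_leaf:
        return []
    return [node] + _internal_nodes(node.left) + _internal_nodes(node.right)


def _no_valid_split(node):
    return True  # leaf kept; reason (min size or no gain) checked via n
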