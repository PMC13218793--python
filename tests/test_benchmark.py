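import numpy as np
import pytest

from metacci.benchmark import (
    SyntheticDesign,
    classification_metrics,
    generate_populations,
    pooled_matrix,
    roc_pr_auc,
    youden_threshold,
)
from metacci.eigencell import compute_eigencells, eigencell_correlation


def pairwise_roc_auc(weights, labels):
    """Fraction of (positive, negative) pairs ranked correctly, ties 1/2."""
    pos = weights[labels]
    neg = weights[~labels]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestGeneratePopulations:
    def test_deterministic(self):
        d = SyntheticDesign(n_cells_per_group=20, oversample=1, seed=5)
        a = generate_populations(d)
        b = generate_populations(d)
        for g in a:
            np.testing.assert_array_equal(a[g].values, b[g].values)

    def test_dimensions_and_nonnegativity(self):
        d = SyntheticDesign(n_genes=8, n_cells_per_group=15, oversample=2, seed=0)
        pops = generate_populations(d)
        assert set(pops) == {"T1", "T2", "F1", "F2"}
        for g, X in pops.items():
            assert X.values.shape == (30, 8)
            assert X.values.min() >= 0.0
            assert list(X.group_labels) == [g] * 30

    def test_shared_signal_aligns_leading_eigencells(self):
        d = SyntheticDesign(n_cells_per_group=300, oversample=1, seed=3)
        pops = generate_populations(d)
        e1 = compute_eigencells(pops["T1"].values)
        e2 = compute_eigencells(pops["T2"].values)
        ef = compute_eigencells(pops["F1"].values)

        def best_match_mean(a, b, k=8):
            G = np.abs(
                np.corrcoef(a.E[:, :k].T, b.E[:, :k].T)[:k, k:]
            )
            return G.max(axis=1).mean()

        # most leading T1 eigen-cells find a strong partner in T2
        # (component order may permute between draws) but not in F1
        assert best_match_mean(e1, e2) > 0.6
        assert best_match_mean(e1, e2) > best_match_mean(e1, ef) + 0.2

    def test_zero_strength_removes_group_mean_correlation(self):
        d = SyntheticDesign(
            n_cells_per_group=200, oversample=1, seed=2, shared_factor_strength=0.0
        )
        pops = generate_populations(d)
        # centered mean profiles of T1 vs T2 only share the baseline; the
        # cell-level factor correlation is gone
        c1 = pops["T1"].values - pops["T1"].values.mean(axis=0)
        c2 = pops["T2"].values - pops["T2"].values.mean(axis=0)
        cross = np.abs(np.corrcoef(c1.T, c2.T)[:8, 8:])
        assert cross.mean() < 0.15

    def test_planted_regulation_only_in_t1(self):
        d = SyntheticDesign(n_cells_per_group=200, oversample=1, seed=1)
        pops = generate_populations(d)
        for grp, lo in [("T1", 0.5), ("T2", 0.0)]:
            V = pops[grp].values
            r = abs(np.corrcoef(V[:, 0], V[:, 1])[0, 1])
            if grp == "T1":
                assert r > lo
        rT1 = abs(np.corrcoef(pops["T1"].values[:, 0], pops["T1"].values[:, 1])[0, 1])
        rT2 = abs(np.corrcoef(pops["T2"].values[:, 0], pops["T2"].values[:, 1])[0, 1])
        assert rT1 > rT2

    def test_invalid_dimensions_error(self):
        with pytest.raises(ValueError):
            generate_populations(SyntheticDesign(n_genes=1))

    def test_pooled_matrix_stacks_groups(self):
        d = SyntheticDesign(n_cells_per_group=5, oversample=1, seed=0)
        pops = generate_populations(d)
        X = pooled_matrix(pops)
        assert X.n_cells == 20
        assert X.groups == ["T1", "T2", "F1", "F2"]


class TestRocPrAuc:
    def test_perfect_separation(self):
        roc, pr = roc_pr_auc(np.array([5.0, 4.0, 1.0, 0.5]), np.array([1, 1, 0, 0]))
        assert roc == 1.0 and pr == 1.0

    def test_rank_enumeration_example(self):
        roc, _ = roc_pr_auc(np.array([3.0, 2.0, 1.0]), np.array([1, 1, 0]))
        assert roc == 1.0

    def test_random_scores_near_half(self, rng):
        w = rng.normal(size=2000)
        y = rng.random(2000) < 0.5
        roc, _ = roc_pr_auc(w, y)
        assert 0.45 < roc < 0.55

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_pairwise_mann_whitney(self, seed):
        r = np.random.default_rng(seed)
        w = np.round(r.normal(size=30), 1)  # coarse values force ties
        y = r.random(30) < 0.4
        if y.all() or not y.any():
            pytest.skip("degenerate draw")
        roc, _ = roc_pr_auc(w, y)
        assert roc == pytest.approx(pairwise_roc_auc(w, y), abs=1e-12)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            roc_pr_auc(np.array([1.0, 2.0]), np.array([1, 1]))


class TestYoudenThreshold:
    def test_perfect_separation_threshold_between_classes(self):
        thr = youden_threshold(np.array([1.0, 2.0, 3.0, 4.0]), np.array([0, 0, 1, 1]))
        assert 2.0 < thr < 3.0

    def test_all_equal_scores_j_zero(self):
        w = np.full(6, 2.0)
        y = np.array([0, 1, 0, 1, 0, 1])
        thr = youden_threshold(w, y)
        pred = w >= thr
        tpr = (pred & (y == 1)).sum() / 3
        tnr = (~pred & (y == 0)).sum() / 3
        assert tpr + tnr - 1 == pytest.approx(0.0)

    def test_exhaustive_scan_agreement(self, rng):
        w = rng.normal(size=40)
        y = rng.random(40) < 0.5
        if y.all() or not y.any():
            y[0] = ~y[0]
        thr = youden_threshold(w, y)

        def j_at(t):
            pred = w >= t
            return (pred & y).sum() / y.sum() + (~pred & ~y).sum() / (~y).sum() - 1

        best = max(j_at(t) for t in np.linspace(w.min() - 1, w.max() + 1, 2000))
        assert j_at(thr) == pytest.approx(best, abs=1e-9)


class TestClassificationMetrics:
    def test_perfect_prediction(self):
        m = classification_metrics(np.array([1, 0, 1]), np.array([1, 0, 1]))
        assert m["accuracy"] == 1.0 and m["f1"] == 1.0

    def test_all_negative_predictor_degenerate_pattern(self):
        # all-negative calls on half-positive truth: TPR 0, TNR 1,
        # precision 0, F1 0 (denominator guard)
        pred = np.zeros(10, dtype=bool)
        truth = np.array([1] * 5 + [0] * 5, dtype=bool)
        m = classification_metrics(pred, truth)
        assert m["tpr"] == 0.0 and m["tnr"] == 1.0
        assert m["precision"] == 0.0 and m["f1"] == 0.0
        assert m["accuracy"] == 0.5

    def test_balanced_half_right(self):
        pred = np.array([1, 1, 0, 0], dtype=bool)
        truth = np.array([1, 0, 1, 0], dtype=bool)
        m = classification_metrics(pred, truth)
        for key in ("accuracy", "precision", "recall", "f1"):
            assert m[key] == pytest.approx(0.5)

    def test_order_invariance(self, rng):
        pred = rng.random(30) < 0.5
        truth = rng.random(30) < 0.5
        perm = rng.permutation(30)
        assert classification_metrics(pred, truth) == classification_metrics(
            pred[perm], truth[perm]
        )


class TestPairGenerators:
    def test_identical_pair_is_exchangeable_by_construction(self):
        from metacci.benchmark import generate_identical_pair

        XQ, XC = generate_identical_pair(n_cells=40, n_genes=6, seed=3)
        XQ2, XC2 = generate_identical_pair(n_cells=40, n_genes=6, seed=3)
        np.testing.assert_array_equal(XQ.values, XQ2.values)
        np.testing.assert_array_equal(XC.values, XC2.values)
        assert XQ.values.min() >= 0 and XC.values.min() >= 0
        # common (not per-group) shift: the global minimum over both
        # groups is exactly zero when any raw value was negative
        assert min(XQ.values.min(), XC.values.min()) == pytest.approx(0.0)
        assert XQ.gene_names == XC.gene_names

    def test_regulator_pair_plants_edges_only_in_query(self):
        from metacci.benchmark import generate_regulator_pair

        XQ, XC = generate_regulator_pair(n_cells=300, n_genes=10, effect=1.0, seed=0)
        rq = abs(np.corrcoef(XQ.values[:, 0], XQ.values[:, 1])[0, 1])
        rc = abs(np.corrcoef(XC.values[:, 0], XC.values[:, 1])[0, 1])
        assert rq > 0.5 and rc < 0.2
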