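"""SVM cross-validation, pairwise posterior coupling, confusion metrics."""

import numpy as np
import pytest

from eegconn.classify import (
    ConfusionMatrix,
    EvaluationReport,
    SVMConfig,
    confusion_metrics,
    couple_multiclass,
    crossval_binary,
    crossval_multiclass,
    crossval_multiclass_pairwise,
    grid_search,
)
from eegconn.selection import FeatureDescriptor, FeatureTable
from eegconn.worked_examples import (
    THREE_CLASS_CONFUSIONS,
    TWO_CLASS_SCI_VS_AD_EPEN,
    recombine_two_class_accuracy,
    recompute_total_accuracy,
)


def clouds(rng, n_per=15, sep=10.0, d=3):
    X = np.vstack(
        [rng.standard_normal((n_per, d)), rng.standard_normal((n_per, d)) + sep]
    )
    y = np.array([0] * n_per + [1] * n_per)
    return X, y


class TestCrossvalBinary:
    def test_separable_clouds_perfect(self, rng):
        X, y = clouds(rng)
        rep = crossval_binary(X, y)
        assert rep.accuracy == 100.0
        assert rep.specificity == 100.0 and rep.sensitivity == 100.0

    def test_permuted_labels_at_chance(self):
        accs = []
        for rep_i in range(50):
            r = np.random.default_rng(rep_i)
            X = r.standard_normal((20, 3))
            y = r.permutation([0] * 10 + [1] * 10)
            accs.append(crossval_binary(X, y).accuracy)
        mean = np.mean(accs)
        se = np.std(accs, ddof=1) / np.sqrt(len(accs))
        # LOOCV on noise is slightly pessimistic; chance is the upper side
        assert mean < 50.0 + 2 * se + 5.0
        assert mean > 20.0

    def test_subject_duplication_keeps_decisions_on_originals(self, rng):
        X, y = clouds(rng, n_per=8, sep=6.0)
        base = crossval_binary(X, y, SVMConfig()).predictions
        Xd = np.vstack([X, X])
        yd = np.concatenate([y, y])
        dup = crossval_binary(Xd, yd, SVMConfig()).predictions
        assert np.array_equal(dup[: len(y)], base)

    def test_single_class_rejected(self, rng):
        X = rng.standard_normal((6, 2))
        with pytest.raises(ValueError):
            crossval_binary(X, np.zeros(6, dtype=int))

    def test_stratified_kfold_runs(self, rng):
        X, y = clouds(rng)
        rep = crossval_binary(X, y, SVMConfig(cv_scheme="stratified_kfold"))
        assert rep.accuracy == 100.0


class TestCoupling:
    def test_consistent_pairwise_recovered_exactly(self):
        p = np.array([0.5, 0.3, 0.2])
        pw = {(i, j): p[i] / (p[i] + p[j]) for i in range(3) for j in range(i + 1, 3)}
        assert np.allclose(couple_multiclass(pw, 3), p, atol=1e-15)

    def test_uniform_pairwise_gives_uniform(self):
        pw = {(0, 1): 0.5, (0, 2): 0.5, (1, 2): 0.5}
        assert np.allclose(couple_multiclass(pw, 3), 1.0 / 3.0)

    def test_thousand_random_consistent_triples_exact(self):
        rng = np.random.default_rng(0)
        worst = 0.0
        for _ in range(1000):
            p = rng.dirichlet(np.ones(3))
            pw = {
                (i, j): p[i] / (p[i] + p[j])
                for i in range(3)
                for j in range(i + 1, 3)
            }
            worst = max(worst, np.max(np.abs(couple_multiclass(pw, 3) - p)))
        assert worst < 1e-12

    def test_two_class_reduction_is_identity(self):
        for pr in (0.2, 0.5, 0.9):
            post = couple_multiclass({(0, 1): pr}, 2)
            assert post[0] == pytest.approx(pr, abs=1e-15)
            assert post[1] == pytest.approx(1 - pr, abs=1e-15)

    def test_class_relabeling_equivariance(self):
        rng = np.random.default_rng(1)
        p = rng.dirichlet(np.ones(3))
        pw = {(i, j): p[i] / (p[i] + p[j]) for i in range(3) for j in range(i + 1, 3)}
        post = couple_multiclass(pw, 3)
        perm = [2, 0, 1]  # relabel classes
        pw_p = {}
        for (i, j), v in pw.items():
            a, b = perm.index(i), perm.index(j)
            if a < b:
                pw_p[(a, b)] = v
            else:
                pw_p[(b, a)] = 1.0 - v
        post_p = couple_multiclass(pw_p, 3)
        assert np.allclose([post_p[perm.index(k)] for k in range(3)], post, atol=1e-12)

    def test_boundary_probability_clipped_with_warning(self):
        with pytest.warns(RuntimeWarning, match="clipped"):
            post = couple_multiclass({(0, 1): 1.0}, 2)
        assert 0 < post[1] < 1


class TestConfusionMetrics:
    @pytest.mark.parametrize("key", list(THREE_CLASS_CONFUSIONS))
    def test_reference_tables_recompute_to_printed_accuracy(self, key):
        recomputed = recompute_total_accuracy(key)
        printed = THREE_CLASS_CONFUSIONS[key][1]
        assert abs(recomputed - printed) <= 0.01

    @pytest.mark.parametrize("param", list(TWO_CLASS_SCI_VS_AD_EPEN))
    def test_two_class_rates_recombine_to_printed_accuracy(self, param):
        assert recombine_two_class_accuracy(param) == pytest.approx(
            TWO_CLASS_SCI_VS_AD_EPEN[param][0], abs=0.01
        )

    def test_perfect_diagonal_is_hundred(self):
        cm = ConfusionMatrix(np.diag([25, 25]), ["a", "b"])
        assert confusion_metrics(cm).total_accuracy == 100.0

    def test_row_column_permutation_invariance(self, rng):
        counts = rng.integers(0, 20, (3, 3))
        perm = [2, 0, 1]
        base = confusion_metrics(ConfusionMatrix(counts, list("abc"))).total_accuracy
        permuted = confusion_metrics(
            ConfusionMatrix(counts[np.ix_(perm, perm)], list("cab"))
        ).total_accuracy
        assert permuted == pytest.approx(base)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(ConfusionMatrix(np.zeros((2, 2), int), ["a", "b"]))


def _pt_tables(rng, pts, n_feats=5, n_per=12, signal_pt=None, signal_n=None):
    """Per-PT single-band tables; optional planted signal in one PT cell."""
    y = np.array([0] * n_per + [1] * n_per)
    out = {}
    for pt in pts:
        X = rng.standard_normal((2 * n_per, n_feats))
        if pt == signal_pt:
            for k in range(signal_n):
                X[:, k] = y + 0.05 * rng.standard_normal(2 * n_per)
        descs = [FeatureDescriptor("alpha", f"C{j}", "CC", pt) for j in range(n_feats)]
        out[pt] = {"alpha": FeatureTable(X, descs, y)}
    return out


class TestGridSearch:
    def test_planted_best_cell_found(self, rng):
        pts = [0.3, 0.5, 0.7]
        tables = _pt_tables(rng, pts, n_feats=6, signal_pt=0.5, signal_n=4)
        rep = grid_search(
            tables, SVMConfig(), n_features_range=range(3, 6), n_probes=60, seed=0
        )
        assert rep.best["pt"] == 0.5
        assert rep.best["accuracy"] == 100.0

    def test_grid_size_nine_pt_times_eight_n(self, rng):
        pts = [round(0.1 * k, 1) for k in range(1, 10)]
        tables = _pt_tables(rng, pts, n_feats=10, signal_pt=0.5, signal_n=10)
        rep = grid_search(
            tables, SVMConfig(), n_features_range=range(3, 11), n_probes=20, seed=0
        )
        assert len(rep.grid) == 72

    def test_tie_rule_smallest_n_then_smallest_pt(self):
        # identical tables at every PT -> identical accuracies everywhere
        rng = np.random.default_rng(3)
        y = np.array([0] * 10 + [1] * 10)
        X = np.column_stack([y + 0.01 * rng.standard_normal(20) for _ in range(6)])
        pts = [0.3, 0.5]
        tables = {
            pt: {
                "alpha": FeatureTable(
                    X.copy(),
                    [FeatureDescriptor("alpha", f"C{j}", "CC", pt) for j in range(6)],
                    y,
                )
            }
            for pt in pts
        }
        rep = grid_search(
            tables, SVMConfig(), n_features_range=range(3, 6), n_probes=20, seed=0
        )
        assert rep.best["n_features"] == 3
        assert rep.best["pt"] == 0.3

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="empty grid"):
            grid_search({}, SVMConfig())


class TestNestedVsFaithful:
    def test_faithful_leaks_nested_does_not(self):
        # pure-noise features with many candidates: selecting on all data
        # then cross-validating inflates accuracy; nested selection stays at
        # chance
        faithful_accs, nested_accs = [], []
        for rep_i in range(15):
            rng = np.random.default_rng(100 + rep_i)
            y = rng.permutation([0] * 10 + [1] * 10)
            tables = _pt_tables(rng, [0.5], n_feats=40, n_per=10)
            tables[0.5]["alpha"].labels[:] = y
            f = grid_search(
                tables,
                SVMConfig(mode="faithful"),
                n_features_range=[3],
                n_probes=30,
                seed=rep_i,
            )
            n = grid_search(
                tables,
                SVMConfig(mode="nested"),
                n_features_range=[3],
                n_probes=30,
                seed=rep_i,
            )
            faithful_accs.append(f.best["accuracy"])
            nested_accs.append(n.best["accuracy"])
        assert np.mean(faithful_accs) > np.mean(nested_accs)
        assert np.mean(nested_accs) < 62.0  # chance within sampling noise


class TestMulticlass:
    def test_separable_three_clouds_pairwise_coupling(self, rng):
        centers = np.array([[0, 0], [8, 0], [0, 8]])
        X = np.vstack([rng.standard_normal((8, 2)) + c for c in centers])
        y = np.repeat(["SCI", "MCI", "AD"], 8)
        rep = crossval_multiclass(X, y, class_order=["SCI", "MCI", "AD"])
        assert rep.total_accuracy == 100.0
        assert rep.confusion.counts.sum() == 24

    def test_pairwise_feature_sets_variant_matches_on_shared_features(self, rng):
        centers = np.array([[0, 0], [8, 0], [0, 8]])
        X = np.vstack([rng.standard_normal((8, 2)) + c for c in centers])
        y = np.repeat(["SCI", "MCI", "AD"], 8)
        feats = {(i, j): X for i in range(3) for j in range(i + 1, 3)}
        rep = crossval_multiclass_pairwise(feats, y, class_order=["SCI", "MCI", "AD"])
        assert rep.total_accuracy == 100.0
        # rows sum to class sizes
        assert np.array_equal(rep.confusion.counts.sum(axis=1), [8, 8, 8])
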