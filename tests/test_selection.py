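"""OFR ranking and random-probe selection."""

import numpy as np
import pytest

from eegconn.selection import (
    FeatureDescriptor,
    FeatureTable,
    ofr_rank,
    probe_select,
    two_stage_select,
)

# ------------------------------------------------------------- naive oracle


def naive_ofr(X, y):
    """Independent OFR re-implementation with explicit projections.

    At every step each remaining candidate is re-orthogonalized from
    scratch against all previously selected features (classic Gram-Schmidt
    loops, no incremental updates), and the squared correlation with the
    equally re-projected output is maximized.
    """
    X = np.asarray(X, dtype=float)
    X = X - X.mean(axis=0)
    y = np.asarray(y, dtype=float)
    y = y - y.mean()
    p = X.shape[1]
    selected = []
    basis = []  # orthonormal vectors of the selected span
    while len(selected) < p:
        yr = y.copy()
        for b in basis:
            yr = yr - (b @ yr) * b
        if yr @ yr <= 1e-10:
            break
        best, best_score = None, -1.0
        for j in range(p):
            if j in selected:
                continue
            f = X[:, j].copy()
            for b in basis:
                f = f - (b @ f) * b
            nf = np.linalg.norm(f)
            if nf <= 1e-10 * max(np.linalg.norm(X[:, j]), 1.0):
                continue
            score = (f @ yr) ** 2 / (nf**2 * (yr @ yr))
            if score > best_score + 1e-15:
                best, best_score = j, score
        if best is None:
            break
        selected.append(best)
        f = X[:, best].copy()
        for b in basis:
            f = f - (b @ f) * b
        basis.append(f / np.linalg.norm(f))
    return selected


def naive_probe_select(X, y, n_probes, risk, seed):
    """Probe stopping rule driven by the naive OFR; returns n accepted."""
    rng = np.random.default_rng(seed)
    p = X.shape[1]
    ranks = []
    for _ in range(n_probes):
        aug = np.column_stack([X, rng.standard_normal(len(y))])
        order = naive_ofr(aug, y)
        ranks.append(order.index(p) + 1 if p in order else p + 2)
    ranks = np.asarray(ranks)
    order = naive_ofr(X, y)
    n_keep = 0
    for step in range(1, len(order) + 1):
        if np.mean(ranks <= step) < risk:
            n_keep = step
        else:
            break
    return order, n_keep


def make_table(X, y, band="alpha"):
    descs = [FeatureDescriptor(band, f"C{j}", "CC", 0.5) for j in range(X.shape[1])]
    return FeatureTable(X, descs, y)


class TestOFRRank:
    def test_label_copy_ranked_first_with_score_one(self, rng):
        y = np.array([0, 0, 0, 1, 1, 1, 0, 1])
        X = np.column_stack([rng.standard_normal(8), y.astype(float), rng.standard_normal(8)])
        order, scores = ofr_rank(X, y)
        assert order[0] == 1
        assert scores[0] == pytest.approx(1.0)

    def test_orthonormal_design_hand_ranking(self):
        # 4 subjects, orthogonal features; y = 2 f1 + 1 f2 + 0 f3
        f1 = np.array([1.0, 1.0, -1.0, -1.0]) / 2
        f2 = np.array([1.0, -1.0, 1.0, -1.0]) / 2
        f3 = np.array([1.0, -1.0, -1.0, 1.0]) / 2
        y = 2 * f1 + 1 * f2
        order, scores = ofr_rank(np.column_stack([f1, f2, f3]), y)
        assert order == [0, 1]  # f3 never explains residual output
        # hand values: cos^2 with y = coef^2 / sum(coef^2), then 1 for f2
        assert scores[0] == pytest.approx(4.0 / 5.0)
        assert scores[1] == pytest.approx(1.0)

    def test_matches_naive_reimplementation(self, rng):
        for _ in range(10):
            X = rng.standard_normal((15, 8))
            y = rng.integers(0, 2, 15)
            order, _ = ofr_rank(X, y)
            assert order == naive_ofr(X, y)

    def test_positive_rescaling_invariance(self, rng):
        X = rng.standard_normal((12, 6))
        y = rng.integers(0, 2, 12)
        scale = rng.uniform(0.1, 10.0, 6)
        o1, s1 = ofr_rank(X, y)
        o2, s2 = ofr_rank(X * scale, y)
        assert o1 == o2
        assert np.allclose(s1, s2, atol=1e-10)

    def test_first_rank_is_argmax_squared_correlation(self, rng):
        X = rng.standard_normal((20, 10))
        y = rng.integers(0, 2, 20)
        order, _ = ofr_rank(X, y)
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        corr2 = (Xc.T @ yc) ** 2 / (np.sum(Xc**2, axis=0) * (yc @ yc))
        assert order[0] == int(np.argmax(corr2))

    def test_all_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            ofr_rank(np.ones((5, 3)), np.array([0, 1, 0, 1, 0]))

    def test_zero_variance_column_dropped_with_warning(self, rng):
        X = rng.standard_normal((10, 3))
        X[:, 1] = 7.0
        y = rng.integers(0, 2, 10)
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            order, _ = ofr_rank(X, y)
        assert 1 not in order

    def test_duplicate_column_skipped_as_collinear(self, rng):
        x = rng.standard_normal(10)
        X = np.column_stack([x, x, rng.standard_normal(10)])
        y = rng.integers(0, 2, 10)
        order, _ = ofr_rank(X, y)
        assert len(order) == 2  # the duplicate never re-enters


class TestProbeSelect:
    def test_risk_zero_selects_nothing(self, rng):
        X = rng.standard_normal((20, 5))
        y = rng.integers(0, 2, 20)
        res = probe_select(make_table(X, y), n_probes=50, risk=0.0, seed=0)
        assert res.selected == []

    def test_selected_is_prefix_of_ranked(self, rng):
        X = rng.standard_normal((24, 8))
        X[:, 3] += 3.0 * rng.integers(0, 2, 24)
        y = (X[:, 3] > X[:, 3].mean()).astype(int)
        res = probe_select(make_table(X, y), n_probes=100, risk=0.1, seed=1)
        assert res.ranked[: res.n_selected] == res.selected

    def test_deterministic_given_seed(self, rng):
        X = rng.standard_normal((20, 6))
        y = rng.integers(0, 2, 20)
        r1 = probe_select(make_table(X, y), n_probes=60, risk=0.1, seed=5)
        r2 = probe_select(make_table(X, y), n_probes=60, risk=0.1, seed=5)
        assert r1.selected == r2.selected
        assert np.array_equal(r1.probe.ranks, r2.probe.ranks)

    def test_informative_feature_recovered_noise_rate_matches_oracle(self):
        # planted f = label + small noise among 20 pure-noise features; the
        # naive re-implementation provides the Monte Carlo reference for the
        # accepted-noise count under the same stopping rule
        n, p_noise, n_probes, risk = 30, 20, 60, 0.1
        impl_counts, first_ok = [], []
        for rep in range(60):
            r = np.random.default_rng(1000 + rep)
            y = np.array([0] * 15 + [1] * 15)
            f = y + 0.1 * r.standard_normal(n)
            X = np.column_stack([r.standard_normal((n, p_noise)), f])
            res = probe_select(
                make_table(X, y), n_probes=n_probes, risk=risk, seed=rep
            )
            names = [d.electrode for d in res.selected]
            first_ok.append(res.ranked[0].electrode == f"C{p_noise}")
            impl_counts.append(len(res.selected) - (f"C{p_noise}" in names))
        assert all(first_ok)
        oracle_counts = []
        for rep in range(40):
            r = np.random.default_rng(5000 + rep)
            y = np.array([0] * 15 + [1] * 15)
            f = y + 0.1 * r.standard_normal(n)
            X = np.column_stack([r.standard_normal((n, p_noise)), f])
            order, n_keep = naive_probe_select(X, y, n_probes, risk, seed=rep)
            oracle_counts.append(n_keep - (p_noise in order[:n_keep]))
        mi, mo = np.mean(impl_counts), np.mean(oracle_counts)
        se = np.sqrt(
            np.var(impl_counts, ddof=1) / len(impl_counts)
            + np.var(oracle_counts, ddof=1) / len(oracle_counts)
        )
        assert abs(mi - mo) < 2 * se + 0.05
        # at the expected probe-rank distribution the rule admits at most
        # floor(risk * (p_noise + 1)) noise features; allow MC fluctuation
        assert mi <= risk * (p_noise + 1) + 1.0


class TestTwoStage:
    def _band_tables(self, rng, signal_band=None):
        y = np.array([0] * 12 + [1] * 12)
        tables = {}
        for band in ("delta", "theta", "alpha", "beta"):
            X = rng.standard_normal((24, 6))
            if band == signal_band:
                X[:, 2] = y + 0.1 * rng.standard_normal(24)
            tables[band] = make_table(X, y, band)
        return tables, y

    def test_signal_only_in_beta_selected_from_beta(self, rng):
        tables, _ = self._band_tables(rng, signal_band="beta")
        res = two_stage_select(tables, n_probes=80, risk=0.1, seed=0)
        assert res.stage == "fused"
        assert res.n_selected >= 1
        assert all(d.band == "beta" for d in res.selected)

    def test_duplicate_feature_across_bands_kept_once(self, rng):
        y = np.array([0] * 12 + [1] * 12)
        f = y + 0.05 * rng.standard_normal(24)
        tables = {}
        for band in ("alpha", "beta"):
            X = np.column_stack([f, rng.standard_normal((24, 4))])
            tables[band] = make_table(X, y, band)
        res = two_stage_select(tables, n_probes=80, risk=0.1, seed=0)
        informative = [d for d in res.selected if d.electrode == "C0"]
        assert len(informative) == 1

    def test_single_noise_candidate_acceptance_calibrated_to_risk(self):
        # with one pure-noise candidate the probe rule is exactly calibrated:
        # the candidate is accepted iff fewer than `risk` of the probes beat
        # it, which happens with probability ~= risk (probability integral
        # transform of the candidate's correlation)
        accepts = 0
        n_rep = 100
        for rep in range(n_rep):
            rng = np.random.default_rng(700 + rep)
            y = rng.permutation([0] * 10 + [1] * 10)
            X = rng.standard_normal((20, 1))
            res = probe_select(make_table(X, y), n_probes=100, risk=0.1, seed=rep)
            accepts += res.n_selected > 0
        se = np.sqrt(0.1 * 0.9 / n_rep)
        assert abs(accepts / n_rep - 0.1) < 2 * se + 0.02

    def test_pure_noise_single_feature_bands_usually_empty(self):
        # one noise feature per band: each band accepts w.p. ~= risk, so all
        # four stay empty w.p. ~= (1 - risk)^4 ~= 0.656; 2-sigma lower band
        # over 20 replicates gives >= 9 empty fused selections
        empties = 0
        for rep in range(20):
            rng = np.random.default_rng(300 + rep)
            y = rng.permutation([0] * 12 + [1] * 12)
            tables = {
                band: make_table(rng.standard_normal((24, 1)), y, band)
                for band in ("delta", "theta", "alpha", "beta")
            }
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                res = two_stage_select(tables, n_probes=100, risk=0.1, seed=rep)
            empties += res.n_selected == 0
        assert empties >= 9


class TestFeatureTableIO:
    def test_csv_round_trip(self, tmp_path, rng):
        X = rng.standard_normal((6, 3))
        y = np.array([0, 1, 0, 1, 0, 1])
        tab = make_table(X, y)
        p = tmp_path / "t.csv"
        tab.to_csv(p)
        back = FeatureTable.from_csv(p)
        assert np.allclose(back.matrix, X)
        assert np.array_equal(back.labels, y)
        assert back.descriptors == tab.descriptors

    def test_nan_rejected(self):
        with pytest.raises(ValueError, match="NaN"):
            FeatureTable(np.full((4, 2), np.nan), ["a", "b"], np.array([0, 1, 0, 1]))
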