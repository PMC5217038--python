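"""PLS-DA: NIPALS against independent oracles, VIP identities, Q2 and
permutation behavior, Hotelling ellipse geometry."""

import numpy as np
import pytest
from scipy import stats as ss

import stemomics as st
from stemomics.plsda import _nipals_pls1, predict_y
from stemomics.synthetic import TARGETED_PANEL, simulate_metabolome


def eigen_pls1(Xs, yc, n_components):
    """Independent PLS oracle: per component the weight vector is the
    dominant eigenvector of X' y y' X; same deflation."""
    X, y = Xs.copy(), yc.copy()
    W, T = [], []
    for _ in range(n_components):
        M = X.T @ np.outer(y, y) @ X
        vals, vecs = np.linalg.eigh(M)
        w = vecs[:, -1]
        t = X @ w
        tt = t @ t
        p = X.T @ t / tt
        q = y @ t / tt
        X = X - np.outer(t, p)
        y = y - t * q
        W.append(w)
        T.append(t)
    return np.column_stack(W), np.column_stack(T)


def _labels(n):
    return ["P"] * (n // 2) + ["S"] * (n - n // 2)


class TestAutoscale:
    def test_standardized_input_unchanged(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 4))
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        Xs, mu, sigma, kept = st.autoscale(X)
        np.testing.assert_allclose(Xs, X, atol=1e-12)

    def test_hand_arithmetic_column(self):
        Xs, mu, sigma, _ = st.autoscale(np.array([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(Xs[:, 0], [-1.0, 0.0, 1.0], atol=1e-12)
        assert sigma[0] == pytest.approx(1.0)

    def test_inverse_transform_recovers(self):
        rng = np.random.default_rng(1)
        X = rng.normal(5, 3, size=(10, 5))
        Xs, mu, sigma, kept = st.autoscale(X)
        np.testing.assert_allclose(Xs * sigma + mu, X, atol=1e-10)

    def test_constant_feature_excluded(self):
        X = np.column_stack([np.arange(5.0), np.full(5, 2.0)])
        Xs, mu, sigma, kept = st.autoscale(X)
        assert kept.tolist() == [True, False]
        assert Xs.shape == (5, 1)


class TestFit:
    def test_nipals_matches_eigen_oracle(self):
        """Scores agree with the eigendecomposition oracle on 50 random
        10x6 matrices, up to sign, to 1e-6."""
        rng = np.random.default_rng(42)
        for _ in range(50):
            X = rng.normal(size=(10, 6))
            y = np.array([0.0] * 5 + [1.0] * 5)
            Xs, *_ = st.autoscale(X)
            yc = y - y.mean()
            W, P, T, q = _nipals_pls1(Xs, yc, 2)
            Wo, To = eigen_pls1(Xs, yc, 2)
            for a in range(2):
                sign = np.sign(T[:, a] @ To[:, a])
                np.testing.assert_allclose(T[:, a], sign * To[:, a],
                                           atol=1e-6)

    def test_scores_match_sklearn(self):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        rng = np.random.default_rng(7)
        X = rng.normal(size=(12, 8))
        y = np.array([0.0] * 6 + [1.0] * 6)
        model = st.fit_plsda(X, _labels(12), 2)
        sk = sklearn.PLSRegression(n_components=2, scale=True).fit(X, y)
        for a in range(2):
            c = np.corrcoef(model.scores[:, a], sk.x_scores_[:, a])[0, 1]
            assert abs(abs(c) - 1.0) < 1e-8

    def test_score_orthogonality_and_unit_weights(self, demo_dataset):
        dataset, _ = demo_dataset
        norm = st.normalize_to_protein(dataset.metabolome_raw, dataset.sheet)
        m = st.fit_plsda(norm, sheet=dataset.sheet, n_components=3)
        T = m.scores
        for a in range(m.n_components):
            assert np.linalg.norm(m.weights[:, a]) == pytest.approx(1.0)
            for b in range(a + 1, m.n_components):
                assert abs(T[:, a] @ T[:, b]) < 1e-8

    def test_r2_bounds_and_monotonicity(self, demo_dataset):
        dataset, _ = demo_dataset
        norm = st.normalize_to_protein(dataset.metabolome_raw, dataset.sheet)
        r2x, r2y = [], []
        for a in (1, 2, 3):
            m = st.fit_plsda(norm, sheet=dataset.sheet, n_components=a)
            assert 0.0 <= m.R2X <= 1.0 and 0.0 <= m.R2Y <= 1.0
            r2x.append(m.R2X)
            r2y.append(m.R2Y)
        assert r2x == sorted(r2x)
        assert r2y == sorted(r2y)

    def test_perfect_single_feature_r2y_one(self):
        rng = np.random.default_rng(3)
        y = np.array([0.0] * 5 + [1.0] * 5)
        X = np.column_stack([y, rng.normal(size=10)])
        m = st.fit_plsda(X, _labels(10), 1)
        # the single weight vector mixes in a little of the noise feature,
        # so R2Y approaches 1 without reaching it exactly at A = 1
        assert m.R2Y > 0.99
        yhat = predict_y(m, X)
        assert np.all((yhat >= 0.5) == (y == 1))

    def test_refit_bit_identical(self, demo_dataset):
        dataset, _ = demo_dataset
        norm = st.normalize_to_protein(dataset.metabolome_raw, dataset.sheet)
        m1 = st.fit_plsda(norm, sheet=dataset.sheet)
        m2 = st.fit_plsda(norm, sheet=dataset.sheet)
        np.testing.assert_array_equal(m1.weights, m2.weights)
        np.testing.assert_array_equal(m1.scores, m2.scores)

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(6, 3))
        with pytest.raises(ValueError, match="2 classes"):
            st.fit_plsda(X, ["P"] * 6)

    def test_separable_synthetic_groups_classified(self):
        """At the study scale (n = 5 + 5, planted folds) the model
        separates the groups without misclassification in most seeds."""
        hits = 0
        for seed in range(10):
            truth = st.default_truth(seed, n_per_group=5)
            raw, sheet = simulate_metabolome(truth, cv=0.1)
            norm = st.normalize_to_protein(raw, sheet)
            m = st.fit_plsda(norm, sheet=sheet)
            yhat = predict_y(m, norm.values.T)
            y = np.array([m.class_encoding[c] for c in sheet.condition],
                         dtype=float)
            hits += np.all((yhat >= 0.5) == (y == 1))
        assert hits >= 8


class TestQ2:
    def test_loo_equals_nfold(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(12, 6))
        y = _labels(12)
        q_loo = st.cross_validate_q2(X, y, 2, folds=12)
        q_n = st.cross_validate_q2(X, y, 2, folds=len(y))
        assert q_loo == q_n

    def test_null_q2_nonpositive(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(60, 10))
        vals = [st.cross_validate_q2(rng.normal(size=(60, 10)), _labels(60), 2)
                for _ in range(10)]
        assert np.mean(vals) <= 0.05

    def test_predictive_feature_q2_near_one(self):
        rng = np.random.default_rng(9)
        y = np.array([0.0] * 10 + [1.0] * 10)
        X = np.column_stack([y + rng.normal(0, 0.01, 20),
                             rng.normal(size=20)])
        assert st.cross_validate_q2(X, _labels(20), 1) > 0.9


class TestVIP:
    def test_equal_weight_symmetry_gives_unit_vip(self):
        """Single component with equal-magnitude weights: all VIP = 1."""
        rng = np.random.default_rng(4)
        t = rng.normal(size=20)
        signs = np.array([1.0, -1.0, 1.0, -1.0])
        X = np.outer(t, signs) + rng.normal(0, 1e-8, (20, 4))
        y = (t > 0).astype(float)
        m = st.fit_plsda(X, ["S" if v else "P" for v in y], 1)
        np.testing.assert_allclose(st.vip_scores(m), 1.0, atol=1e-4)

    def test_vip_normalization_identity(self, demo_dataset):
        dataset, _ = demo_dataset
        norm = st.normalize_to_protein(dataset.metabolome_raw, dataset.sheet)
        for a in (1, 2, 3):
            m = st.fit_plsda(norm, sheet=dataset.sheet, n_components=a)
            vip = st.vip_scores(m)
            assert (vip ** 2).sum() == pytest.approx(len(m.feature_names),
                                                     abs=1e-8)

    def test_planted_discriminators_rank_high(self):
        """Planted fold-change metabolites occupy the top VIP decile."""
        top_hits = 0
        for seed in range(10):
            truth = st.default_truth(seed, n_per_group=10)
            raw, sheet = simulate_metabolome(truth, cv=0.1)
            norm = st.normalize_to_protein(raw, sheet)
            m = st.fit_plsda(norm, sheet=sheet)
            vip = dict(zip(m.feature_names, st.vip_scores(m)))
            decile = sorted(vip, key=vip.get, reverse=True)[
                :max(4, len(vip) // 10)]
            top_hits += "NAAD+" in decile
        assert top_hits >= 8

    def test_selection_requires_both_criteria(self, demo_dataset):
        dataset, _ = demo_dataset
        norm = st.normalize_to_protein(dataset.metabolome_raw, dataset.sheet)
        stats = st.compare_groups(norm, dataset.sheet)
        m = st.fit_plsda(norm, sheet=dataset.sheet)
        sel = st.select_discriminant(m, stats["p_value"])
        vip = dict(zip(m.feature_names, st.vip_scores(m)))
        for name in sel:
            assert vip[name] > 1.0
            assert stats.loc[name, "p_value"] < 0.05


class TestPermutation:
    def test_separable_data_gives_floor_p(self):
        """Well-separated groups drive the permutation p to its floor.

        At n = 5 + 5 a uniform random permutation occasionally reproduces
        the true labeling (or its complement), and such rounds tie the
        observed Q2, so the attainable p is 1/101 plus those ties."""
        truth = st.default_truth(2, n_per_group=5)
        raw, sheet = simulate_metabolome(truth, cv=0.05)
        norm = st.normalize_to_protein(raw, sheet)
        rec = st.permutation_validate(norm, sheet=sheet, n_perm=100, seed=1)
        assert rec.empirical_p_Q2 <= 5 / 101
        # every permutation at or above the observed Q2 is a relabeling
        # equivalent to the truth, not a genuinely better model
        ties = rec.permuted_Q2[rec.permuted_Q2 >= rec.observed_Q2]
        np.testing.assert_allclose(ties, rec.observed_Q2, atol=1e-9)

    def test_p_formula_invariant(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(10, 8))
        rec = st.permutation_validate(X, _labels(10), 2, n_perm=30, seed=5)
        k = int((rec.permuted_Q2 >= rec.observed_Q2).sum())
        assert rec.empirical_p_Q2 == (1 + k) / (len(rec.permuted_Q2) + 1)

    def test_minimum_rounds_enforced(self):
        X = np.random.default_rng(0).normal(size=(10, 4))
        with pytest.raises(ValueError, match="n_perm"):
            st.permutation_validate(X, _labels(10), 2, n_perm=5)


class TestHotellingEllipse:
    def test_alpha_to_one_degenerates(self):
        rng = np.random.default_rng(0)
        t1, t2 = rng.normal(size=20), rng.normal(size=20)
        a, b = st.hotelling_ellipse(t1, t2, alpha=1 - 1e-12)
        assert a < 1e-4 and b < 1e-4

    def test_scale_equivariance(self):
        rng = np.random.default_rng(1)
        t1, t2 = rng.normal(size=15), rng.normal(size=15)
        a1, b1 = st.hotelling_ellipse(t1, t2)
        a2, b2 = st.hotelling_ellipse(2 * t1, 2 * t2)
        assert a2 == pytest.approx(2 * a1) and b2 == pytest.approx(2 * b1)

    def test_coverage_near_95_percent(self):
        """~95% (+-2%) of bivariate-normal scores fall inside the ellipse."""
        rng = np.random.default_rng(12)
        inside = []
        for _ in range(200):
            t1 = rng.normal(size=50)
            t2 = rng.normal(size=50)
            a, b = st.hotelling_ellipse(t1, t2, alpha=0.05)
            inside.append(((t1 / a) ** 2 + (t2 / b) ** 2 <= 1).mean())
        assert abs(np.mean(inside) - 0.95) < 0.02

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            st.hotelling_ellipse([1.0, 2.0], [0.0, 1.0])
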