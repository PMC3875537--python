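"""OPLS-DA fitting, prediction, cross-validation and CV-ANOVA."""

import numpy as np
import pytest

from conftest import centered_random, make_matrix
from helpers import nipals_pls1
from moplsda import (DegenerateModelError, DummyResponse, FoldCompositionError,
                     RankError, cross_validate, cv_anova, dummy_response,
                     fit_opls, fit_opls_da, predict, select_n_ortho)


def binary_y(pattern):
    return DummyResponse(values=np.asarray(pattern, dtype=float),
                         positive_class="pos")


def make_two_class(rng, n1=10, n0=10, n_genes=30, n_markers=6, effect=2.0,
                   noise=0.3):
    """Centered X with a planted mean shift on the first genes."""
    y = np.array([1.0] * n1 + [0.0] * n0)
    X = rng.normal(scale=noise, size=(n1 + n0, n_genes))
    X[:n1, :n_markers] += effect
    X = X - X.mean(axis=0)
    return X, binary_y(y)


class TestDummyResponse:
    def test_requires_two_binary_classes(self):
        with pytest.raises(ValueError):
            binary_y([1, 1, 1, 1])
        with pytest.raises(ValueError):
            binary_y([0, 1, 2, 1])
        with pytest.raises(ValueError, match=">= 2 samples"):
            binary_y([1, 0, 0, 0])

    def test_coding_from_labels(self):
        y = dummy_response(["a", "b", "a", "b"], positive_class="b")
        assert y.values.tolist() == [0.0, 1.0, 0.0, 1.0]
        with pytest.raises(ValueError):
            dummy_response(["a", "b"], positive_class="c")


class TestFitOpls:
    def test_perfect_predictor_column(self, rng):
        y = binary_y([1, 1, 1, 0, 0, 0])
        X = np.zeros((6, 5))
        X[:, 2] = y.centered
        model = fit_opls(X, y, n_ortho=0)
        assert abs(model.r2y - 1.0) < 1e-10
        assert abs(abs(model.w[2]) - 1.0) < 1e-10

    def test_orthogonal_response_degenerate(self):
        # every column orthogonal to centered y
        y = binary_y([1, 1, 0, 0])
        X = np.array([[1.0, 2.0], [-1.0, -2.0], [1.0, 2.0], [-1.0, -2.0]])
        X = X - X.mean(axis=0)
        with pytest.raises(DegenerateModelError):
            fit_opls(X, y, n_ortho=0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_zero_ortho_equals_pls1_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = centered_random(rng, 10, 8)
        y = binary_y([1, 0] * 5)
        model = fit_opls(X, y, n_ortho=0)
        t_ref, w_ref, p_ref, b_ref, r2y_ref = nipals_pls1(X, y.centered)
        sign = np.sign(t_ref @ model.t)
        np.testing.assert_allclose(model.t, sign * t_ref, atol=1e-8)
        np.testing.assert_allclose(model.w, sign * w_ref, atol=1e-8)
        assert abs(model.r2y - r2y_ref) < 1e-8

    def test_zero_ortho_matches_sklearn_first_component(self, rng):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X = centered_random(rng, 12, 7)
        y = binary_y([1, 0] * 6)
        model = fit_opls(X, y, n_ortho=0)
        pls = sklearn.PLSRegression(n_components=1, scale=False).fit(
            X, y.centered)
        t_sk = pls.x_scores_[:, 0]
        sign = np.sign(t_sk @ model.t)
        np.testing.assert_allclose(model.t, sign * t_sk, atol=1e-8)

    @pytest.mark.parametrize("n_ortho", [1, 2, 3])
    def test_orthogonality_invariants(self, n_ortho, rng):
        for _ in range(10):
            X = centered_random(rng, 12, 9)
            y = binary_y(rng.permutation([1] * 6 + [0] * 6))
            model = fit_opls(X, y, n_ortho=n_ortho)
            assert abs(np.linalg.norm(model.w) - 1) < 1e-10
            yc = y.centered
            for k in range(n_ortho):
                w_o, t_o = model.W_o[:, k], model.T_o[:, k]
                assert abs(np.linalg.norm(w_o) - 1) < 1e-10
                cos_t = abs(model.t @ t_o) / (np.linalg.norm(model.t)
                                              * np.linalg.norm(t_o))
                assert cos_t < 1e-8
                cos_y = abs(t_o @ yc) / (np.linalg.norm(t_o) * np.linalg.norm(yc))
                assert cos_y < 1e-8
            assert 0 <= model.r2x <= 1
            assert 0 <= model.r2y <= 1

    def test_positive_class_has_positive_mean_score(self, rng):
        X, y = make_two_class(rng)
        model = fit_opls(X, y, n_ortho=1)
        assert model.t[y.values == 1].mean() > 0
        assert model.b > 0

    def test_coding_swap_flips_scores_keeps_r2y(self, rng):
        X, y = make_two_class(rng)
        m1 = fit_opls(X, y, n_ortho=1)
        y_swapped = DummyResponse(values=1.0 - y.values, positive_class="neg")
        m2 = fit_opls(X, y_swapped, n_ortho=1)
        assert abs(m1.r2y - m2.r2y) < 1e-10
        np.testing.assert_allclose(m1.t, -m2.t, atol=1e-8)
        np.testing.assert_allclose(m1.w, -m2.w, atol=1e-8)

    @pytest.mark.parametrize("n_ortho", [0, 1, 2])
    def test_x_variance_decomposition(self, n_ortho, rng):
        X, y = make_two_class(rng, n_genes=20)
        model = fit_opls(X, y, n_ortho=n_ortho)
        reconstructed = np.outer(model.t, model.p)
        for k in range(n_ortho):
            reconstructed = reconstructed + np.outer(model.T_o[:, k], model.P_o[:, k])
        resid = X - reconstructed
        total = np.sum(X * X)
        assert abs(model.r2x + np.sum(resid * resid) / total - 1.0) < 1e-8

    def test_rank_errors(self, rng):
        X, y = make_two_class(rng, n1=3, n0=3, n_genes=4)
        with pytest.raises(RankError):
            fit_opls(X, y, n_ortho=4)
        # rank-1 matrix aligned with y leaves nothing orthogonal to extract
        yy = binary_y([1, 1, 1, 0, 0, 0])
        X1 = np.outer(yy.centered, np.ones(5))
        with pytest.raises(RankError):
            fit_opls(X1, yy, n_ortho=1)

    def test_requires_centered_x(self, rng):
        X = rng.normal(loc=5.0, size=(8, 6))
        with pytest.raises(ValueError, match="centered"):
            fit_opls(X, binary_y([1, 0] * 4), n_ortho=0)


class TestPredict:
    def test_training_self_consistency(self, rng):
        X, y = make_two_class(rng)
        model = fit_opls(X, y, n_ortho=2)
        y_hat, t_new = predict(model, X)
        ss = np.sum((y.values - y.values.mean()) ** 2)
        r2 = 1 - np.sum((y.values - y_hat) ** 2) / ss
        assert abs(r2 - model.r2y) < 1e-10
        np.testing.assert_allclose(t_new, model.t, atol=1e-10)

    def test_duplicated_sample_identical_prediction(self, rng):
        X, y = make_two_class(rng)
        model = fit_opls(X, y, n_ortho=1)
        dup = np.vstack([X[0], X[0]])
        y_hat, _ = predict(model, dup)
        assert y_hat[0] == y_hat[1]

    def test_held_out_sample_correct_side(self, rng):
        X = rng.normal(scale=0.3, size=(21, 30))
        X[:10, :6] += 2.0  # strong effect for the first 10 samples
        y_full = np.array([1.0] * 10 + [0.0] * 11)
        means = X[:-1].mean(axis=0)
        model = fit_opls(X[:-1] - means, binary_y(y_full[:-1]), n_ortho=0,
                         x_means=means)
        y_hat, _ = predict(model, X[-1])
        assert y_hat[0] < 0.5  # held-out sample belongs to the 0 class

    def test_gene_mismatch_raises(self, rng):
        X, y = make_two_class(rng, n_genes=10)
        model = fit_opls(X, y, n_ortho=0, gene_ids=[f"g{i}" for i in range(10)])
        with pytest.raises(KeyError):
            predict(model, np.zeros((2, 7)))
        with pytest.raises(KeyError):
            predict(model, np.zeros((2, 10)),
                    gene_ids=[f"h{i}" for i in range(10)])


class TestCrossValidate:
    def test_hand_accumulated_folds_match_exactly(self, rng):
        # 12-sample fixture; accumulate PRESS fold by fold with explicit refits
        X, y = make_two_class(rng, n1=6, n0=6, n_genes=8, effect=1.0)
        n_folds = 4
        res = cross_validate(X, y, n_ortho=1, n_folds=n_folds)
        press = 0.0
        folds = np.arange(12) % n_folds
        for f in range(n_folds):
            tr, te = folds != f, folds == f
            mu = X[tr].mean(axis=0)
            sub = fit_opls(X[tr] - mu, binary_y(y.values[tr]), n_ortho=1,
                           x_means=mu)
            y_hat, _ = predict(sub, X[te])
            press += float(np.sum((y.values[te] - y_hat) ** 2))
        ss = float(np.sum((y.values - y.values.mean()) ** 2))
        assert res.press == press
        assert res.ss == ss
        assert res.q2y == 1.0 - press / ss

    def test_strong_effect_q2_near_one(self, rng):
        X, y = make_two_class(rng, n1=12, n0=12, n_genes=40, n_markers=10,
                              effect=3.0, noise=0.2)
        res = cross_validate(X, y, n_ortho=0, n_folds=7)
        assert res.q2y > 0.9

    def test_permutation_null_q2_not_positive(self, rng):
        X = centered_random(rng, 21, 40)
        q2s = []
        for _ in range(20):
            y_perm = rng.permutation([1.0] * 10 + [0.0] * 11)
            try:
                q2s.append(cross_validate(X, binary_y(y_perm), n_ortho=0,
                                          n_folds=7).q2y)
            except FoldCompositionError:
                continue
        assert np.mean(q2s) < 0.1

    def test_single_class_fold_error(self):
        y = binary_y([1, 0, 1, 0, 1, 0, 1, 0])
        X = centered_random(np.random.default_rng(0), 8, 5)
        with pytest.raises(FoldCompositionError):
            cross_validate(X, y, n_ortho=0, n_folds=2)  # venetian blinds split by parity

    def test_schemes_are_deterministic(self, rng):
        X, y = make_two_class(rng, n1=8, n0=8, n_genes=10)
        a = cross_validate(X, y, n_ortho=1, scheme="venetian_blind")
        b = cross_validate(X, y, n_ortho=1, scheme="venetian_blind")
        assert a.q2y == b.q2y
        c = cross_validate(X, y, n_ortho=1, scheme="random", seed=5)
        d = cross_validate(X, y, n_ortho=1, scheme="random", seed=5)
        assert c.q2y == d.q2y


class TestSelectNOrtho:
    def test_single_latent_direction_returns_zero(self, rng):
        y = binary_y([1, 0] * 7)
        u = rng.normal(size=20)
        X = np.outer(y.centered, u) + rng.normal(scale=0.01, size=(14, 20))
        X -= X.mean(axis=0)
        assert select_n_ortho(X, y, max_ortho=3) == 0

    def test_structured_confounder_needs_at_least_one(self, rng):
        # a strong within-class direction sharing genes with the class effect
        y = binary_y([1, 0] * 7)
        conf = rng.normal(size=14)
        conf -= conf.mean()
        conf -= (conf @ y.centered) / (y.centered @ y.centered) * y.centered
        u = np.zeros(20); u[:8] = 1.0
        v = np.zeros(20); v[4:12] = 1.0  # overlapping loadings
        X = (np.outer(y.centered, u) + 3.0 * np.outer(conf, v)
             + rng.normal(scale=0.05, size=(14, 20)))
        X -= X.mean(axis=0)
        assert select_n_ortho(X, y, max_ortho=3) >= 1

    def test_max_ortho_zero(self, rng):
        X, y = make_two_class(rng, n1=6, n0=6, n_genes=10)
        assert select_n_ortho(X, y, max_ortho=0) == 0


class TestCvAnova:
    def test_press_equals_ss_gives_f_zero_p_one(self, rng):
        X, y = make_two_class(rng, n1=6, n0=6, n_genes=8)
        res = cross_validate(X, y, n_ortho=0)
        res.press = res.ss
        f, p = cv_anova(res, n_samples=12, n_components=1)
        assert f == 0.0 and p == 1.0

    def test_tiny_press_limit(self, rng):
        X, y = make_two_class(rng, n1=6, n0=6, n_genes=8)
        res = cross_validate(X, y, n_ortho=0)
        res.press = res.ss * 1e-6
        f, p = cv_anova(res, n_samples=38, n_components=3)
        assert p < 1e-6

    def test_negative_f_maps_to_p_one(self, rng):
        X, y = make_two_class(rng, n1=6, n0=6, n_genes=8)
        res = cross_validate(X, y, n_ortho=0)
        res.press = res.ss * 2
        f, p = cv_anova(res, n_samples=12, n_components=1)
        assert f < 0 and p == 1.0

    def test_insufficient_samples(self, rng):
        X, y = make_two_class(rng, n1=6, n0=6, n_genes=8)
        res = cross_validate(X, y, n_ortho=0)
        with pytest.raises(ValueError, match="insufficient"):
            cv_anova(res, n_samples=4, n_components=3)

    def test_strong_effect_significant(self, rng):
        X, y = make_two_class(rng, n1=12, n0=12, n_genes=40, n_markers=10,
                              effect=2.0, noise=0.3)
        res = cross_validate(X, y, n_ortho=0, n_folds=7)
        _, p = cv_anova(res, n_samples=24, n_components=1)
        assert p < 0.001


class TestFitOplsDa:
    def test_matrix_level_fit_reports_cv(self, rng):
        vals = rng.normal(3.0, 0.3, size=(30, 16))
        vals[:6, :8] += 1.0  # markers up in the first class
        labels = ["A"] * 8 + ["B"] * 8
        m = make_matrix(vals, state="log10", labels=labels)
        model = fit_opls_da(m, "A", n_ortho=0)
        assert model.q2y is not None and model.q2y > 0.5
        assert model.positive_class == "A"
        assert model.gene_ids == m.gene_ids
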