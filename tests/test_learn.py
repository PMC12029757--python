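import itertools

import numpy as np
import pytest

import breathgate as bg
from breathgate.learn import (
    _cv_accuracy,
    LDAPipeline,
    _BareSVM,
    metrics_from_confusion,
    svm_decision_values,
)


# --------------------------------------------------------------------------
# independent oracles
# --------------------------------------------------------------------------

def scatter_matrices(X, y):
    """S_w and S_b straight from their definitions."""
    classes = sorted(set(y))
    mu = X.mean(axis=0)
    d = X.shape[1]
    s_w, s_b = np.zeros((d, d)), np.zeros((d, d))
    for cls in classes:
        xc = X[np.asarray(y) == cls]
        mu_j = xc.mean(axis=0)
        s_w += (xc - mu_j).T @ (xc - mu_j)
        s_b += len(xc) * np.outer(mu_j - mu, mu_j - mu)
    return s_w, s_b


def generalized_eig_2x2(B, W):
    """Closed-form eigenpairs of B v = lambda W v for 2x2 matrices.

    Solves det(B - lambda W) = 0 by the quadratic formula and recovers each
    eigenvector from the nullspace of (B - lambda W) — no shared code with
    the fitted path.
    """
    a = np.linalg.det(W)
    b = -(B[0, 0] * W[1, 1] + B[1, 1] * W[0, 0]
          - B[0, 1] * W[1, 0] - B[1, 0] * W[0, 1])
    c = np.linalg.det(B)
    disc = np.sqrt(b * b - 4 * a * c)
    lams = sorted([(-b + disc) / (2 * a), (-b - disc) / (2 * a)], reverse=True)
    vecs = []
    for lam in lams:
        M = B - lam * W
        v = np.array([-M[0, 1], M[0, 0]])
        if np.allclose(v, 0):
            v = np.array([-M[1, 1], M[1, 0]])
        v = v / np.linalg.norm(v)
        if v[np.argmax(np.abs(v))] < 0:
            v = -v
        vecs.append(v)
    return np.array(lams), np.column_stack(vecs)


def svm_dual_active_set(X, y, C, gamma):
    """Exact soft-margin RBF-SVM dual by exhaustive active-set enumeration.

    Every assignment of each alpha_i to {0, C, free} is tried; free alphas
    and the bias solve the KKT linear system, and the KKT inequalities are
    checked.  Returns (alpha, b) of the best feasible solution.  Exponential
    in n — usable only for tiny problems, which is the point of an oracle.
    """
    n = len(y)
    K = np.exp(-gamma * ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    y = np.asarray(y, dtype=float)
    best_obj, best = -np.inf, None
    for pattern in itertools.product((0, 1, 2), repeat=n):
        free = [i for i in range(n) if pattern[i] == 2]
        at_c = [i for i in range(n) if pattern[i] == 1]
        if not free:
            continue
        m = len(free)
        A = np.zeros((m + 1, m + 1))
        rhs = np.zeros(m + 1)
        for r, i in enumerate(free):
            A[r, :m] = y[i] * y[free] * K[i, free]
            A[r, m] = y[i]
            rhs[r] = 1.0 - C * y[i] * (y[at_c] * K[i, at_c]).sum()
        A[m, :m] = y[free]
        rhs[m] = -C * y[at_c].sum()
        try:
            sol = np.linalg.solve(A, rhs)
        except np.linalg.LinAlgError:
            continue
        alpha = np.zeros(n)
        alpha[free] = sol[:m]
        alpha[at_c] = C
        b = sol[m]
        if np.any(alpha[free] < -1e-9) or np.any(alpha[free] > C + 1e-9):
            continue
        margins = y * ((alpha * y) @ K + b)
        ok = all(margins[i] >= 1 - 1e-7 for i in range(n) if pattern[i] == 0)
        ok = ok and all(margins[i] <= 1 + 1e-7 for i in at_c)
        if not ok:
            continue
        obj = alpha.sum() - 0.5 * ((alpha * y) @ K @ (alpha * y))
        if obj > best_obj:
            best_obj, best = obj, (alpha, b)
    return best


# --------------------------------------------------------------------------
# LDA
# --------------------------------------------------------------------------

class TestLDA:
    def make_data(self, seed=0, n=90, d=50):
        rng = np.random.default_rng(seed)
        means = rng.normal(0, 2, (3, d))
        X = np.vstack([rng.normal(means[k], 1.0, (n // 3, d)) for k in range(3)])
        y = np.repeat(["a", "b", "c"], n // 3)
        return X, y

    def test_projection_is_two_dimensional(self):
        X, y = self.make_data()
        model = bg.lda_fit(X, y)
        assert model.projection.shape == (50, 2)
        assert bg.lda_transform(model, X).shape == (len(y), 2)

    def test_equal_class_means_give_null_eigenvalues(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, (120, 5))
        y = np.repeat(["a", "b", "c"], 40)
        X = X - np.vstack([X[y == c].mean(0) for c in y])  # equalize means
        model = bg.lda_fit(X, y)
        assert np.all(model.eigenvalues < 1e-10)

    def test_single_class_rejected(self):
        X = np.random.default_rng(2).normal(size=(10, 3))
        with pytest.raises(ValueError):
            bg.lda_fit(X, np.repeat("a", 10))

    def test_2d_worked_example_matches_closed_form_eigensolve(self):
        """Eigenpairs of the 2x2 generalized problem match the quadratic
        formula oracle to 1e-8 (regularization included on both sides)."""
        rng = np.random.default_rng(3)
        X = np.vstack([
            rng.normal([0, 0], 0.5, (8, 2)),
            rng.normal([3, 0], 0.5, (8, 2)),
            rng.normal([0, 2], 0.5, (8, 2)),
        ])
        y = np.repeat(["a", "b", "c"], 8)
        model = bg.lda_fit(X, y, shrinkage=1e-2)
        s_w, s_b = scatter_matrices(X, y)
        eps = 1e-2 * np.trace(s_w) / 2
        lams, vecs = generalized_eig_2x2(s_b, s_w + eps * np.eye(2))
        assert np.allclose(model.eigenvalues, lams, atol=1e-8)
        assert np.allclose(model.projection, vecs, atol=1e-8)

    def test_transform_is_matrix_product(self):
        X, y = self.make_data(seed=4, n=30, d=6)
        model = bg.lda_fit(X, y)
        Z = bg.lda_transform(model, X)
        assert np.allclose(Z, X @ model.projection)
        assert np.allclose(bg.lda_transform(model, np.zeros((1, 6))), 0.0)

    def test_transform_of_basis_vector(self):
        X, y = self.make_data(seed=5, n=30, d=6)
        model = bg.lda_fit(X, y)
        w1 = model.projection[:, 0]
        out = bg.lda_transform(model, w1[None, :])
        assert out[0, 0] == pytest.approx(1.0, abs=1e-12)
        assert out[0, 1] == pytest.approx(float(model.projection[:, 1] @ w1))

    def test_dimension_mismatch_rejected(self):
        X, y = self.make_data(seed=6, n=30, d=6)
        model = bg.lda_fit(X, y)
        with pytest.raises(ValueError):
            bg.lda_transform(model, np.zeros((2, 7)))


# --------------------------------------------------------------------------
# SVM
# --------------------------------------------------------------------------

class TestSVM:
    def test_three_classes_give_three_machines(self):
        rng = np.random.default_rng(7)
        X = rng.normal(0, 1, (30, 2))
        y = np.repeat(["a", "b", "c"], 10)
        model = bg.svm_train(X, y, c=1.0, gamma=1.0)
        assert len(model.machines) == 3

    def test_separable_clusters_fit_perfectly(self):
        rng = np.random.default_rng(8)
        centers = np.array([[0, 0], [10, 0], [0, 10]])
        X = np.vstack([rng.normal(c, 0.3, (10, 2)) for c in centers])
        y = np.repeat(["a", "b", "c"], 10)
        model = bg.svm_train(X, y, c=100.0, gamma=0.5)
        assert np.all(bg.svm_predict(model, X) == y)

    def test_six_point_toy_matches_active_set_oracle(self):
        """Decision values of a 6-point binary problem agree with the
        exhaustively enumerated KKT solution within 1e-4."""
        X = np.array([[0.0, 0.0], [1.0, 0.5], [0.5, 1.0],
                      [2.0, 2.0], [2.5, 1.5], [1.5, 2.5]])
        y = np.array(["neg", "neg", "neg", "pos", "pos", "pos"])
        C, gamma = 1.0, 0.5
        model = bg.svm_train(X, y, c=C, gamma=gamma)
        alpha, b = svm_dual_active_set(X, np.where(y == "neg", -1.0, 1.0), C, gamma)
        queries = np.array([[0.5, 0.5], [2.0, 1.8], [1.2, 1.2], [0.0, 2.0]])
        Kq = np.exp(-gamma * ((queries[:, None] - X[None]) ** 2).sum(-1))
        oracle_dec = Kq @ (alpha * np.where(y == "neg", -1.0, 1.0)) + b
        got_dec = svm_decision_values(model, queries)[0]
        assert np.allclose(got_dec, oracle_dec, atol=1e-4)

    def test_invalid_hyperparameters_rejected(self):
        X = np.zeros((4, 2))
        y = np.array(["a", "a", "b", "b"])
        with pytest.raises(ValueError):
            bg.svm_train(X, y, c=0.0, gamma=1.0)
        with pytest.raises(ValueError):
            bg.svm_train(X, y, c=1.0, gamma=-1.0)


# --------------------------------------------------------------------------
# GA
# --------------------------------------------------------------------------

def small_instance(seed=0, n=60):
    rng = np.random.default_rng(seed)
    centers = np.array([[0, 0], [2.0, 0.5], [0.5, 2.0]])
    X = np.vstack([rng.normal(c, 0.8, (n // 3, 2)) for c in centers])
    y = np.repeat(["a", "b", "c"], n // 3)
    return X, y


class TestGA:
    def test_fitness_matches_independent_cv(self):
        X, y = small_instance()
        config = bg.GAConfig(seed=3, cv_folds=5)
        from sklearn.model_selection import StratifiedKFold

        c, g = 2.0, 0.5
        skf = StratifiedKFold(5, shuffle=True, random_state=config.seed)
        correct = 0
        for tr, te in skf.split(X, y):
            m = bg.svm_train(X[tr], y[tr], c, g)
            correct += int((bg.svm_predict(m, X[te]) == y[te]).sum())
        expected = correct / len(y)
        got = _cv_accuracy(lambda: _BareSVM(c, g), X, y, 5, config.seed)
        assert got == pytest.approx(expected)

    def test_history_non_decreasing_and_deterministic(self):
        X, y = small_instance()
        config = bg.GAConfig(population_size=8, generations=5, seed=11)
        c1, g1, h1 = bg.ga_optimize(X, y, config)
        c2, g2, h2 = bg.ga_optimize(X, y, config)
        assert (c1, g1, h1) == (c2, g2, h2)
        assert all(b >= a for a, b in zip(h1, h1[1:]))

    def test_range_containing_good_pair_is_not_lost(self):
        """With the search range collapsed around a known-good pair and
        mutation off, elitism keeps fitness at least that pair's fitness."""
        X, y = small_instance()
        c0, g0 = 10.0, 0.5
        config = bg.GAConfig(
            population_size=4, generations=3, mutation_prob=0.0,
            c_range=(c0 * 0.999, c0 * 1.001), gamma_range=(g0 * 0.999, g0 * 1.001),
            seed=5,
        )
        baseline = _cv_accuracy(lambda: _BareSVM(c0, g0), X, y, 5, config.seed)
        _, _, history = bg.ga_optimize(X, y, config)
        assert history[-1] >= baseline - 1e-9

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError):
            bg.ga_optimize(np.empty((0, 2)), np.array([]), bg.GAConfig())


# --------------------------------------------------------------------------
# KNN / RF / PCA
# --------------------------------------------------------------------------

class TestKNN:
    def test_query_on_training_point(self):
        X = np.array([[0.0, 0.0], [5.0, 5.0]])
        y = np.array(["a", "b"])
        assert bg.knn_classify(X, y, [0.0, 0.0], k=1) == "a"

    def test_three_four_five_distance_ordering(self):
        X = np.array([[3.0, 4.0], [0.0, 6.0]])  # distances 5 and 6 from origin
        y = np.array(["near", "far"])
        assert bg.knn_classify(X, y, [0.0, 0.0], k=1) == "near"

    def test_matches_brute_force_sort_oracle(self):
        rng = np.random.default_rng(12)
        X = rng.normal(0, 1, (40, 3))
        y = rng.choice(["a", "b", "c"], 40)
        queries = rng.normal(0, 1, (15, 3))
        for q in queries:
            d = np.array([np.sqrt(((x - q) ** 2).sum()) for x in X])
            order = sorted(range(40), key=lambda i: (d[i], i))[:5]
            labels, counts = np.unique(y[order], return_counts=True)
            top = labels[counts == counts.max()]
            if len(top) == 1:
                expected = top[0]
            else:
                expected = min(top, key=lambda l: d[[i for i in order if y[i] == l]].mean())
            assert bg.knn_classify(X, y, q, k=5) == expected

    def test_k_out_of_range_rejected(self):
        X = np.zeros((3, 2))
        y = np.array(["a", "b", "a"])
        with pytest.raises(ValueError):
            bg.knn_classify(X, y, [0, 0], k=4)
        with pytest.raises(ValueError):
            bg.knn_classify(X, y, [0, 0], k=0)


class TestRF:
    def test_pure_training_set_predicts_that_class(self):
        X = np.random.default_rng(13).normal(0, 1, (20, 2))
        y = np.repeat("only", 20)
        assert bg.rf_classify(X, y, [0.0, 0.0], n_trees=5, seed=1) == "only"

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(14)
        X = rng.normal(0, 1, (30, 2))
        y = np.repeat(["a", "b", "c"], 10)
        q = [0.1, -0.2]
        assert bg.rf_classify(X, y, q, seed=3) == bg.rf_classify(X, y, q, seed=3)

    def test_single_tree_forest(self):
        X, y = small_instance(seed=15)
        pred = bg.rf_classify(X, y, [0.0, 0.0], n_trees=1, seed=0)
        assert pred in set(y)

    def test_invalid_tree_count(self):
        with pytest.raises(ValueError):
            bg.rf_classify(np.zeros((2, 2)), ["a", "b"], [0, 0], n_trees=0)


class TestPCA:
    def test_three_components_capture_planted_subspace(self):
        rng = np.random.default_rng(16)
        basis = np.linalg.qr(rng.normal(size=(50, 3)))[0]
        X = rng.normal(0, 1, (80, 3)) @ basis.T
        scores, ev = bg.pca_reduce(X, 3)
        assert scores.shape == (80, 3)
        assert ev.sum() == pytest.approx(1.0, abs=1e-9)

    def test_components_match_covariance_eigensolve(self):
        rng = np.random.default_rng(17)
        X = rng.normal(0, 1, (60, 5)) @ np.diag([3.0, 2.0, 1.0, 0.5, 0.1])
        scores, _ = bg.pca_reduce(X, 3)
        Xc = X - X.mean(0)
        evals, evecs = np.linalg.eigh(Xc.T @ Xc / (len(X) - 1))
        V = evecs[:, np.argsort(evals)[::-1][:3]]
        oracle = Xc @ V
        for k in range(3):  # components defined up to sign
            assert np.allclose(scores[:, k], oracle[:, k], atol=1e-8) or np.allclose(
                scores[:, k], -oracle[:, k], atol=1e-8
            )

    def test_invalid_component_count(self):
        with pytest.raises(ValueError):
            bg.pca_reduce(np.zeros((4, 3)), 5)


# --------------------------------------------------------------------------
# cross-validation and metrics
# --------------------------------------------------------------------------

class TestCrossValidate:
    def test_label_lookup_classifier_scores_perfectly(self):
        """With unique rows, a classifier that looks labels up by row value
        must score 100% — checks the aggregation plumbing."""
        rng = np.random.default_rng(18)
        X = rng.normal(0, 1, (30, 4))
        y = np.array([f"c{i % 3}" for i in range(30)])
        lookup = {tuple(row): lbl for row, lbl in zip(X, y)}

        class Oracle:
            def fit(self, X, y):
                return self

            def predict(self, Q):
                return np.array([lookup[tuple(q)] for q in Q])

        report = bg.cross_validate(Oracle, X, y, folds=5, seed=0)
        assert report.accuracy == 1.0
        assert np.all(np.diag(report.confusion.to_numpy()) == [10, 10, 10])
        assert np.allclose(report.per_class["f1"], 1.0)

    def test_metrics_match_hand_computed_confusion(self):
        conf = np.array([[8, 1, 1], [2, 6, 2], [0, 1, 9]])
        m = metrics_from_confusion(conf, ["p", "g", "e"])
        assert m.loc["p", "recall"] == pytest.approx(8 / 10)
        assert m.loc["p", "precision"] == pytest.approx(8 / 10)
        assert m.loc["g", "recall"] == pytest.approx(6 / 10)
        assert m.loc["g", "precision"] == pytest.approx(6 / 8)
        f1 = 2 * (6 / 10) * (6 / 8) / ((6 / 10) + (6 / 8))
        assert m.loc["g", "f1"] == pytest.approx(f1)
        assert m.loc["e", "f1"] == pytest.approx(2 * 0.9 * 0.75 / (0.9 + 0.75))

    def test_training_fit_ignores_test_row_order(self):
        """Permuting held-out rows permutes predictions identically: the
        fitted fold model is independent of the test fold."""
        X, y = small_instance(seed=19)
        model = LDAPipeline("svm", c=1.0, gamma=1.0).fit(X[:45], y[:45])
        test = X[45:]
        perm = np.random.default_rng(20).permutation(len(test))
        direct = model.predict(test)
        permuted = model.predict(test[perm])
        assert np.all(permuted == direct[perm])

    def test_class_smaller_than_folds_rejected(self):
        X = np.zeros((7, 2))
        y = np.array(["a", "a", "a", "a", "a", "b", "b"])
        with pytest.raises(ValueError):
            bg.cross_validate(lambda: _BareSVM(1, 1), X, y, folds=5, seed=0)

    def test_hyperparameter_comparison_harness(self):
        """The fixed reference (c, gamma) pairs and the GA's choice are all
        scored on the same folds, one row each."""
        X, y = small_instance(seed=21, n=45)
        table = bg.hyperparameter_comparison(X, y, (5.0, 0.5), folds=3, seed=1)
        assert len(table) == 6
        assert list(table["source"]).count("ga") == 1
        assert table["accuracy"].between(0, 1).all()

    def test_confusion_rows_sum_to_class_counts(self, cohort_features):
        X, y = cohort_features
        report = bg.cross_validate(
            lambda: LDAPipeline("knn"), X, y, folds=5, seed=0
        )
        counts = report.confusion.sum(axis=1)
        for cls in counts.index:
            assert counts[cls] == (y == cls).sum()
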