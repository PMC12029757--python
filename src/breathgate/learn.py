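"""Classification stack: scatter-matrix LDA, one-vs-one RBF-SVM with GA
hyperparameter search, KNN, random forest, PCA baseline, and stratified
five-fold cross-validation.

The 50-dimensional feature vectors are first reduced to 2 dimensions with
Fisher LDA: with within-class scatter S_w = sum_j sum_{x in C_j}
(x - mu_j)(x - mu_j)^T and between-class scatter S_b = sum_j N_j
(mu_j - mu)(mu_j - mu)^T, the projection directions solve the generalized
eigenproblem S_b w = lambda S_w w and the two leading eigenvectors are kept
(two directions suffice for three classes).  S_w is ridge-regularized,
S_w + eps I with eps = shrinkage * tr(S_w)/d (default shrinkage 1e-2):
per-fold sample counts near the feature dimension and the strong collinearity
of the per-channel features make S_w ill-conditioned, and a vanishing ridge
overfits the discriminant directions; 1e-2 is of the same order as the
Ledoit-Wolf shrinkage these tables select.

The reduced data feed a soft-margin RBF SVM (one binary machine per class
pair, n(n-1)/2 machines, majority vote with ties broken by summed decision
values), a KNN classifier, or a random forest.  SVM hyperparameters (cost c,
kernel width gamma) are tuned by a seeded genetic algorithm whose fitness is
stratified k-fold cross-validated accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.linalg
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

__all__ = [
    "LDAModel",
    "SVMModel",
    "GAConfig",
    "EvaluationReport",
    "lda_fit",
    "lda_transform",
    "svm_train",
    "svm_predict",
    "ga_optimize",
    "grid_search",
    "knn_classify",
    "rf_classify",
    "pca_reduce",
    "cross_validate",
    "LDAPipeline",
    "hyperparameter_comparison",
    "REFERENCE_HYPERPARAMS",
]

#: Fixed (c, gamma) pairs used as the untuned baseline in the comparison
#: harness, spanning the same log range the GA searches.
REFERENCE_HYPERPARAMS = ((0.01, 1.0), (0.1, 1.0), (1.0, 1.0), (1.0, 10.0), (10.0, 100.0))


# --------------------------------------------------------------------------
# LDA
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LDAModel:
    """Fisher discriminant projection fitted from scatter matrices."""

    projection: np.ndarray  # (d, 2), columns are unit-norm w1, w2
    class_means: dict
    grand_mean: np.ndarray
    eigenvalues: np.ndarray  # descending, non-negative (clipped at 0)
    classes: tuple


def lda_fit(
    X: np.ndarray, y: np.ndarray, n_components: int = 2, shrinkage: float = 1e-2
) -> LDAModel:
    """Fit LDA by solving the generalized eigenproblem S_b w = lambda S_w w.

    Keeps the ``n_components`` leading eigenvectors, unit-normalized with the
    sign convention that each direction's largest-magnitude component is
    positive.  S_w is regularized as S_w + eps I with
    eps = ``shrinkage`` * tr(S_w)/d, so a singular or ill-conditioned
    within-class scatter never aborts or destabilizes the fit; pass a tiny
    ``shrinkage`` to recover the unregularized eigenproblem on
    well-conditioned data.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = tuple(pd.unique(y))
    if len(classes) < 2:
        raise ValueError("LDA needs at least two classes")
    d = X.shape[1]
    mu = X.mean(axis=0)
    s_w = np.zeros((d, d))
    s_b = np.zeros((d, d))
    class_means = {}
    for cls in classes:
        xc = X[y == cls]
        mu_j = xc.mean(axis=0)
        class_means[cls] = mu_j
        dev = xc - mu_j
        s_w += dev.T @ dev
        diff = (mu_j - mu)[:, None]
        s_b += xc.shape[0] * (diff @ diff.T)
    eps = shrinkage * np.trace(s_w) / d
    if eps <= 0:
        eps = 1e-12
    s_w_reg = s_w + eps * np.eye(d)
    eigvals, eigvecs = scipy.linalg.eigh(s_b, s_w_reg)
    order = np.argsort(eigvals)[::-1][:n_components]
    w = eigvecs[:, order]
    lam = np.clip(eigvals[order], 0.0, None)
    w = w / np.linalg.norm(w, axis=0, keepdims=True)
    for k in range(w.shape[1]):  # sign convention: dominant component positive
        if w[np.argmax(np.abs(w[:, k])), k] < 0:
            w[:, k] = -w[:, k]
    return LDAModel(
        projection=w,
        class_means=class_means,
        grand_mean=mu,
        eigenvalues=lam,
        classes=classes,
    )


def lda_transform(model: LDAModel, X: np.ndarray) -> np.ndarray:
    """Project rows onto the fitted discriminant directions: y_i = W^T x_i."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.projection.shape[0]:
        raise ValueError(
            f"X has {X.shape[1]} columns, model was fitted on "
            f"{model.projection.shape[0]}"
        )
    return X @ model.projection


# --------------------------------------------------------------------------
# One-vs-one soft-margin RBF SVM
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SVMModel:
    """One-vs-one multiclass RBF-SVM: one binary machine per class pair.

    Each pairwise machine stores its support vectors, dual coefficients
    alpha_i y_i, and bias; prediction is by majority vote over the pairwise
    decisions, ties broken by the summed signed decision values.
    """

    machines: tuple  # ((cls_a, cls_b, fitted SVC), ...)
    classes: tuple
    c: float
    gamma: float


def svm_train(X: np.ndarray, y: np.ndarray, c: float, gamma: float) -> SVMModel:
    """Train the one-vs-one soft-margin RBF SVM.

    For k classes, k(k-1)/2 binary machines are trained, each on the samples
    of its two classes only.  Each binary subproblem is solved by the SMO
    dual optimizer (decision function sum_i alpha_i y_i K(x_i, x) + b with
    the Gaussian kernel K(u, v) = exp(-gamma ||u - v||^2) and 0 <= alpha_i <= c).
    """
    if c <= 0 or gamma <= 0:
        raise ValueError("c and gamma must be positive")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = tuple(pd.unique(y))
    if any((y == cls).sum() < 1 for cls in classes):
        raise ValueError("every class needs at least one sample")
    machines = []
    for i in range(len(classes)):
        for j in range(i + 1, len(classes)):
            a, b = classes[i], classes[j]
            mask = (y == a) | (y == b)
            yy = np.where(y[mask] == a, -1, 1)
            clf = SVC(kernel="rbf", C=c, gamma=gamma, tol=1e-8)
            clf.fit(X[mask], yy)
            machines.append((a, b, clf))
    return SVMModel(machines=tuple(machines), classes=classes, c=c, gamma=gamma)


def svm_decision_values(model: SVMModel, X: np.ndarray) -> list[np.ndarray]:
    """Signed decision value of each pairwise machine (positive -> class b)."""
    X = np.asarray(X, dtype=float)
    return [clf.decision_function(X) for _, _, clf in model.machines]


def svm_predict(model: SVMModel, X: np.ndarray) -> np.ndarray:
    """Majority vote over pairwise machines; ties by summed decision values."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    idx = {cls: k for k, cls in enumerate(model.classes)}
    votes = np.zeros((n, len(model.classes)))
    scores = np.zeros((n, len(model.classes)))
    for (a, b, clf) in model.machines:
        d = clf.decision_function(X)  # > 0 -> b
        winner_b = d > 0
        votes[winner_b, idx[b]] += 1
        votes[~winner_b, idx[a]] += 1
        scores[:, idx[b]] += d
        scores[:, idx[a]] -= d
    out = np.empty(n, dtype=object)
    for i in range(n):
        top = votes[i] == votes[i].max()
        if top.sum() == 1:
            out[i] = model.classes[int(np.argmax(votes[i]))]
        else:  # vote tie: largest summed decision value among the tied classes
            tied = np.where(top)[0]
            out[i] = model.classes[int(tied[np.argmax(scores[i, tied])])]
    return np.array(list(out))


# --------------------------------------------------------------------------
# Estimator pipelines (LDA reduction + classifier)
# --------------------------------------------------------------------------

class LDAPipeline:
    """LDA dimensionality reduction followed by a classifier.

    ``classifier`` is one of ``"svm"``, ``"knn"``, ``"rf"``; hyperparameters
    are passed through (``c``/``gamma`` for SVM, ``k`` for KNN, ``n_trees``
    and ``seed`` for RF).  The projected scores are standardized (per-axis
    z-scores fitted on the training data) before the classifier, because the
    unit-norm discriminant directions leave the score scale tied to the raw
    feature units, which a fixed-range RBF kernel cannot absorb.  Fitting
    happens entirely on the data given to :meth:`fit`, so using one instance
    per CV fold is leakage-free.
    """

    def __init__(self, classifier: str = "svm", c: float = 1.0, gamma: float = 1.0,
                 k: int = 5, n_trees: int = 100, seed: int = 0,
                 n_components: int = 2):
        if classifier not in {"svm", "knn", "rf"}:
            raise ValueError(f"unknown classifier {classifier!r}")
        self.classifier = classifier
        self.c, self.gamma, self.k, self.n_trees = c, gamma, k, n_trees
        self.seed, self.n_components = seed, n_components
        self._lda = None
        self._model = None
        self._train = None

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self._lda = lda_fit(X, y, self.n_components)
        Z = lda_transform(self._lda, X)
        self._center = Z.mean(axis=0)
        self._scale = np.where(Z.std(axis=0) > 0, Z.std(axis=0), 1.0)
        Z = (Z - self._center) / self._scale
        if self.classifier == "svm":
            self._model = svm_train(Z, y, self.c, self.gamma)
        elif self.classifier == "rf":
            self._model = RandomForestClassifier(
                n_estimators=self.n_trees, random_state=self.seed
            ).fit(Z, y)
        else:
            self._train = (Z, y)
        return self

    def predict(self, X):
        Z = lda_transform(self._lda, np.asarray(X, dtype=float))
        Z = (Z - self._center) / self._scale
        if self.classifier == "svm":
            return svm_predict(self._model, Z)
        if self.classifier == "rf":
            return self._model.predict(Z)
        train_X, train_y = self._train
        return np.array([knn_classify(train_X, train_y, q, self.k) for q in Z])


# --------------------------------------------------------------------------
# Genetic algorithm for (c, gamma)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm settings for the (c, gamma) search.

    Genes live on the log10 scale over ``c_range`` x ``gamma_range``;
    fitness is stratified ``cv_folds``-fold CV accuracy.  Elitism keeps the
    best individual each generation, so the best-fitness history is
    non-decreasing.
    """

    population_size: int = 20
    generations: int = 50
    c_range: tuple[float, float] = (1e-2, 1e2)
    gamma_range: tuple[float, float] = (1e-2, 1e2)
    crossover_prob: float = 0.8
    mutation_prob: float = 0.1
    mutation_sd: float = 0.3  # log10 units
    tournament_size: int = 3
    elitism: int = 1
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be at least 2")
        for lo, hi in (self.c_range, self.gamma_range):
            if not (0 < lo < hi):
                raise ValueError("ranges must be positive and increasing")
        for p in (self.crossover_prob, self.mutation_prob):
            if not (0 <= p <= 1):
                raise ValueError("probabilities must lie in [0, 1]")


def _cv_accuracy(pipeline_factory, X, y, folds: int, seed: int) -> float:
    """Stratified k-fold CV accuracy of a freshly built pipeline per fold."""
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    correct = 0
    for train_idx, test_idx in skf.split(X, y):
        model = pipeline_factory().fit(X[train_idx], y[train_idx])
        correct += int((model.predict(X[test_idx]) == y[test_idx]).sum())
    return correct / len(y)


class _BareSVM:
    """svm_train/svm_predict wrapped with the fit/predict interface."""

    def __init__(self, c, gamma):
        self.c, self.gamma, self._model = c, gamma, None

    def fit(self, X, y):
        self._model = svm_train(X, y, self.c, self.gamma)
        return self

    def predict(self, X):
        return svm_predict(self._model, X)


def ga_optimize(
    X: np.ndarray,
    y: np.ndarray,
    config: GAConfig,
    pipeline_factory=None,
) -> tuple[float, float, list[float]]:
    """Tune (c, gamma) with a seeded genetic algorithm.

    ``pipeline_factory(c, gamma)`` builds the estimator whose stratified
    ``config.cv_folds``-fold CV accuracy is the fitness; the default trains
    the bare one-vs-one SVM on ``X`` directly.  Evolution uses tournament
    selection, arithmetic (blend) crossover and Gaussian log-scale mutation,
    with elitism.  Returns (best c, best gamma, per-generation best fitness);
    the history is non-decreasing.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.size == 0 or y.size == 0:
        raise ValueError("empty training data")
    if pipeline_factory is None:
        pipeline_factory = lambda c, g: _BareSVM(c, g)
    rng = np.random.default_rng(config.seed)
    lo = np.log10([config.c_range[0], config.gamma_range[0]])
    hi = np.log10([config.c_range[1], config.gamma_range[1]])
    cache: dict[tuple[float, float], float] = {}

    def fitness(gene: np.ndarray) -> float:
        key = (round(float(gene[0]), 6), round(float(gene[1]), 6))
        if key not in cache:
            c, g = 10.0 ** gene
            cache[key] = _cv_accuracy(
                lambda: pipeline_factory(c, g), X, y, config.cv_folds, config.seed
            )
        return cache[key]

    pop = rng.uniform(lo, hi, size=(config.population_size, 2))
    fits = np.array([fitness(g) for g in pop])
    history = [float(fits.max())]
    for _ in range(config.generations):
        elite_idx = np.argsort(fits)[::-1][: config.elitism]
        new_pop = [pop[i].copy() for i in elite_idx]
        while len(new_pop) < config.population_size:
            parents = []
            for _ in range(2):  # tournament selection
                contenders = rng.integers(0, config.population_size, config.tournament_size)
                parents.append(pop[contenders[np.argmax(fits[contenders])]])
            child = parents[0].copy()
            if rng.random() < config.crossover_prob:  # arithmetic blend
                u = rng.random()
                child = u * parents[0] + (1 - u) * parents[1]
            for k in range(2):  # log-scale Gaussian mutation, clipped to range
                if rng.random() < config.mutation_prob:
                    child[k] += rng.normal(0.0, config.mutation_sd)
            new_pop.append(np.clip(child, lo, hi))
        pop = np.array(new_pop)
        fits = np.array([fitness(g) for g in pop])
        history.append(max(history[-1], float(fits.max())))
    best_gene = pop[int(np.argmax(fits))]
    # with elitism the final population contains the best-ever individual
    best_c, best_gamma = 10.0 ** best_gene
    return float(best_c), float(best_gamma), history


def grid_search(
    X: np.ndarray,
    y: np.ndarray,
    config: GAConfig,
    grid_points: int = 13,
    pipeline_factory=None,
) -> tuple[float, float, float]:
    """Exhaustive log-grid search over the GA's (c, gamma) ranges.

    The independent baseline for the GA: returns (best c, best gamma, best
    CV accuracy) over a ``grid_points`` x ``grid_points`` log10 grid using
    the same fitness (same folds, same seed).
    """
    if pipeline_factory is None:
        pipeline_factory = lambda c, g: _BareSVM(c, g)
    cs = np.logspace(*np.log10(config.c_range), grid_points)
    gs = np.logspace(*np.log10(config.gamma_range), grid_points)
    best = (-1.0, None, None)
    for c in cs:
        for g in gs:
            acc = _cv_accuracy(lambda: pipeline_factory(c, g), X, y,
                               config.cv_folds, config.seed)
            if acc > best[0]:
                best = (acc, c, g)
    return float(best[1]), float(best[2]), float(best[0])


# --------------------------------------------------------------------------
# KNN / RF / PCA
# --------------------------------------------------------------------------

def knn_classify(train_X: np.ndarray, train_y: np.ndarray, query: np.ndarray,
                 k: int = 5):
    """Majority label among the k Euclidean-nearest training points.

    Distance ties are broken by training-set order (stable sort); vote ties
    by the smallest mean distance among the tied classes.
    """
    train_X = np.asarray(train_X, dtype=float)
    train_y = np.asarray(train_y)
    if not (1 <= k <= len(train_y)):
        raise ValueError(f"k={k} outside [1, {len(train_y)}]")
    dist = np.sqrt(((train_X - np.asarray(query, dtype=float)) ** 2).sum(axis=1))
    nearest = np.argsort(dist, kind="stable")[:k]
    labels, counts = np.unique(train_y[nearest], return_counts=True)
    top = labels[counts == counts.max()]
    if len(top) == 1:
        return top[0]
    mean_d = [dist[nearest][train_y[nearest] == lbl].mean() for lbl in top]
    return top[int(np.argmin(mean_d))]


def rf_classify(train_X, train_y, query, n_trees: int = 100, seed: int = 0):
    """Majority vote over a seeded bootstrap forest for a single query point."""
    if n_trees < 1:
        raise ValueError("n_trees must be at least 1")
    clf = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    clf.fit(np.asarray(train_X, dtype=float), np.asarray(train_y))
    return clf.predict(np.atleast_2d(np.asarray(query, dtype=float)))[0]


def pca_reduce(X: np.ndarray, n_components: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """PCA baseline: project onto the leading principal components.

    Returns (scores with ``n_components`` columns, explained-variance ratio).
    """
    X = np.asarray(X, dtype=float)
    if not (1 <= n_components <= min(X.shape)):
        raise ValueError(f"n_components={n_components} invalid for shape {X.shape}")
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(X)
    return scores, pca.explained_variance_ratio_


# --------------------------------------------------------------------------
# Cross-validation and metrics
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class EvaluationReport:
    """Cross-validated performance in the standard multi-class layout."""

    accuracy: float
    per_class: pd.DataFrame  # index: class; columns: recall, precision, f1, support
    confusion: pd.DataFrame  # rows: true class, columns: predicted
    fold_assignments: np.ndarray
    seed: int

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "per_class": {
                str(cls): {m: float(v) for m, v in row.items()}
                for cls, row in self.per_class.iterrows()
            },
            "confusion": self.confusion.to_dict(),
            "seed": self.seed,
        }

    def render(self) -> str:
        """Plain-text metrics table: one row per class plus overall accuracy."""
        lines = [f"{'class':<12}{'recall':>9}{'precision':>11}{'F1':>9}{'n':>6}"]
        for cls, row in self.per_class.iterrows():
            lines.append(
                f"{str(cls):<12}{row['recall']:>8.1%}{row['precision']:>10.1%}"
                f"{row['f1']:>8.1%}{int(row['support']):>6d}"
            )
        lines.append(f"overall accuracy: {self.accuracy:.1%}")
        return "\n".join(lines)


def metrics_from_confusion(conf: np.ndarray, classes) -> pd.DataFrame:
    """Per-class recall, precision and F1 from a confusion matrix.

    Rows of ``conf`` are true classes, columns predicted.  Zero denominators
    yield 0 (a class never predicted has precision 0 by convention).
    """
    conf = np.asarray(conf, dtype=float)
    tp = np.diag(conf)
    recall = np.divide(tp, conf.sum(axis=1), out=np.zeros_like(tp),
                       where=conf.sum(axis=1) > 0)
    precision = np.divide(tp, conf.sum(axis=0), out=np.zeros_like(tp),
                          where=conf.sum(axis=0) > 0)
    denom = recall + precision
    f1 = np.divide(2 * recall * precision, denom, out=np.zeros_like(tp),
                   where=denom > 0)
    return pd.DataFrame(
        {"recall": recall, "precision": precision, "f1": f1,
         "support": conf.sum(axis=1)},
        index=list(classes),
    )


def cross_validate(
    pipeline_factory,
    X: np.ndarray,
    y: np.ndarray,
    folds: int = 5,
    seed: int = 0,
) -> EvaluationReport:
    """Stratified k-fold cross-validation with leakage-free per-fold fits.

    ``pipeline_factory()`` must return a fresh estimator with fit/predict
    (e.g. ``lambda: LDAPipeline("svm", c=..., gamma=...)``); both the
    reducer and the classifier are fitted on training folds only.

    Raises
    ------
    ValueError
        If any class has fewer members than ``folds``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if folds < 2:
        raise ValueError("folds must be at least 2")
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ValueError(
            f"smallest class has {counts.min()} members, fewer than {folds} folds"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    y_pred = np.empty(len(y), dtype=y.dtype if y.dtype != object else object)
    fold_of = np.empty(len(y), dtype=int)
    for fold, (train_idx, test_idx) in enumerate(skf.split(X, y)):
        model = pipeline_factory().fit(X[train_idx], y[train_idx])
        y_pred[test_idx] = model.predict(X[test_idx])
        fold_of[test_idx] = fold
    conf = confusion_matrix(y, y_pred, labels=classes)
    per_class = metrics_from_confusion(conf, classes)
    return EvaluationReport(
        accuracy=float((y_pred == y).mean()),
        per_class=per_class,
        confusion=pd.DataFrame(conf, index=list(classes), columns=list(classes)),
        fold_assignments=fold_of,
        seed=seed,
    )


def hyperparameter_comparison(
    X: np.ndarray,
    y: np.ndarray,
    ga_result: tuple[float, float],
    folds: int = 5,
    seed: int = 0,
    pairs=REFERENCE_HYPERPARAMS,
) -> pd.DataFrame:
    """CV accuracy of fixed reference (c, gamma) pairs vs the GA's choice.

    All rows are evaluated on the same stratified folds with the LDA-SVM
    pipeline, so the comparison isolates the hyperparameters.
    """
    rows = []
    for c, g in [*pairs, ga_result]:
        rep = cross_validate(
            lambda: LDAPipeline("svm", c=c, gamma=g), X, y, folds, seed
        )
        rows.append({"c": c, "gamma": g, "accuracy": rep.accuracy,
                     "source": "ga" if (c, g) == tuple(ga_result) else "reference"})
    return pd.DataFrame(rows)
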