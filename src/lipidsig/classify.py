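"""Linear-discriminant diagnostic scoring and the cross-validation grid.

The diagnostic score is Gaussian LDA with a shared within-class
covariance.  Writing mu0/mu1 for the class means, Sigma for the pooled
covariance and pi0/pi1 for the priors,

    alpha   = Sigma^-1 (mu1 - mu0)
    alpha_0 = -1/2 (mu1 + mu0)' Sigma^-1 (mu1 - mu0) + log(pi1 / pi0)

the linear discriminant ``sum_k alpha_k x_k + alpha_0`` is the posterior
log-odds of the positive (cancer) class, and the reported score is its
logistic transform — a probability in [0, 1].  A sample is called positive
iff its score is strictly greater than 0.5.

Panel size and algorithm are chosen on a grid: nested panel prefixes of
sizes 2..50 crossed with candidate classifiers, each cell evaluated by
stratified 10-fold cross-validation repeated 10 times, with per-fold
re-standardization.  The best cell maximises mean accuracy, ties broken by
the smaller panel, then by a fixed algorithm order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier

from .datatypes import ProcessedMatrix

__all__ = [
    "LdaModel",
    "fit_lda",
    "predict_score",
    "ClassifierSpec",
    "default_classifiers",
    "CvGrid",
    "cross_validate_grid",
    "select_best",
    "ALGORITHM_ORDER",
]

#: Fixed tie-break order for algorithms in :func:`select_best`.
ALGORITHM_ORDER = ("lda", "qda", "knn", "enet")


def _as_xy(X, y) -> tuple[np.ndarray, np.ndarray, list[str]]:
    if isinstance(X, ProcessedMatrix):
        cols = list(map(str, X.feature_ids))
        X = X.values.to_numpy(dtype=float)
    elif isinstance(X, pd.DataFrame):
        cols = list(map(str, X.columns))
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        cols = [f"x{i}" for i in range(X.shape[1])]
    return X, np.asarray(y), cols


@dataclass
class LdaModel:
    """Fitted LDA diagnostic model on a lipid panel."""

    feature_ids: list[str]
    alpha: np.ndarray          # log-odds coefficients
    alpha0: float              # log-odds intercept
    means: np.ndarray          # (2, K) class means, row 1 = positive class
    covariance: np.ndarray     # pooled within-class covariance (after ridge)
    priors: np.ndarray
    classes: np.ndarray
    threshold: float = 0.5
    ridge: float = 0.0

    def predict_proba(self, X) -> np.ndarray:
        s, _ = predict_score(self, X)
        return np.column_stack([1 - s, s])


def fit_lda(X, y, positive=None, ridge: str | float = "auto") -> LdaModel:
    """Fit Gaussian LDA with a pooled covariance.

    *positive* names the class treated as the score-1 end (default: the
    larger of the two sorted labels).  If the pooled covariance is
    ill-conditioned (or ``ridge`` is a number), a ridge term
    ``1e-6 * trace(Sigma)/K * I`` is added before inversion.
    """
    Xa, yv, cols = _as_xy(X, y)
    classes = np.unique(yv)
    if classes.size != 2:
        raise ValueError("LDA needs exactly two classes")
    if positive is not None:
        classes = np.array([c for c in classes if c != positive] + [positive])
    n, k = Xa.shape
    m0 = Xa[yv == classes[0]].mean(axis=0)
    m1 = Xa[yv == classes[1]].mean(axis=0)
    n0 = int((yv == classes[0]).sum())
    n1 = int((yv == classes[1]).sum())
    d0 = Xa[yv == classes[0]] - m0
    d1 = Xa[yv == classes[1]] - m1
    cov = (d0.T @ d0 + d1.T @ d1) / (n - 2)
    cov = np.atleast_2d(cov)
    lam = 0.0
    if ridge == "auto":
        if np.linalg.cond(cov) > 1e10:
            lam = 1e-6 * np.trace(cov) / k
    else:
        lam = float(ridge)
    if lam:
        cov = cov + lam * np.eye(k)
    try:
        alpha = np.linalg.solve(cov, m1 - m0)
    except np.linalg.LinAlgError as err:
        raise FloatingPointError(
            f"singular pooled covariance (cond={np.linalg.cond(cov):.2e})"
        ) from err
    priors = np.array([n0, n1]) / n
    alpha0 = -0.5 * (m1 + m0) @ alpha + np.log(priors[1] / priors[0])
    return LdaModel(
        cols, alpha, float(alpha0), np.vstack([m0, m1]), cov, priors,
        classes, ridge=lam,
    )


def predict_score(model: LdaModel, X) -> tuple[np.ndarray, np.ndarray]:
    """Posterior score in [0, 1] and the thresholded class labels.

    The score is ``logistic(alpha'x + alpha_0)``; a sample is assigned the
    positive class iff its score is strictly greater than the threshold, so
    a score of exactly 0.5 is called negative.
    """
    if isinstance(X, ProcessedMatrix):
        X = X.values
    if isinstance(X, pd.DataFrame):
        missing = [f for f in model.feature_ids if f not in X.columns]
        if missing:
            raise KeyError(f"panel features missing from input: {missing[:5]}")
        X = X[model.feature_ids]
    Xa = np.asarray(X, dtype=float)
    if Xa.ndim == 1:
        Xa = Xa[:, None]
    lin = Xa @ model.alpha + model.alpha0
    with np.errstate(over="ignore"):
        score = 1.0 / (1.0 + np.exp(-lin))
    labels = np.where(score > model.threshold, model.classes[1], model.classes[0])
    return score, labels


# ---------------------------------------------------------------------
# classifier registry for the grid search

@dataclass
class ClassifierSpec:
    """A pluggable classifier: name + factory returning a fit/predict_proba
    estimator.  Hyperparameter tuning (if any) happens inside the factory's
    estimator, i.e. within each training fold."""

    name: str
    make: Callable[[int], object]


class _LdaEstimator:
    """sklearn-style wrapper around :func:`fit_lda`."""

    def __init__(self):
        self._model = None

    def fit(self, X, y):
        self._model = fit_lda(X, y)
        return self

    def predict(self, X):
        return predict_score(self._model, X)[1]

    def predict_proba(self, X):
        s = predict_score(self._model, X)[0]
        return np.column_stack([1 - s, s])


def default_classifiers(seed: int = 0) -> list[ClassifierSpec]:
    """The four natively supported algorithms.

    Additional algorithms plug in as extra :class:`ClassifierSpec` entries
    (any estimator with ``fit``/``predict``).
    """
    def knn(seed):
        return GridSearchCV(
            KNeighborsClassifier(),
            {"n_neighbors": [3, 5, 7, 9]},
            cv=3,
            n_jobs=1,
        )

    def enet(seed):
        return GridSearchCV(
            LogisticRegression(
                solver="saga", l1_ratio=0.5, max_iter=5000, tol=1e-4,
            ),
            {"C": [0.01, 0.1, 1.0, 10.0]},
            cv=3,
            n_jobs=1,
        )

    return [
        ClassifierSpec("lda", lambda seed: _LdaEstimator()),
        ClassifierSpec("qda", lambda seed: QuadraticDiscriminantAnalysis(
            reg_param=1e-4)),
        ClassifierSpec("knn", knn),
        ClassifierSpec("enet", enet),
    ]


# ---------------------------------------------------------------------
# cross-validation grid

@dataclass
class CvGrid:
    """Mean/SD accuracy per (algorithm, panel size) cell."""

    table: pd.DataFrame  # index (algorithm, size); columns mean_acc, sd_acc
    k: int
    repeats: int
    seed: int
    panel_order: list[str] = field(default_factory=list)
    #: per repeat, the test-fold index assigned to each sample
    fold_assignments: list[np.ndarray] = field(default_factory=list)

    def cell(self, algorithm: str, size: int) -> pd.Series:
        return self.table.loc[(algorithm, size)]


def cross_validate_grid(
    X,
    y,
    panel_order: Sequence[str],
    sizes: Sequence[int] = tuple(range(2, 51)),
    classifiers: list[ClassifierSpec] | None = None,
    k: int = 10,
    repeats: int = 10,
    seed: int = 0,
) -> CvGrid:
    """Evaluate nested panel prefixes x algorithms by repeated stratified CV.

    *panel_order* is the decorrelated ranking; each size ``s`` uses its
    first ``s`` features, so panels are nested.  Within each fold the
    training portion is re-standardized and the parameters applied to the
    held-out portion.  Deterministic for a fixed seed.
    """
    if classifiers is None:
        classifiers = [c for c in default_classifiers(seed) if c.name == "lda"]
    if isinstance(X, ProcessedMatrix):
        X = X.values
    X = pd.DataFrame(X)
    yv = np.asarray(y)
    n = len(X)
    if n < k:
        raise ValueError("fewer samples than folds")
    sizes = [s for s in sizes if s <= len(panel_order)]
    Xp = X[list(panel_order)].to_numpy(dtype=float)

    acc: dict[tuple[str, int], list[float]] = {
        (c.name, s): [] for c in classifiers for s in sizes
    }
    rng = np.random.default_rng(seed)
    fold_assignments = []
    for rep in range(repeats):
        skf = StratifiedKFold(
            n_splits=k, shuffle=True, random_state=int(rng.integers(2**31))
        )
        folds = np.empty(n, dtype=int)
        for f, (tr, te) in enumerate(skf.split(Xp, yv)):
            folds[te] = f
        fold_assignments.append(folds)
        for tr, te in skf.split(Xp, yv):
            if len(np.unique(yv[tr])) < 2:  # pathological stratum; refold
                continue
            mu = Xp[tr].mean(axis=0)
            sd = Xp[tr].std(axis=0, ddof=1)
            sd[sd == 0] = 1.0
            Ztr = (Xp[tr] - mu) / sd
            Zte = (Xp[te] - mu) / sd
            for spec in classifiers:
                for s in sizes:
                    est = spec.make(seed)
                    est.fit(Ztr[:, :s], yv[tr])
                    pred = est.predict(Zte[:, :s])
                    acc[(spec.name, s)].append(float(np.mean(pred == yv[te])))
    rows = []
    for (name, s), vals in acc.items():
        rows.append(
            {
                "algorithm": name,
                "size": s,
                "mean_acc": float(np.mean(vals)),
                "sd_acc": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
            }
        )
    table = pd.DataFrame(rows).set_index(["algorithm", "size"]).sort_index()
    return CvGrid(table, k, repeats, seed, list(panel_order), fold_assignments)


def select_best(grid: CvGrid) -> tuple[str, int]:
    """Best (algorithm, panel size) by mean CV accuracy.

    Ties break toward the smaller panel, then the fixed
    :data:`ALGORITHM_ORDER`.
    """
    if grid.table.empty:
        raise ValueError("empty CV grid")

    def algo_rank(name: str) -> int:
        return (
            ALGORITHM_ORDER.index(name)
            if name in ALGORITHM_ORDER
            else len(ALGORITHM_ORDER)
        )

    best = min(
        grid.table.itertuples(),
        key=lambda r: (-r.mean_acc, r.Index[1], algo_rank(r.Index[0])),
    )
    return best.Index[0], int(best.Index[1])
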