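"""Survival machinery for prognostic subtyping.

Covers the survival side of the prognostic pipeline: a fast univariable
Cox proportional-hazards screen over all lipids (one continuous covariate
at a time, Efron tie handling, vectorized Newton iterations across
features), Kaplan-Meier curves with the log-rank test, multivariable Cox
fits (via lifelines), and the elastic-net penalized logistic subtype
predictor,

    min_{b0,b} (1/N) sum_i w_i * l(y_i, b0 + b'x_i)
               + lambda * [ (1 - a) ||b||_2^2 / 2 + a ||b||_1 ],

with the binomial negative log-likelihood l, mixing parameter a in [0, 1]
(a = 1 lasso, a = 0 ridge) and lambda chosen by cross-validated deviance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedKFold

from .datatypes import ProcessedMatrix
from .panel import spearman_matrix, stepwise_decorrelate

__all__ = [
    "CoxScreenResult",
    "univariate_cox_screen",
    "cox_univariate_batch",
    "KmFit",
    "km_logrank",
    "cox_multivariable",
    "SubtypePredictor",
    "fit_subtype_predictor",
    "predict_subtype",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------
# univariable Cox screen

def cox_univariate_batch(
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    max_iter: int = 25,
    tol: float = 1e-9,
) -> pd.DataFrame:
    """Single-covariate Cox PH fits for every column of X at once.

    Newton-Raphson on the Efron partial likelihood, vectorized across
    features (each feature is an independent one-parameter problem sharing
    the same risk-set structure).  Returns per-feature ``coef``, ``hr``,
    ``se``, ``p``, and ``converged``.
    """
    X = np.asarray(X, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    n, F = X.shape
    order = np.argsort(time, kind="stable")
    t, e, Xs = time[order], event[order], X[order]

    # death-tie groups: unique event times and member slices
    death_mask = e == 1
    uniq_times = np.unique(t[death_mask])
    groups = []  # (slice of all at-risk start index, death row indices)
    for ut in uniq_times:
        at_risk_start = np.searchsorted(t, ut, side="left")
        deaths = np.where((t == ut) & death_mask)[0]
        groups.append((at_risk_start, deaths))

    beta = np.zeros(F)
    converged = np.zeros(F, dtype=bool)
    for _ in range(max_iter):
        eta = Xs * beta[None, :]
        eta -= eta.max(axis=0, keepdims=True)  # stabilise exp
        w = np.exp(eta)
        wx = w * Xs
        wx2 = wx * Xs
        # suffix sums: risk set at time t = samples with index >= start
        S0 = np.cumsum(w[::-1], axis=0)[::-1]
        S1 = np.cumsum(wx[::-1], axis=0)[::-1]
        S2 = np.cumsum(wx2[::-1], axis=0)[::-1]
        U = np.zeros(F)
        Info = np.zeros(F)
        for start, deaths in groups:
            d = len(deaths)
            U += Xs[deaths].sum(axis=0)
            sd0 = w[deaths].sum(axis=0)
            sd1 = wx[deaths].sum(axis=0)
            sd2 = wx2[deaths].sum(axis=0)
            for l in range(d):
                phi = l / d
                den0 = S0[start] - phi * sd0
                den1 = S1[start] - phi * sd1
                den2 = S2[start] - phi * sd2
                mu = den1 / den0
                U -= mu
                Info += den2 / den0 - mu**2
        Info = np.maximum(Info, 1e-300)
        step = U / Info
        step = np.clip(step, -5, 5)
        beta = beta + step
        newly = np.abs(step) < tol
        converged |= newly
        if converged.all():
            break
    se = 1.0 / np.sqrt(Info)
    z = beta / se
    p = 2 * stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {
            "coef": beta,
            "hr": np.exp(beta),
            "se": se,
            "p": p,
            "converged": converged,
        }
    )


@dataclass
class CoxScreenResult:
    """Per-lipid univariable Cox fits and the decorrelated retained set."""

    table: pd.DataFrame          # index = feature id; hr, ci, p, converged
    retained: list[str]          # p < alpha, ranked by p, then decorrelated
    significant: list[str]       # p < alpha before decorrelation
    excluded: list[str] = field(default_factory=list)


def univariate_cox_screen(
    X,
    time,
    event,
    alpha: float = 0.05,
    scc_threshold: float = 0.5,
    min_events: int = 10,
) -> CoxScreenResult:
    """Screen lipids by univariable Cox p < alpha, then prune redundancy.

    Each lipid is a continuous covariate in its own Cox PH fit (Efron
    ties).  Lipids with Wald p below *alpha* are ranked by ascending p and
    passed through the stepwise Spearman decorrelation rule (|SCC| <
    *scc_threshold* against every already-retained lipid).  Constant or
    non-converged lipids are excluded with a logged reason.
    """
    if isinstance(X, ProcessedMatrix):
        X = X.values
    X = pd.DataFrame(X)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    if np.isnan(time).any() or np.isnan(np.asarray(event, dtype=float)).any():
        raise ValueError("survival data must be complete for all samples")
    if event.sum() < min_events:
        logger.warning(
            "univariate_cox_screen: only %d events (<%d recommended)",
            int(event.sum()), min_events,
        )
    arr = X.to_numpy(dtype=float)
    constant = arr.std(axis=0) == 0
    excluded = [str(c) for c in X.columns[constant]]
    cols = X.columns[~constant]
    fits = cox_univariate_batch(arr[:, ~constant], time, event)
    fits.index = cols
    bad = fits.index[~fits["converged"]]
    if len(bad):
        logger.warning("cox screen: %d lipids failed to converge", len(bad))
        excluded.extend(map(str, bad))
        fits = fits[fits["converged"]]
    fits["ci_low"] = np.exp(fits["coef"] - 1.959964 * fits["se"])
    fits["ci_high"] = np.exp(fits["coef"] + 1.959964 * fits["se"])
    significant = (
        fits[fits["p"] < alpha].sort_values("p").index.astype(str).tolist()
    )
    retained = significant
    if len(significant) > 1:
        corr = spearman_matrix(X[significant])
        retained = stepwise_decorrelate(
            significant, corr, threshold=scc_threshold
        ).selected
    return CoxScreenResult(fits, retained, significant, excluded)


# ---------------------------------------------------------------------
# Kaplan-Meier / log-rank / Cox

@dataclass
class KmFit:
    """Group-wise Kaplan-Meier fit with log-rank test and hazard ratio."""

    fitters: dict[str, KaplanMeierFitter]
    chi2: float
    p: float
    hr: float | None                    # group 2 vs group 1 (sorted labels)
    hr_ci: tuple[float, float] | None
    survival_at: pd.DataFrame           # groups x horizons
    zero_event_groups: list[str] = field(default_factory=list)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for name, kmf in self.fitters.items():
            kmf.plot_survival_function(ax=ax, label=str(name))
        ax.set_xlabel("months")
        ax.set_ylabel("overall survival")
        return ax


def km_logrank(groups, time, event, horizons=(24.0,)) -> KmFit:
    """Kaplan-Meier per group, log-rank test, and two-group hazard ratio.

    ``survival_at`` evaluates each step function at the given horizons
    (right-continuous, e.g. two-year OS at 24 months).  With exactly two
    groups the HR (second sorted label vs first) comes from a
    one-covariate Cox fit; a group with zero events flags an unbounded CI.
    """
    groups = pd.Series(np.asarray(groups), name="group").astype(str)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    labels = sorted(groups.unique())
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    fitters: dict[str, KaplanMeierFitter] = {}
    surv_rows = {}
    zero_event = []
    for g in labels:
        m = (groups == g).to_numpy()
        kmf = KaplanMeierFitter()
        kmf.fit(time[m], event[m], label=str(g))
        fitters[g] = kmf
        surv_rows[g] = [float(kmf.predict(h)) for h in horizons]
        if event[m].sum() == 0:
            zero_event.append(g)
    lr = multivariate_logrank_test(time, groups.to_numpy(), event)
    hr = hr_ci = None
    if len(labels) == 2:
        df = pd.DataFrame(
            {
                "time": time,
                "event": event,
                "g": (groups == labels[1]).astype(int).to_numpy(),
            }
        )
        try:
            cph = CoxPHFitter()
            cph.fit(df, duration_col="time", event_col="event")
            hr = float(np.exp(cph.params_["g"]))
            lo, hi = cph.confidence_intervals_.loc["g"]
            hr_ci = (float(np.exp(lo)), float(np.exp(hi)))
        except Exception as err:  # zero events in a group etc.
            logger.warning("km_logrank: HR fit failed (%s)", err)
    return KmFit(
        fitters,
        float(lr.test_statistic),
        float(lr.p_value),
        hr,
        hr_ci,
        pd.DataFrame(surv_rows, index=list(horizons)).T,
        zero_event,
    )


def cox_multivariable(
    df: pd.DataFrame,
    duration_col: str = "time_months",
    event_col: str = "event",
    condition_limit: float = 1e8,
) -> pd.DataFrame:
    """Multivariable Cox PH fit (Efron ties) over all remaining columns.

    Categorical covariates are expanded to indicators against the first
    sorted level.  Collinear covariates raise before fitting.  Returns the
    lifelines summary (HR, CI, p per covariate).
    """
    covs = df.drop(columns=[duration_col, event_col])
    covs = pd.get_dummies(covs, drop_first=True, dtype=float)
    mat = covs.to_numpy(dtype=float)
    centered = mat - mat.mean(axis=0)
    if np.linalg.matrix_rank(centered) < centered.shape[1] or (
        np.linalg.cond(centered) > condition_limit
    ):
        raise ValueError("collinear covariates in multivariable Cox fit")
    full = pd.concat([df[[duration_col, event_col]], covs], axis=1)
    cph = CoxPHFitter()
    cph.fit(full, duration_col=duration_col, event_col=event_col)
    out = cph.summary[
        ["exp(coef)", "exp(coef) lower 95%", "exp(coef) upper 95%", "p"]
    ]
    return out.rename(
        columns={
            "exp(coef)": "hr",
            "exp(coef) lower 95%": "ci_low",
            "exp(coef) upper 95%": "ci_high",
        }
    )


# ---------------------------------------------------------------------
# elastic-net subtype predictor

@dataclass
class SubtypePredictor:
    """Penalized logistic model mapping lipid profiles to subtype labels."""

    feature_ids: list[str]
    beta: np.ndarray
    beta0: float
    alpha: float        # elastic-net mixing (1 = lasso, 0 = ridge)
    lambda_: float      # selected penalty strength (glmnet scale)
    classes: list[str]  # [class coded 0, class coded 1]
    cv_deviance: pd.Series | None = None


def _lambda_to_C(lam: float, n: int) -> float:
    # sklearn minimises sum(loss) + (1/C)*penalty; glmnet minimises
    # mean(loss) + lambda*penalty, so C = 1 / (n * lambda)
    return 1.0 / (n * lam)


def fit_subtype_predictor(
    X,
    labels,
    alpha: float = 1.0,
    lambda_grid=None,
    weights=None,
    cv: int = 5,
    seed: int = 0,
) -> SubtypePredictor:
    """Fit the elastic-net logistic subtype predictor.

    lambda is chosen by *cv*-fold cross-validated binomial deviance over
    *lambda_grid* (default: 30 log-spaced values from just below the
    smallest lambda that zeroes every coefficient down to 1e-4 of it).
    Deterministic for a fixed seed.
    """
    if isinstance(X, ProcessedMatrix):
        X = X.values
    X = pd.DataFrame(X)
    feature_ids = list(map(str, X.columns))
    Xa = X.to_numpy(dtype=float)
    yv = np.asarray(labels)
    classes = sorted(map(str, np.unique(yv)))
    if len(classes) != 2:
        raise ValueError("need exactly two subtype labels")
    y01 = (yv.astype(str) == classes[1]).astype(int)
    n = len(y01)
    if lambda_grid is None:
        # glmnet-style path anchored at lambda_max = max |X'(y - ybar)| / (N a)
        resid = y01 - y01.mean()
        lam_max = np.abs(Xa.T @ resid).max() / (n * max(alpha, 1e-3))
        lambda_grid = np.geomspace(lam_max, lam_max * 1e-2, 20)
    lambda_grid = np.asarray(sorted(lambda_grid, reverse=True), dtype=float)

    skf = StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed)
    folds = list(skf.split(Xa, y01))
    dev = np.zeros(len(lambda_grid))
    ok = np.ones(len(lambda_grid), dtype=bool)
    for j, lam in enumerate(lambda_grid):
        losses = []
        try:
            for tr, te in folds:
                est = _make_enet(alpha, lam, len(tr), weights)
                est.fit(Xa[tr], y01[tr])
                prob = est.predict_proba(Xa[te])[:, 1]
                losses.append(log_loss(y01[te], prob, labels=[0, 1]))
            dev[j] = float(np.mean(losses))
        except Exception as err:
            logger.warning("enet: dropping lambda=%.3g (%s)", lam, err)
            ok[j] = False
            dev[j] = np.inf
    best = int(np.argmin(dev))
    lam = float(lambda_grid[best])
    final = _make_enet(alpha, lam, n, weights)
    final.fit(Xa, y01)
    beta = final.coef_.ravel().copy()
    # the intercept is unpenalized, so given beta its exact optimum solves a
    # 1-D MLE; polish it by Newton (saga can leave it short at strong
    # penalties once every coefficient is zeroed)
    beta0 = _polish_intercept(Xa @ beta, y01, float(final.intercept_[0]))
    return SubtypePredictor(
        feature_ids,
        beta,
        beta0,
        alpha,
        lam,
        classes,
        pd.Series(dev, index=lambda_grid, name="cv_deviance"),
    )


def _polish_intercept(offset: np.ndarray, y01: np.ndarray,
                      b0: float, max_iter: int = 50) -> float:
    for _ in range(max_iter):
        p = 1.0 / (1.0 + np.exp(-(offset + b0)))
        grad = float(np.sum(y01 - p))
        hess = float(np.sum(p * (1 - p)))
        if hess <= 0:
            break
        step = grad / hess
        b0 += step
        if abs(step) < 1e-12:
            break
    return b0


def _make_enet(alpha: float, lam: float, n: int, weights) -> LogisticRegression:
    return LogisticRegression(
        l1_ratio=float(alpha),
        C=_lambda_to_C(lam, n),
        solver="saga",
        max_iter=5000,
        tol=1e-5,
    )


def predict_subtype(
    predictor: SubtypePredictor, X
) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-class probabilities and the higher-score subtype label.

    Exact probability ties (linear predictor 0) resolve to the first class
    (the worse-prognosis subtype, by the SI/SII naming convention).
    """
    if isinstance(X, ProcessedMatrix):
        X = X.values
    if isinstance(X, pd.DataFrame):
        missing = [f for f in predictor.feature_ids if f not in X.columns]
        if missing:
            raise KeyError(f"missing predictor features: {missing[:5]}")
        X = X[predictor.feature_ids]
    Xa = np.asarray(X, dtype=float)
    eta = Xa @ predictor.beta + predictor.beta0
    with np.errstate(over="ignore"):
        p1 = 1.0 / (1.0 + np.exp(-eta))
    probs = pd.DataFrame(
        {predictor.classes[0]: 1 - p1, predictor.classes[1]: p1}
    )
    labels = np.where(p1 > 0.5, predictor.classes[1], predictor.classes[0])
    return probs, labels
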