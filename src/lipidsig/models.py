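"""Model / Results objects tying the pipeline stages together.

Two estimators, in the statsmodels idiom (a Model built from data whose
``fit()`` returns a Results object carrying estimates, uncertainties,
diagnostics and a ``summary()`` table):

:class:`DiagnosticSignature`
    cancer-vs-healthy scoring: PLS-DA VIP ranking -> stepwise Spearman
    decorrelation of the top 50 -> (algorithm, panel size) chosen on a
    repeated stratified CV grid -> LDA panel with the logistic-posterior
    score and the strict 0.5 decision rule.

:class:`PrognosticSubtypes`
    survival subtyping of the cancer samples: univariable Cox screen with
    decorrelation -> consensus clustering with delta-area K choice ->
    SI/SII naming by worse observed survival -> Kaplan-Meier / log-rank /
    Cox hazard ratio -> elastic-net subtype predictor for new cohorts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, consensus as consensus_mod, plsda, prognosis
from .datatypes import ProcessedMatrix
from .metrics import MetricsReport, confusion_metrics
from .panel import SelectedPanel, spearman_matrix, stepwise_decorrelate
from .preprocess import autoscale

__all__ = [
    "DiagnosticSignature",
    "DiagnosticSignatureResults",
    "PrognosticSubtypes",
    "PrognosticSubtypesResults",
]


def _to_pm(X) -> ProcessedMatrix:
    if isinstance(X, ProcessedMatrix):
        return X
    return ProcessedMatrix(pd.DataFrame(X))


class DiagnosticSignature:
    """Diagnostic lipid-signature model on a scaled training matrix.

    Parameters
    ----------
    X : ProcessedMatrix or DataFrame
        Training matrix (samples x lipids), already normalized; it is
        autoscaled internally and the scaling parameters are frozen for
        prediction on new cohorts.
    y : array-like
        Binary group labels; *positive* names the cancer class.
    """

    def __init__(
        self,
        X,
        y,
        positive="GC",
        n_components: int = 2,
        top_n: int = 50,
        scc_threshold: float = 0.5,
        sizes=tuple(range(2, 51)),
        algorithms=("lda",),
        cv_folds: int = 10,
        cv_repeats: int = 10,
        vip_components: int | None = None,
    ):
        self.X = _to_pm(X)
        self.y = np.asarray(y)
        self.positive = positive
        self.n_components = n_components
        self.top_n = top_n
        self.scc_threshold = scc_threshold
        self.sizes = sizes
        self.algorithms = algorithms
        self.cv_folds = cv_folds
        self.cv_repeats = cv_repeats
        self.vip_components = vip_components

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_col: str, **kwargs):
        y = df[label_col]
        X = df.drop(columns=[label_col])
        return cls(X, y, **kwargs)

    def fit(self, seed: int = 0) -> "DiagnosticSignatureResults":
        scaled = autoscale(self.X)[0]
        model = plsda.fit_plsda(scaled, self.y, self.n_components)
        vip = plsda.vip_scores(model, components=self.vip_components)
        ranking = plsda.rank_by_vip(vip, top_n=self.top_n)
        corr = spearman_matrix(scaled.subset_features(ranking))
        panel = stepwise_decorrelate(ranking, corr, self.scc_threshold)
        specs = [
            c
            for c in classify.default_classifiers(seed)
            if c.name in self.algorithms
        ]
        grid = classify.cross_validate_grid(
            scaled,
            (self.y == self.positive),
            panel.selected,
            sizes=self.sizes,
            classifiers=specs,
            k=self.cv_folds,
            repeats=self.cv_repeats,
            seed=seed,
        )
        algorithm, size = classify.select_best(grid)
        final_panel = panel.selected[:size]
        lda = classify.fit_lda(
            scaled.subset_features(final_panel),
            (self.y == self.positive),
            positive=True,
        )
        return DiagnosticSignatureResults(
            model=self,
            scaling=scaled.scaling,
            plsda_model=model,
            vip=vip,
            ranking=ranking,
            decorrelated=panel,
            cv_grid=grid,
            algorithm=algorithm,
            panel_size=size,
            panel=final_panel,
            lda=lda,
        )


@dataclass
class DiagnosticSignatureResults:
    """Fitted diagnostic signature: panel, coefficients and CV diagnostics."""

    model: DiagnosticSignature
    scaling: object
    plsda_model: plsda.PlsdaModel
    vip: pd.Series
    ranking: list[str]
    decorrelated: SelectedPanel
    cv_grid: classify.CvGrid
    algorithm: str
    panel_size: int
    panel: list[str]
    lda: classify.LdaModel

    @property
    def alpha(self) -> pd.Series:
        """LDA log-odds coefficients per panel lipid."""
        return pd.Series(self.lda.alpha, index=self.panel, name="alpha")

    @property
    def alpha0(self) -> float:
        return self.lda.alpha0

    @property
    def cv_accuracy(self) -> float:
        return float(self.cv_grid.cell(self.algorithm, self.panel_size)["mean_acc"])

    def _scale_new(self, X) -> pd.DataFrame:
        X = _to_pm(X).values
        s = self.scaling
        cols = [f for f in self.panel]
        missing = [f for f in cols if f not in X.columns]
        if missing:
            raise KeyError(f"panel features missing: {missing[:5]}")
        return (X[cols] - s.mean[cols]) / s.sd[cols]

    def predict(self, X) -> pd.DataFrame:
        """Scores (posterior probability of cancer) and 0.5-rule labels."""
        Z = self._scale_new(X)
        scores, labels = classify.predict_score(self.lda, Z)
        return pd.DataFrame(
            {"score": scores, "label": np.where(labels, "GC", "HD")},
            index=Z.index,
        )

    def evaluate(self, X, y) -> MetricsReport:
        """Confusion metrics with exact CIs, plus AUC, on a new cohort."""
        pred = self.predict(X)
        truth = np.asarray(y) == self.model.positive
        return confusion_metrics(pred["score"].to_numpy(), truth)

    def plot_roc(self, X, y, ax=None):
        import matplotlib.pyplot as plt

        from .metrics import roc_auc

        pred = self.predict(X)
        roc = roc_auc(pred["score"], np.asarray(y) == self.model.positive)
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(roc.fpr, roc.tpr, label=f"AUC = {roc.auc:.3f}")
        ax.plot([0, 1], [0, 1], "k--", lw=0.5)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.legend()
        return ax

    def summary(self) -> str:
        lines = [
            "Diagnostic lipid signature (LDA posterior score)",
            "=" * 52,
            f"algorithm:         {self.algorithm}",
            f"panel size:        {self.panel_size}"
            f" (from {len(self.decorrelated)} decorrelated of "
            f"top {len(self.ranking)} by VIP)",
            f"CV mean accuracy:  {self.cv_accuracy:.3f} "
            f"({self.cv_grid.k}-fold x {self.cv_grid.repeats})",
            f"intercept alpha_0: {self.alpha0:+.4f}",
            "",
            "panel lipid        alpha       VIP",
            "-" * 36,
        ]
        for f in self.panel:
            lines.append(f"{f:<16s} {self.alpha[f]:+9.4f} {self.vip[f]:9.3f}")
        return "\n".join(lines)

    def save(self, path: str | Path) -> None:
        """Serialize panel, coefficients and scaling parameters as JSON."""
        s = self.scaling
        payload = {
            "panel": self.panel,
            "alpha": self.alpha.tolist(),
            "alpha0": self.alpha0,
            "algorithm": self.algorithm,
            "scaling_mean": {f: float(s.mean[f]) for f in self.panel},
            "scaling_sd": {f: float(s.sd[f]) for f in self.panel},
        }
        Path(path).write_text(json.dumps(payload, indent=1))


class PrognosticSubtypes:
    """Prognostic subtype model on the cancer samples' lipid matrix.

    *X* is the normalized (log2) lipid matrix of cancer patients; *time*
    (months) and *event* (0/1) describe overall survival.
    """

    def __init__(
        self,
        X,
        time,
        event,
        screen_alpha: float = 0.05,
        scc_threshold: float = 0.5,
        k_range=range(2, 7),
        reps: int = 1000,
        subsample: float = 0.8,
        enet_alpha: float = 1.0,
        horizons=(24.0,),
    ):
        self.X = _to_pm(X)
        self.time = np.asarray(time, dtype=float)
        self.event = np.asarray(event).astype(int)
        self.screen_alpha = screen_alpha
        self.scc_threshold = scc_threshold
        self.k_range = list(k_range)
        self.reps = reps
        self.subsample = subsample
        self.enet_alpha = enet_alpha
        self.horizons = tuple(horizons)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, time_col="time_months", event_col="event",
        **kwargs,
    ):
        X = df.drop(columns=[time_col, event_col])
        return cls(X, df[time_col], df[event_col], **kwargs)

    def fit(self, seed: int = 0) -> "PrognosticSubtypesResults":
        scaled = autoscale(self.X)[0]
        screen = prognosis.univariate_cox_screen(
            self.X, self.time, self.event,
            alpha=self.screen_alpha, scc_threshold=self.scc_threshold,
        )
        if len(screen.retained) < 2:
            raise ValueError(
                f"only {len(screen.retained)} prognostic lipids retained; "
                "cannot cluster"
            )
        Xp = scaled.subset_features(screen.retained).values
        cons = consensus_mod.consensus_cluster(
            Xp, self.k_range, reps=self.reps, subsample=self.subsample,
            seed=seed,
        )
        k, k_diag = consensus_mod.choose_k(cons)
        raw_labels = cons.labels(k)
        labels = self._name_subtypes(raw_labels)
        km = prognosis.km_logrank(
            labels.to_numpy(), self.time, self.event, horizons=self.horizons
        )
        predictor = prognosis.fit_subtype_predictor(
            Xp, labels.to_numpy(), alpha=self.enet_alpha, seed=seed
        )
        return PrognosticSubtypesResults(
            model=self,
            scaling=scaled.scaling,
            screen=screen,
            consensus=cons,
            k=k,
            k_diagnostics=k_diag,
            labels=labels,
            km=km,
            predictor=predictor,
        )

    def _name_subtypes(self, raw: pd.Series) -> pd.Series:
        """SI..Sk ordered by worse observed survival (SI = worst).

        Groups are ranked by restricted-mean survival time up to the last
        follow-up; the shortest RMST becomes SI.
        """
        from lifelines import KaplanMeierFitter
        from lifelines.utils import restricted_mean_survival_time

        horizon = float(self.time.max())
        rmst = {}
        for g in sorted(raw.unique()):
            m = (raw == g).to_numpy()
            kmf = KaplanMeierFitter().fit(self.time[m], self.event[m])
            rmst[g] = restricted_mean_survival_time(kmf, t=horizon)
        order = sorted(rmst, key=lambda g: rmst[g])
        roman = ["I", "II", "III", "IV", "V", "VI"]
        name = {g: f"S{roman[i]}" for i, g in enumerate(order)}
        return raw.map(name).rename("subtype")


@dataclass
class PrognosticSubtypesResults:
    """Fitted prognostic subtyping: labels, survival contrast, predictor."""

    model: PrognosticSubtypes
    scaling: object
    screen: prognosis.CoxScreenResult
    consensus: consensus_mod.ConsensusModel
    k: int
    k_diagnostics: dict
    labels: pd.Series
    km: prognosis.KmFit
    predictor: prognosis.SubtypePredictor
    extras: dict = field(default_factory=dict)

    @property
    def hazard_ratio(self) -> float | None:
        """HR of SI (worse survival) vs SII from the one-covariate Cox fit.

        ``km.hr`` contrasts the second sorted label (SII) against the
        first (SI); invert so the reported HR is risk of SI relative to
        SII, matching the clinical reading.
        """
        return None if self.km.hr is None else 1.0 / self.km.hr

    @property
    def hazard_ratio_ci(self) -> tuple[float, float] | None:
        if self.km.hr_ci is None:
            return None
        lo, hi = self.km.hr_ci
        return (1.0 / hi, 1.0 / lo)

    @property
    def logrank_p(self) -> float:
        return self.km.p

    def predict(self, X) -> pd.DataFrame:
        """Subtype of new samples by the higher elastic-net class score."""
        Xn = _to_pm(X).values
        s = self.scaling
        cols = self.predictor.feature_ids
        missing = [f for f in cols if f not in Xn.columns]
        if missing:
            raise KeyError(f"predictor features missing: {missing[:5]}")
        Z = (Xn[cols] - s.mean[cols]) / s.sd[cols]
        probs, labels = prognosis.predict_subtype(self.predictor, Z)
        probs.index = Xn.index
        out = probs.copy()
        out["subtype"] = labels
        return out

    def cox_multivariable(self, covariates: pd.DataFrame) -> pd.DataFrame:
        """Multivariable Cox of survival on subtype + clinical covariates."""
        df = covariates.copy()
        df["subtype"] = self.labels.to_numpy()
        df["time_months"] = self.model.time
        df["event"] = self.model.event
        return prognosis.cox_multivariable(df)

    def summary(self) -> str:
        surv = self.km.survival_at
        lines = [
            "Prognostic subtypes from serum lipids (consensus clustering)",
            "=" * 60,
            f"lipids screened:    {len(self.screen.table)}"
            f" -> {len(self.screen.significant)} at p<"
            f"{self.model.screen_alpha} -> {len(self.screen.retained)}"
            " after decorrelation",
            f"chosen K:           {self.k}"
            + ("  [low confidence]" if self.k_diagnostics["low_confidence"]
               else ""),
            f"subtype sizes:      "
            + ", ".join(
                f"{g}={int((self.labels == g).sum())}"
                for g in sorted(self.labels.unique())
            ),
            f"log-rank:           chi2={self.km.chi2:.2f}, p={self.km.p:.3g}",
        ]
        if self.hazard_ratio is not None:
            lo, hi = self.hazard_ratio_ci
            lines.append(
                f"HR (SI vs SII):     {self.hazard_ratio:.2f} "
                f"(95% CI {lo:.2f}-{hi:.2f})"
            )
        for h in surv.columns:
            rates = ", ".join(
                f"{g}: {surv.at[g, h] * 100:.1f}%" for g in surv.index
            )
            lines.append(f"OS at {h:g} months:  {rates}")
        nz = int(np.sum(self.predictor.beta != 0))
        lines.append(
            f"subtype predictor:  elastic net (alpha={self.predictor.alpha},"
            f" lambda={self.predictor.lambda_:.3g}), {nz} nonzero coefficients"
        )
        return "\n".join(lines)
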