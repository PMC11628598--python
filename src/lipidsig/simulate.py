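"""Synthetic serum-lipidomics cohorts with planted diagnostic and prognostic signal.

The generator emulates the statistical structure of an untargeted serum
lipidomics case/control study:

* ~581 lipid features on the log2 abundance scale, organised into
  correlated blocks (Gaussian copula with a shared block factor, so the
  within-block rank correlation is tunable and intensities stay positive
  after exponentiation);
* a subset of disease-informative lipids whose cancer-vs-healthy shift
  follows one of four pathological-stage trends (monotone up, monotone
  down, biphasic rise-then-fall, stage-flat);
* precancerous-lesion samples receiving intermediate shifts;
* two latent prognostic subtypes among the cancer samples, separated on a
  dedicated set of prognostic lipids and driving proportional-hazards
  survival with administrative plus dropout censoring;
* per-sample internal-standard intensities per ion mode, and pooled-QC
  replicate rows inserted one per 20 study samples.

Raw intensities are constructed as ``IS * 2**(L - 5)`` from the latent log2
matrix ``L``, so internal-standard normalization followed by the
``log2 + 5`` transform recovers ``L`` exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import IntensityTable

__all__ = [
    "SimulationConfig",
    "CohortTruth",
    "generate_cohort",
    "simulate_survival",
    "generate_qc_replicates",
    "write_cohort",
]

#: Stage multipliers applied to ``effect_size`` for each trend family,
#: indexed by pTNM stage I..IV.  "biphasic" rises through stage II then
#: partially declines; "down" lipids are depleted progressively.
TREND_PROFILES = {
    "up": np.array([0.5, 0.833, 1.167, 1.5]),
    "down": -np.array([0.5, 0.833, 1.167, 1.5]),
    "biphasic": np.array([0.6, 1.5, 1.2, 0.9]),
    "flat": np.array([1.0, 1.0, 1.0, 1.0]),
}

STAGES = ("I", "II", "III", "IV")

_TREND_CYCLE = ("up", "down", "biphasic", "flat")


def _default_block_sizes() -> list[int]:
    # 10 informative blocks of 4 lipids + 20 correlated noise blocks of 10;
    # remaining features are independent.
    return [4] * 10 + [10] * 20


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Effect sizes are in units of the within-group SD on the log2 scale.
    ``block_rho`` is the target within-block Spearman correlation.
    """

    n_gc: int = 266
    n_hd: int = 266
    n_pl: int = 0
    n_features: int = 581
    n_informative: int = 40
    block_sizes: list[int] = field(default_factory=_default_block_sizes)
    block_rho: float = 0.7
    effect_size: float = 1.0
    trend_profiles: list[str] | None = None
    n_prognostic: int = 20
    subtype_effect: float = 1.5
    n_subtypes: int = 2
    subtype_hr: float = 3.34
    baseline_hazard: float = 0.005
    censor_horizon: float = 60.0
    dropout_scale: float = 180.0
    qc_cv: float = 0.10
    n_unstable_qc: int = 20
    unstable_qc_cv: float = 0.5
    stage_probs: tuple[float, ...] = (0.20, 0.21, 0.38, 0.21)
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_gc, self.n_hd, self.n_pl, self.n_features,
                  self.n_informative, self.n_subtypes, self.n_prognostic)
        if any(c < 0 for c in counts):
            raise ValueError("counts must be nonnegative")
        if sum(self.block_sizes) > self.n_features:
            raise ValueError("sum(block_sizes) exceeds n_features")
        if not 0 <= self.block_rho < 1:
            raise ValueError("block_rho must be in [0, 1)")
        if self.n_informative > self.n_features:
            raise ValueError("n_informative exceeds n_features")
        if self.subtype_hr <= 0 or self.baseline_hazard <= 0:
            raise ValueError("hazard parameters must be positive")
        if self.qc_cv < 0:
            raise ValueError("qc_cv must be nonnegative")
        if self.trend_profiles is not None:
            bad = set(self.trend_profiles) - set(TREND_PROFILES)
            if bad:
                raise ValueError(f"unknown trend labels: {sorted(bad)}")
            if len(self.trend_profiles) != self.n_informative:
                raise ValueError("need one trend label per informative feature")


@dataclass
class CohortTruth:
    """Ground truth of a generated cohort, for benchmarking recovery."""

    informative_feature_ids: list[str]
    trend_labels: dict[str, str]
    informative_blocks: list[list[str]]
    prognostic_feature_ids: list[str]
    subtype: dict[str, int]  # GC sample id -> latent subtype (1 = high risk)
    hazard_ratio: float

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortTruth":
        return cls(**json.loads(Path(path).read_text()))


def _latent_correlated(
    rng: np.random.Generator, n: int, config: SimulationConfig
) -> tuple[np.ndarray, list[list[int]]]:
    """Block-correlated standard normal matrix via a shared-factor copula.

    Within a block, pairwise latent Pearson correlation r is chosen so the
    rank (Spearman) correlation is ``block_rho``: r = 2 sin(pi * rho / 6).
    """
    p = config.n_features
    z = rng.standard_normal((n, p))
    r = 2.0 * math.sin(math.pi * config.block_rho / 6.0)
    blocks: list[list[int]] = []
    start = 0
    for size in config.block_sizes:
        cols = list(range(start, start + size))
        g = rng.standard_normal(n)
        z[:, cols] = math.sqrt(r) * g[:, None] + math.sqrt(1 - r) * z[:, cols]
        blocks.append(cols)
        start += size
    return z, blocks


def simulate_survival(
    subtype_labels: Sequence[int],
    subtype_hr: float,
    baseline_hazard: float,
    censor_horizon: float,
    seed: int,
    shape: float = 1.0,
    dropout_scale: float | None = None,
) -> pd.DataFrame:
    """Proportional-hazards event times with two censoring sources.

    Event times are Weibull with the given *shape* (1.0 = exponential) and
    per-sample rate ``baseline_hazard * subtype_hr**label``.  Censoring is
    administrative at *censor_horizon* plus independent uniform dropout on
    ``(0, dropout_scale)`` (default 3x the horizon).

    Returns a frame with ``time_months`` (> 0) and ``event`` (0/1) columns.
    """
    labels = np.asarray(subtype_labels)
    if labels.size == 0:
        raise ValueError("subtype labels must be nonempty")
    if subtype_hr <= 0 or baseline_hazard <= 0:
        raise ValueError("hazard parameters must be positive")
    rng = np.random.default_rng(seed)
    rate = baseline_hazard * subtype_hr ** labels.astype(float)
    u = rng.uniform(size=labels.size)
    # Weibull with cumulative hazard H(t) = rate * t**shape, so hazards stay
    # proportional across subtypes at any shape; shape=1 is exponential
    t_event = (-np.log(u) / rate) ** (1.0 / shape)
    if dropout_scale is None:
        dropout_scale = 3.0 * censor_horizon
    t_cens = np.minimum(censor_horizon, rng.uniform(0, dropout_scale, labels.size))
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    time = np.maximum(time, 1e-9)
    return pd.DataFrame({"time_months": time, "event": event})


def generate_qc_replicates(
    table: IntensityTable,
    qc_cv: float,
    seed: int,
    feature_cv: pd.Series | None = None,
) -> IntensityTable:
    """Append pooled-QC replicate rows, one per 20 study samples.

    QC rows are multiplicative log-normal perturbations of the mean study
    profile with per-feature coefficient of variation *qc_cv* (overridable
    per feature via *feature_cv*).  ``qc_cv=0`` yields identical rows.
    """
    if qc_cv < 0:
        raise ValueError("qc_cv must be nonnegative")
    rng = np.random.default_rng(seed)
    study = table.intensities.loc[~table.qc_flags]
    n_qc = math.ceil(len(study) / 20)
    pooled = study.mean(axis=0).to_numpy()
    cv = np.full(table.intensities.shape[1], float(qc_cv))
    if feature_cv is not None:
        aligned = feature_cv.reindex(table.feature_ids)
        cv = np.where(aligned.notna(), aligned.fillna(0.0), cv)
    sigma = np.sqrt(np.log1p(cv**2))
    noise = np.exp(
        rng.standard_normal((n_qc, cv.size)) * sigma[None, :]
        - sigma[None, :] ** 2 / 2.0
    )
    qc_ids = [f"QC{i + 1:03d}" for i in range(n_qc)]
    qc_rows = pd.DataFrame(
        pooled[None, :] * noise, index=qc_ids, columns=table.feature_ids
    )
    is_mean = table.internal_standards.loc[~table.qc_flags].mean(axis=0)
    qc_is = pd.DataFrame(
        np.tile(is_mean.to_numpy(), (n_qc, 1)),
        index=qc_ids,
        columns=table.internal_standards.columns,
    )
    return IntensityTable(
        pd.concat([table.intensities, qc_rows]),
        table.feature_modes,
        pd.concat([table.internal_standards, qc_is]),
        pd.concat([table.qc_flags, pd.Series(True, index=qc_ids)]),
    )


def _biomarkers(rng: np.random.Generator, group: np.ndarray) -> pd.DataFrame:
    """Conventional serum tumor markers with realistic low sensitivity."""
    n = group.size
    gc = group == "GC"
    # (median_hd, sigma_hd, median_gc, sigma_gc)
    params = {
        "cea": (1.5, 0.6, 1.8, 0.7),
        "ca199": (8.0, 0.8, 9.0, 0.95),
        "ca724": (2.5, 0.9, 3.0, 1.0),
    }
    out = {}
    for name, (m0, s0, m1, s1) in params.items():
        med = np.where(gc, m1, m0)
        sig = np.where(gc, s1, s0)
        out[name] = med * np.exp(rng.standard_normal(n) * sig)
    return pd.DataFrame(out)


def generate_cohort(
    config: SimulationConfig,
) -> tuple[IntensityTable, pd.DataFrame, CohortTruth]:
    """Generate one cohort: intensities + QC rows, annotations, and truth.

    Deterministic for a fixed ``config.seed``.  Informative lipids shift
    between GC and HD by ``effect_size`` SD units on the log2 scale
    (modulated by the stage-trend profile); PL samples receive half the
    stage-I shift; prognostic lipids separate the two latent GC subtypes by
    ``subtype_effect`` SD units.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_gc + config.n_hd + config.n_pl
    p = config.n_features

    feature_ids = [f"L{i + 1:04d}" for i in range(p)]
    modes = pd.Series(
        ["pos" if i % 2 == 0 else "neg" for i in range(p)], index=feature_ids
    )

    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    group = np.array(
        ["GC"] * config.n_gc + ["HD"] * config.n_hd + ["PL"] * config.n_pl
    )

    # latent block-correlated noise
    z, block_cols = _latent_correlated(rng, n, config)

    # stage assignment for GC samples
    stage = np.full(n, None, dtype=object)
    probs = np.asarray(config.stage_probs, dtype=float)
    probs = probs / probs.sum()
    stage_idx = rng.choice(4, size=config.n_gc, p=probs)
    stage[: config.n_gc] = [STAGES[i] for i in stage_idx]

    # latent prognostic subtype (1 = high risk) for GC samples
    subtype = rng.integers(0, config.n_subtypes, size=config.n_gc)

    # informative features: leading blocks, one trend family per block
    informative = list(range(config.n_informative))
    trend = np.empty(config.n_informative, dtype=object)
    if config.trend_profiles is not None:
        trend[:] = config.trend_profiles
    else:
        b = 0
        for cols in block_cols:
            inside = [c for c in cols if c < config.n_informative]
            if not inside:
                continue
            trend[inside] = _TREND_CYCLE[b % len(_TREND_CYCLE)]
            b += 1
        loose = [i for i in informative if trend[i] is None]
        for j, i in enumerate(loose):
            trend[i] = _TREND_CYCLE[j % len(_TREND_CYCLE)]
    # flat blocks alternate direction so not every flat lipid is elevated
    sign = np.ones(config.n_informative)
    flat_ids = [i for i in informative if trend[i] == "flat"]
    for j, i in enumerate(flat_ids):
        if (j // 4) % 2 == 1:
            sign[i] = -1.0

    # prognostic features: the trailing features, outside the correlated
    # blocks, so they are mutually independent apart from the correlation
    # the shared subtype shift itself induces (~0.36 at 1.5 SD separation,
    # below the 0.5 redundancy threshold)
    in_blocks = sum(config.block_sizes)
    start_prog = max(in_blocks, p - config.n_prognostic)
    prognostic = list(range(start_prog, p))

    # assemble log2 abundance: baseline + correlated noise + shifts.
    # Baseline abundance is a property of each lipid, not of the cohort:
    # it is drawn from a fixed stream so independent cohorts share it and
    # models transfer across cohorts, as they would on real serum panels.
    mu = np.random.default_rng(777).normal(0.0, 1.0, size=p)
    L = mu[None, :] + z
    gc_rows = np.where(group == "GC")[0]
    for i in informative:
        mult = TREND_PROFILES[str(trend[i])]
        L[gc_rows, i] += config.effect_size * sign[i] * mult[stage_idx]
    if config.n_pl:
        pl_rows = np.where(group == "PL")[0]
        for i in informative:
            mult = TREND_PROFILES[str(trend[i])]
            L[pl_rows, i] += 0.5 * config.effect_size * sign[i] * mult[0]
    half = config.subtype_effect / 2.0
    for i in prognostic:
        L[gc_rows, i] += np.where(subtype == 1, half, -half)

    # internal standards and raw intensities
    is_vals = pd.DataFrame(
        1e5 * np.exp(rng.normal(0, 0.05, size=(n, 2))),
        index=sample_ids,
        columns=["pos", "neg"],
    )
    is_per_feature = is_vals[modes.to_numpy()].to_numpy()
    raw = is_per_feature * np.exp2(L - 5.0)
    table = IntensityTable(
        pd.DataFrame(raw, index=sample_ids, columns=feature_ids),
        modes,
        is_vals,
        pd.Series(False, index=sample_ids),
    )

    # QC replicates, with a set of unstable non-informative features
    feature_cv = None
    if config.n_unstable_qc:
        candidates = [
            i for i in range(p) if i not in set(informative) | set(prognostic)
        ]
        unstable = candidates[-config.n_unstable_qc:]
        feature_cv = pd.Series(
            config.unstable_qc_cv, index=[feature_ids[i] for i in unstable]
        )
    table = generate_qc_replicates(
        table, config.qc_cv, seed=int(rng.integers(2**31)), feature_cv=feature_cv
    )

    # survival for GC samples (none when the cohort has no patients)
    surv = None
    if config.n_gc:
        surv = simulate_survival(
            subtype,
            config.subtype_hr,
            config.baseline_hazard,
            config.censor_horizon,
            seed=int(rng.integers(2**31)),
            dropout_scale=config.dropout_scale,
        )

    ann = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "group": group,
            "cohort": pd.NA,
            "stage": stage,
        }
    )
    ann = pd.concat([ann, _biomarkers(rng, group)], axis=1)
    ann["time_months"] = np.nan
    ann["event"] = np.nan
    if surv is not None:
        ann.loc[: config.n_gc - 1, "time_months"] = surv["time_months"].to_numpy()
        ann.loc[: config.n_gc - 1, "event"] = surv["event"].to_numpy()
    ann = ann.set_index("sample_id")

    truth = CohortTruth(
        informative_feature_ids=[feature_ids[i] for i in informative],
        trend_labels={feature_ids[i]: str(trend[i]) for i in informative},
        informative_blocks=[
            [feature_ids[c] for c in cols if c < config.n_informative]
            for cols in block_cols
            if any(c < config.n_informative for c in cols)
        ],
        prognostic_feature_ids=[feature_ids[i] for i in prognostic],
        subtype={sample_ids[j]: int(subtype[j]) for j in range(config.n_gc)},
        hazard_ratio=config.subtype_hr,
    )
    return table, ann, truth


def write_cohort(
    outdir: str | Path,
    table: IntensityTable,
    annotations: pd.DataFrame,
    truth: CohortTruth,
) -> None:
    """Write intensities (CSV + sidecar), annotations (CSV), truth (JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table.to_csv(outdir / "intensities.csv")
    annotations.to_csv(outdir / "annotations.csv", na_rep="NA")
    truth.to_json(outdir / "truth.json")
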