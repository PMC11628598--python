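"""QC filtering, internal-standard normalization, scaling and cohort splits.

The preprocessing chain for untargeted serum lipidomics:

1. :func:`rsd_qc_filter` — keep features whose relative standard deviation
   across pooled-QC replicate injections is below 30%.
2. :func:`normalize_log` — divide each raw intensity by the sample's
   internal-standard intensity for the feature's ion mode, then transform to
   ``log2(ratio) + 5``.
3. :func:`merge_modes` — concatenate positive- and negative-mode matrices,
   namespacing feature ids by mode.
4. :func:`autoscale` — per-feature standardization with parameters fitted on
   the training cohort only and applied frozen to all other cohorts.
5. :func:`split_cohort` — stratified 85/15 training/testing split.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import IntensityTable, ProcessedMatrix, ScalingParams

__all__ = [
    "rsd_qc_filter",
    "normalize_log",
    "merge_modes",
    "autoscale",
    "split_cohort",
]

logger = logging.getLogger(__name__)


def rsd_qc_filter(
    table: IntensityTable, threshold: float = 0.30
) -> tuple[IntensityTable, list[str]]:
    """Drop features whose QC relative standard deviation is >= *threshold*.

    RSD is the sample (n-1) standard deviation divided by the mean of the
    raw intensities over the QC replicate rows.  Features with zero QC mean
    are removed (RSD undefined) with a logged reason.

    Returns the filtered table and the list of removed feature ids.
    """
    qc = table.qc_samples()
    if len(qc) < 2:
        raise ValueError(f"need >= 2 QC rows to estimate RSD, got {len(qc)}")
    mean = qc.mean(axis=0)
    sd = qc.std(axis=0, ddof=1)
    degenerate = mean == 0
    if degenerate.any():
        logger.info(
            "rsd_qc_filter: removing %d features with zero QC mean",
            int(degenerate.sum()),
        )
    rsd = sd / mean.where(~degenerate)
    keep = (rsd < threshold) & ~degenerate
    removed = [str(f) for f in table.feature_ids[~keep]]
    return table.subset_features(table.feature_ids[keep]), removed


def normalize_log(
    table: IntensityTable, zero_policy: str = "impute"
) -> ProcessedMatrix:
    """Internal-standard normalization followed by ``log2 + 5`` transform.

    value = log2(raw / IS of that sample and ion mode) + 5.

    Non-positive raw intensities are handled per *zero_policy*: ``"impute"``
    replaces them with half the feature's minimum positive value before the
    transform (logged); ``"reject"`` raises.
    """
    raw = table.intensities.astype(float).copy()
    nonpos = raw.to_numpy() <= 0
    if nonpos.any():
        if zero_policy == "reject":
            raise ValueError(f"{int(nonpos.sum())} non-positive intensities")
        if zero_policy != "impute":
            raise ValueError(f"unknown zero_policy {zero_policy!r}")
        logger.info(
            "normalize_log: imputing %d non-positive intensities with "
            "half-minimum", int(nonpos.sum()),
        )
        arr = raw.to_numpy()
        with np.errstate(invalid="ignore"):
            pos = np.where(arr > 0, arr, np.nan)
        halfmin = np.nanmin(pos, axis=0) / 2.0
        # features that are entirely non-positive get a nominal epsilon
        halfmin = np.where(np.isnan(halfmin), 1e-12, halfmin)
        arr = np.where(arr > 0, arr, halfmin[None, :])
        raw = pd.DataFrame(arr, index=raw.index, columns=raw.columns)
    # divide each feature column by the IS of its ion mode, per sample
    is_per_feature = table.internal_standards[
        table.feature_modes.to_numpy()
    ].to_numpy()
    ratio = raw.to_numpy() / is_per_feature
    values = pd.DataFrame(
        np.log2(ratio) + 5.0, index=raw.index, columns=raw.columns
    )
    return ProcessedMatrix(values)


def merge_modes(pos: ProcessedMatrix, neg: ProcessedMatrix) -> ProcessedMatrix:
    """Column-concatenate positive- and negative-mode matrices.

    Feature ids are namespaced ``pos:<id>`` / ``neg:<id>`` so the same lipid
    annotation appearing in both modes never collides.  Sample ids must
    match as sets; rows of *neg* are aligned to *pos* order.
    """
    if len(neg.values.columns) == 0:
        return ProcessedMatrix(pos.values.copy())
    if len(pos.values.columns) == 0:
        return ProcessedMatrix(neg.values.copy())
    missing = pos.sample_ids.symmetric_difference(neg.sample_ids)
    if len(missing):
        raise ValueError(f"sample mismatch between modes: {list(missing)[:5]}")
    left = pos.values.add_prefix("pos:")
    right = neg.values.reindex(pos.sample_ids).add_prefix("neg:")
    return ProcessedMatrix(pd.concat([left, right], axis=1))


def autoscale(
    fit_on: ProcessedMatrix,
    apply_to: list[ProcessedMatrix] | None = None,
) -> list[ProcessedMatrix]:
    """Unit-variance scale columns, parameters fitted on *fit_on* only.

    Constant columns in *fit_on* are dropped from every output and recorded
    in the returned matrices' :class:`~lipidsig.datatypes.ScalingParams`.
    Each matrix in *apply_to* (default ``[fit_on]``) is transformed with the
    frozen parameters; a feature present in *apply_to* but absent from the
    fit parameters raises.
    """
    if apply_to is None:
        apply_to = [fit_on]
    mean = fit_on.values.mean(axis=0)
    sd = fit_on.values.std(axis=0, ddof=1)
    constant = sd == 0
    dropped = [str(c) for c in fit_on.feature_ids[constant]]
    if dropped:
        logger.warning("autoscale: dropping %d constant columns", len(dropped))
    keep = fit_on.feature_ids[~constant]
    params = ScalingParams(
        mean=mean[keep],
        sd=sd[keep],
        fitted_on=list(map(str, fit_on.sample_ids)),
        dropped_constant=dropped,
    )
    out = []
    for m in apply_to:
        extra = m.feature_ids.difference(fit_on.feature_ids)
        if len(extra):
            raise ValueError(
                f"features absent from scaling parameters: {list(extra)[:5]}"
            )
        cols = keep.intersection(m.feature_ids)
        scaled = (m.values[cols] - params.mean[cols]) / params.sd[cols]
        out.append(ProcessedMatrix(scaled, params))
    return out


def split_cohort(
    annotations: pd.DataFrame,
    fraction: float = 0.85,
    seed: int = 0,
    stratify_by: str = "group",
) -> tuple[list[str], list[str]]:
    """Stratified random train/test partition of sample ids.

    Within each stratum the test count is ``floor((1 - fraction) * n)``, so
    a 266 GC / 266 HD cohort at 0.85 yields 227/39 per group.  Strata with
    fewer than 2 samples go entirely to train with a warning.  Deterministic
    for a fixed seed.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    idx = annotations.index if annotations.index.name else annotations.index
    rng = np.random.default_rng(seed)
    train: list[str] = []
    test: list[str] = []
    strata = annotations.groupby(stratify_by, sort=True).groups
    for _, ids in sorted(strata.items()):
        ids = sorted(map(str, ids))
        if len(ids) < 2:
            logger.warning("split_cohort: stratum with <2 samples goes to train")
            train.extend(ids)
            continue
        n_test = int(np.floor((1 - fraction) * len(ids)))
        perm = rng.permutation(len(ids))
        test.extend(ids[i] for i in perm[:n_test])
        train.extend(ids[i] for i in perm[n_test:])
    return sorted(train), sorted(test)
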