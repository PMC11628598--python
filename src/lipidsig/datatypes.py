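"""Core containers for lipidomic feature tables and sample annotations.

The package moves data through three stages:

``IntensityTable``
    Raw, strictly positive sample x lipid intensities as they come off the
    instrument software, together with per-sample internal-standard (IS)
    intensities for each ion mode and a QC flag marking pooled quality-control
    replicate injections.

``ProcessedMatrix``
    The normalized / transformed matrix used for all statistics, optionally
    carrying the autoscaling parameters (per-feature mean and SD and the ids
    of the samples they were fitted on) so that held-out cohorts can be
    scaled with frozen training parameters.

Sample annotations travel as a plain :class:`pandas.DataFrame` with the
column conventions documented in :data:`ANNOTATION_COLUMNS`;
:func:`validate_annotations` enforces them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "IntensityTable",
    "ProcessedMatrix",
    "ScalingParams",
    "ANNOTATION_COLUMNS",
    "validate_annotations",
]

#: Recognised annotation columns.  ``group`` is one of GC / HD / PL,
#: ``cohort`` one of training / testing / external / predictive, ``stage``
#: one of I / II / III / IV or missing, biomarkers are in their clinical
#: units (CEA ng/mL, CA19-9 U/mL, CA72-4 U/mL) and may be missing,
#: ``time_months`` / ``event`` describe overall survival for GC samples.
ANNOTATION_COLUMNS = (
    "sample_id",
    "group",
    "cohort",
    "stage",
    "cea",
    "ca199",
    "ca724",
    "time_months",
    "event",
)

_GROUPS = {"GC", "HD", "PL"}
_STAGES = {"I", "II", "III", "IV"}


def validate_annotations(ann: pd.DataFrame) -> pd.DataFrame:
    """Validate an annotation frame and return it indexed by sample id.

    Raises ``ValueError`` on unknown group labels, non-positive survival
    times, or event flags outside {0, 1}.
    """
    ann = ann.copy()
    if "sample_id" in ann.columns:
        ann = ann.set_index("sample_id")
    bad = set(ann["group"].dropna()) - _GROUPS
    if bad:
        raise ValueError(f"unknown group labels: {sorted(bad)}")
    if "stage" in ann.columns:
        bad = set(ann["stage"].dropna()) - _STAGES
        if bad:
            raise ValueError(f"unknown stage labels: {sorted(bad)}")
    if "time_months" in ann.columns:
        t = ann["time_months"].dropna()
        if (t <= 0).any():
            raise ValueError("survival time must be positive")
    if "event" in ann.columns:
        e = ann["event"].dropna()
        if not set(np.unique(e)) <= {0, 1, 0.0, 1.0}:
            raise ValueError("event flag must be 0/1")
    return ann


@dataclass
class IntensityTable:
    """Raw sample x feature intensity table for one or both ion modes.

    Parameters
    ----------
    intensities
        Samples in rows, lipid features in columns; strictly positive.
    feature_modes
        Maps each feature id to its ion mode (``"pos"`` or ``"neg"``).
    internal_standards
        Per-sample IS intensity, one column per ion mode; strictly positive.
    qc_flags
        Boolean per sample; True marks a pooled-QC replicate injection.
    """

    intensities: pd.DataFrame
    feature_modes: pd.Series
    internal_standards: pd.DataFrame
    qc_flags: pd.Series

    def __post_init__(self) -> None:
        self.feature_modes = self.feature_modes.reindex(self.intensities.columns)
        if self.feature_modes.isna().any():
            missing = self.feature_modes.index[self.feature_modes.isna()]
            raise ValueError(f"features without an ion mode: {list(missing)[:5]}")
        self.internal_standards = self.internal_standards.reindex(
            self.intensities.index
        )
        self.qc_flags = self.qc_flags.reindex(self.intensities.index).fillna(False)
        if (self.internal_standards.to_numpy() <= 0).any():
            raise ValueError("internal-standard intensities must be positive")
        if (self.intensities.to_numpy() < 0).any():
            raise ValueError("negative raw intensities")

    # -- convenience -------------------------------------------------
    @property
    def sample_ids(self) -> pd.Index:
        return self.intensities.index

    @property
    def feature_ids(self) -> pd.Index:
        return self.intensities.columns

    @property
    def modes(self) -> list[str]:
        return sorted(self.feature_modes.unique())

    def study_samples(self) -> "IntensityTable":
        """Table restricted to non-QC (study) samples."""
        keep = ~self.qc_flags
        return self.subset_samples(self.sample_ids[keep])

    def qc_samples(self) -> pd.DataFrame:
        """Raw intensities of the QC replicate rows only."""
        return self.intensities.loc[self.qc_flags]

    def subset_samples(self, ids: Iterable[str]) -> "IntensityTable":
        ids = pd.Index(ids)
        return IntensityTable(
            self.intensities.loc[ids],
            self.feature_modes,
            self.internal_standards.loc[ids],
            self.qc_flags.loc[ids],
        )

    def subset_features(self, ids: Sequence[str]) -> "IntensityTable":
        ids = pd.Index(ids)
        return IntensityTable(
            self.intensities[ids],
            self.feature_modes[ids],
            self.internal_standards,
            self.qc_flags,
        )

    # -- I/O ----------------------------------------------------------
    # Single CSV: feature columns plus __IS_<mode> columns and a __QC flag
    # column; the feature -> mode map rides in a JSON sidecar.
    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        out = self.intensities.copy()
        for mode in self.internal_standards.columns:
            out[f"__IS_{mode}"] = self.internal_standards[mode]
        out["__QC"] = self.qc_flags.astype(int)
        out.to_csv(path, index_label="sample_id")
        sidecar = path.with_suffix(path.suffix + ".features.json")
        sidecar.write_text(json.dumps(self.feature_modes.to_dict(), indent=0))

    @classmethod
    def from_csv(cls, path: str | Path) -> "IntensityTable":
        path = Path(path)
        df = pd.read_csv(path, index_col="sample_id")
        is_cols = [c for c in df.columns if c.startswith("__IS_")]
        internal = df[is_cols].rename(columns=lambda c: c[len("__IS_"):])
        qc = df["__QC"].astype(bool)
        feats = df.drop(columns=is_cols + ["__QC"])
        sidecar = path.with_suffix(path.suffix + ".features.json")
        modes = pd.Series(json.loads(sidecar.read_text()))
        return cls(feats, modes, internal, qc)


@dataclass
class ScalingParams:
    """Frozen per-feature autoscaling parameters with provenance."""

    mean: pd.Series
    sd: pd.Series
    fitted_on: list[str] = field(default_factory=list)
    dropped_constant: list[str] = field(default_factory=list)


@dataclass
class ProcessedMatrix:
    """Normalized (and optionally autoscaled) sample x feature matrix."""

    values: pd.DataFrame
    scaling: ScalingParams | None = None

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.columns

    def subset_samples(self, ids: Iterable[str]) -> "ProcessedMatrix":
        return ProcessedMatrix(self.values.loc[pd.Index(ids)], self.scaling)

    def subset_features(self, ids: Sequence[str]) -> "ProcessedMatrix":
        return ProcessedMatrix(self.values[pd.Index(ids)], self.scaling)

    def to_csv(self, path: str | Path) -> None:
        self.values.to_csv(path, index_label="sample_id")

    @classmethod
    def from_csv(cls, path: str | Path) -> "ProcessedMatrix":
        return cls(pd.read_csv(path, index_col="sample_id"))
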