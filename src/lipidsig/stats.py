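"""Differential abundance, stage-trend clustering and set enrichment.

Group comparisons use Student's t (pooled variance; Welch by flag) or the
paired t for pre/post-operative designs, with Benjamini-Hochberg step-up
FDR control across features.  Stage trends z-score each lipid's
stage-mean profile and cluster the shapes hierarchically (Ward,
Euclidean).  Enrichment of a selected lipid list against user-supplied
annotation sets uses the upper-tail hypergeometric test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import fcluster, linkage
from statsmodels.stats.multitest import multipletests

from .datatypes import ProcessedMatrix

__all__ = [
    "differential_abundance",
    "TrendClusters",
    "stage_trend_clusters",
    "hypergeometric_enrichment",
    "read_gmt",
]

logger = logging.getLogger(__name__)


def _frame(X) -> pd.DataFrame:
    if isinstance(X, ProcessedMatrix):
        return X.values
    return pd.DataFrame(X)


def differential_abundance(
    X,
    group_labels,
    paired_ids=None,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-feature two-group t tests with BH adjustment.

    Unpaired mode runs Student's t with pooled variance (``equal_var=False``
    switches to Welch).  Paired mode matches samples via *paired_ids* (one
    id per sample; each id must appear exactly once per group) and runs the
    paired t.  Features with zero variance and equal means get t = 0,
    p = 1, flagged degenerate.

    Returns a frame indexed by feature with group means, the mean
    difference (a log2 fold difference when the input is log2-scaled),
    t, p and BH-adjusted q.
    """
    X = _frame(X)
    groups = pd.Series(np.asarray(group_labels), index=X.index)
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {levels}")
    a = X.loc[groups == levels[0]]
    b = X.loc[groups == levels[1]]
    if paired_ids is not None:
        pid = pd.Series(np.asarray(paired_ids), index=X.index)
        ida = pid.loc[a.index]
        idb = pid.loc[b.index]
        if sorted(ida) != sorted(idb) or ida.duplicated().any():
            raise ValueError("paired mode requires a bijection between groups")
        a = a.set_index(ida.to_numpy()).sort_index()
        b = b.set_index(idb.to_numpy()).sort_index()
        t, p = sps.ttest_rel(b.to_numpy(), a.to_numpy(), axis=0)
    else:
        t, p = sps.ttest_ind(
            b.to_numpy(), a.to_numpy(), axis=0, equal_var=equal_var
        )
    mean_a = a.mean(axis=0).to_numpy()
    mean_b = b.mean(axis=0).to_numpy()
    degenerate = np.isnan(t)
    if degenerate.any():
        logger.info(
            "differential_abundance: %d zero-variance features set to p=1",
            int(degenerate.sum()),
        )
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)
    q = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            f"mean_{levels[0]}": mean_a,
            f"mean_{levels[1]}": mean_b,
            "log2_fd": mean_b - mean_a,
            "t": t,
            "p": p,
            "q": q,
            "degenerate": degenerate,
        },
        index=X.columns,
    )


@dataclass
class TrendClusters:
    """Stage-mean shape profiles and their cluster assignment."""

    profiles: pd.DataFrame   # features x stages, z-scored across stages
    clusters: pd.Series      # feature -> 1..k
    excluded: list[str]      # stage-constant features
    linkage_matrix: np.ndarray


def stage_trend_clusters(X, stages, k: int = 3) -> TrendClusters:
    """Cluster lipids by the shape of their mean profile across pTNM stages.

    Stage means are z-scored per feature across stages (shape, not
    magnitude) and clustered hierarchically (Euclidean, Ward) with the
    tree cut at *k*.  Stage-constant features are excluded with a flag.
    Requires >= 2 stages with >= 2 samples each.
    """
    X = _frame(X)
    stages = pd.Series(np.asarray(stages, dtype=object), index=X.index)
    counts = stages.value_counts()
    if (counts >= 2).sum() < 2:
        raise ValueError("need >= 2 stages with >= 2 samples each")
    means = X.groupby(stages, sort=True).mean().T  # features x stages
    sd = means.std(axis=1, ddof=0)
    constant = sd == 0
    excluded = [str(f) for f in means.index[constant]]
    if excluded:
        logger.info("stage_trend_clusters: %d constant profiles excluded",
                    len(excluded))
    prof = means.loc[~constant]
    z = prof.sub(prof.mean(axis=1), axis=0).div(sd[~constant], axis=0)
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(z) == 0:
        raise ValueError("no non-constant stage profiles")
    if len(z) == 1:
        Z = np.empty((0, 4))
        labels = np.array([1])
    else:
        Z = linkage(z.to_numpy(), method="ward", metric="euclidean")
        labels = fcluster(Z, min(k, len(z)), criterion="maxclust")
    return TrendClusters(
        z, pd.Series(labels, index=z.index, name="cluster"), excluded, Z
    )


def hypergeometric_enrichment(
    selected,
    annotation_sets: dict[str, list[str]],
    universe,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of *selected* in each set.

    p = P(overlap >= observed) drawing |selected| items from a universe of
    size |universe| containing |set| marked items; BH adjustment across
    sets.  Set members outside the universe are trimmed with a warning;
    selected ids must all lie in the universe.
    """
    universe = set(map(str, universe))
    if not universe:
        raise ValueError("empty universe")
    selected = set(map(str, selected))
    stray = selected - universe
    if stray:
        raise ValueError(f"selected ids outside universe: {sorted(stray)[:5]}")
    rows = []
    for name, members in annotation_sets.items():
        members = set(map(str, members))
        trimmed = members - universe
        if trimmed:
            logger.warning(
                "enrichment: trimming %d ids of set %r outside universe",
                len(trimmed), name,
            )
            members &= universe
        overlap = len(members & selected)
        p = float(
            sps.hypergeom.sf(
                overlap - 1, len(universe), len(members), len(selected)
            )
        )
        rows.append(
            {
                "set": name,
                "overlap": overlap,
                "set_size": len(members),
                "selected_size": len(selected),
                "universe_size": len(universe),
                "p": min(p, 1.0),
            }
        )
    out = pd.DataFrame(rows).set_index("set")
    out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read GMT-style annotation sets: name <tab> description <tab> ids..."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:50]!r}")
        sets[parts[0]] = [p for p in parts[2:] if p]
    return sets
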