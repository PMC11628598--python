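"""Monti-style consensus clustering for metabolic subtype discovery.

Stability-based clustering: repeatedly subsample the samples, run a base
clusterer (hierarchical Ward linkage by default; Pearson/average as an
option) at each candidate K, and record for every pair of samples the
fraction of co-sampled replicates in which they land in the same cluster.
A clean K yields a near-binary consensus matrix; K is chosen by the
largest relative increase in the area under the consensus CDF
(delta-area), with the proportion of ambiguous clustering (PAC, the CDF
mass between 0.1 and 0.9) reported as a confidence diagnostic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = ["ConsensusModel", "consensus_cluster", "choose_k"]

logger = logging.getLogger(__name__)

#: PAC above this at the chosen K flags a low-confidence structure.
PAC_WARN = 0.3


@dataclass
class ConsensusModel:
    """Consensus matrices over a K range plus the labelling machinery."""

    sample_ids: list[str]
    k_range: list[int]
    consensus: dict[int, np.ndarray]
    reps: int
    subsample: float
    base: str
    seed: int

    def labels(self, k: int) -> pd.Series:
        """Cluster labels at K, from hierarchical clustering of 1 - consensus."""
        m = self.consensus[k]
        dist = squareform(1.0 - m, checks=False)
        lab = fcluster(linkage(dist, method="average"), k, criterion="maxclust")
        return pd.Series(lab, index=self.sample_ids, name="cluster")

    def pac(self, k: int, lower: float = 0.1, upper: float = 0.9) -> float:
        """Proportion of ambiguous clustering at K (off-diagonal entries)."""
        m = self.consensus[k]
        tri = m[np.triu_indices_from(m, k=1)]
        return float(np.mean((tri > lower) & (tri < upper)))


def _pairwise_corr_distance(X: np.ndarray) -> np.ndarray:
    c = np.corrcoef(X)
    # constant rows produce NaN correlations; treat them as uncorrelated
    c = np.nan_to_num(c, nan=0.0)
    np.fill_diagonal(c, 1.0)
    return 1.0 - c


def consensus_cluster(
    X,
    k_range=range(2, 7),
    reps: int = 1000,
    subsample: float = 0.8,
    seed: int = 0,
    base: str = "ward",
) -> ConsensusModel:
    """Resampled consensus clustering of samples (rows of X).

    Each replicate subsamples ``floor(subsample * n)`` samples without
    replacement, clusters them with the base clusterer, and cuts the tree
    at every K in *k_range*.  Consensus_ij is the co-clustering count
    divided by the co-sampling count; the diagonal is 1.

    ``base="ward"`` (default) is hierarchical Ward linkage on Euclidean
    distance — compact, variance-minimising clusters.  ``base="average"``
    is average linkage on 1 - Pearson correlation; it is a common
    consensus-clustering configuration but prone to chaining (peeling off
    singleton outliers instead of splitting the data) on noisy matrices.
    """
    if reps < 10:
        raise ValueError("need >= 10 resampling replicates")
    if isinstance(X, pd.DataFrame):
        ids = list(map(str, X.index))
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(getattr(X, "values", X), dtype=float)
        ids = list(map(str, getattr(X, "sample_ids", range(len(Xa)))))
        if hasattr(X, "values") and hasattr(X.values, "index"):
            ids = list(map(str, X.values.index))
    n = Xa.shape[0]
    if n < 10:
        raise ValueError("need >= 10 samples")
    k_range = [int(k) for k in k_range if k < n]
    rng = np.random.default_rng(seed)
    m = max(2, int(np.floor(subsample * n)))
    co_sampled = np.zeros((n, n))
    co_clustered = {k: np.zeros((n, n)) for k in k_range}
    if base not in ("ward", "average"):
        raise ValueError(f"unknown base clusterer {base!r}")
    for _ in range(reps):
        idx = rng.choice(n, size=m, replace=False)
        co_sampled[np.ix_(idx, idx)] += 1.0
        if base == "ward":
            Z = linkage(Xa[idx], method="ward")
        else:
            dist = squareform(_pairwise_corr_distance(Xa[idx]), checks=False)
            Z = linkage(dist, method="average")
        for k in k_range:
            lab = fcluster(Z, k, criterion="maxclust")
            same = lab[:, None] == lab[None, :]
            co_clustered[k][np.ix_(idx, idx)] += same
    consensus = {}
    with np.errstate(invalid="ignore"):
        for k in k_range:
            c = np.where(co_sampled > 0, co_clustered[k] / co_sampled, 0.0)
            np.fill_diagonal(c, 1.0)
            consensus[k] = c
    return ConsensusModel(
        ids, k_range, consensus, reps, subsample, base, seed
    )


def _cdf_area(values: np.ndarray) -> float:
    """Area under the empirical CDF of consensus entries on [0, 1]."""
    x = np.sort(values)
    # A = integral of CDF = sum over sorted points of (x_{i+1}-x_i) * F(x_i)
    grid = np.concatenate([x, [1.0]])
    F = np.arange(1, len(x) + 1) / len(x)
    return float(np.sum(np.diff(grid) * F))


def choose_k(model: ConsensusModel) -> tuple[int, dict]:
    """Pick K by delta-area among the unambiguously clustered K values.

    delta(k_min) is the CDF area itself; for larger K it is the relative
    increase over the previous K.  The argmax is taken over K values whose
    PAC is at most ``PAC_WARN``; if none qualifies (a single homogeneous
    blob) the smallest K is returned with a low-confidence flag.
    Diagnostics carry per-K areas, deltas and PAC.
    """
    if len(model.k_range) < 2:
        raise ValueError("evaluate at least two values of K")
    areas = {}
    for k in model.k_range:
        m = model.consensus[k]
        areas[k] = _cdf_area(m[np.triu_indices_from(m, k=1)])
    ks = sorted(areas)
    deltas = {ks[0]: areas[ks[0]]}
    for prev, k in zip(ks, ks[1:]):
        deltas[k] = (areas[k] - areas[prev]) / areas[prev] if areas[prev] > 0 else 0.0
    pac = {k: model.pac(k) for k in ks}
    # the raw delta-area argmax is biased toward the smallest K (its delta
    # is the full area), so restrict candidates to K values whose consensus
    # is unambiguous (PAC at or below the warning level) before taking the
    # argmax; with no confident K (e.g. a single homogeneous blob) fall
    # back to the smallest K evaluated, flagged low-confidence
    confident = [k for k in ks if pac[k] <= PAC_WARN]
    low_confidence = not confident
    if confident:
        chosen = max(confident, key=lambda k: deltas[k])
    else:
        chosen = ks[0]
        logger.warning(
            "choose_k: min PAC=%.2f, no confident structure; falling back "
            "to K=%d", min(pac.values()), chosen,
        )
    return chosen, {
        "areas": areas,
        "deltas": deltas,
        "pac": pac,
        "low_confidence": low_confidence,
    }
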