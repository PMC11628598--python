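"""Correlation-redundancy pruning of a ranked lipid list.

Untargeted lipidomes are highly redundant (co-regulated species within a
lipid class), so a VIP ranking alone yields near-duplicate panels.  The
selection rule walks the ranking once: the top lipid is always included,
and each subsequent lipid enters only if its Spearman correlation with
every already-included lipid is below the threshold (0.5 by default, on
the absolute value — redundancy is sign-symmetric).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ProcessedMatrix

__all__ = ["SelectedPanel", "spearman_matrix", "stepwise_decorrelate"]


@dataclass
class SelectedPanel:
    """Result of the stepwise decorrelation pass."""

    selected: list[str]
    threshold: float
    #: (candidate, blocking feature already in the panel, their SCC)
    rejections: list[tuple[str, str, float]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.selected)


def spearman_matrix(X) -> pd.DataFrame:
    """Pairwise Spearman rank correlation between features (columns).

    Uses average ranks for ties.  Constant features yield NaN rows/columns
    (flagged undefined); the diagonal is set to exactly 1 for non-constant
    features.  Requires at least 3 samples.
    """
    if isinstance(X, ProcessedMatrix):
        X = X.values
    X = pd.DataFrame(X)
    if X.shape[0] < 3:
        raise ValueError("need >= 3 samples for a rank correlation")
    arr = X.to_numpy(dtype=float)
    if X.shape[1] == 1:
        rho = np.ones((1, 1))
    elif X.shape[1] == 2:
        r = float(stats.spearmanr(arr[:, 0], arr[:, 1]).statistic)
        rho = np.array([[1.0, r], [r, 1.0]])
    else:
        rho = np.atleast_2d(stats.spearmanr(arr).statistic)
    constant = arr.std(axis=0) == 0
    rho[constant, :] = np.nan
    rho[:, constant] = np.nan
    np.fill_diagonal(rho, np.where(constant, np.nan, 1.0))
    return pd.DataFrame(rho, index=X.columns, columns=X.columns)


def stepwise_decorrelate(
    ranking: list[str],
    corr: pd.DataFrame,
    threshold: float = 0.5,
    max_panel: int | None = None,
    signed: bool = False,
) -> SelectedPanel:
    """Greedy single pass over *ranking*, keeping mutually decorrelated lipids.

    A candidate is included iff its correlation with every already-included
    lipid is below *threshold* (absolute value unless ``signed=True``).  A
    candidate whose correlation with an included lipid is undefined (NaN,
    e.g. a constant feature) is rejected with that reason.  Stops once
    *max_panel* lipids are selected.
    """
    missing = [f for f in ranking if f not in corr.index]
    if missing:
        raise KeyError(f"ranking ids absent from correlation matrix: {missing[:5]}")
    panel: list[str] = []
    rejections: list[tuple[str, str, float]] = []
    for f in ranking:
        if max_panel is not None and len(panel) >= max_panel:
            break
        blocked = None
        for g in panel:
            rho = corr.at[f, g]
            if np.isnan(rho):
                blocked = (g, float("nan"))
                break
            val = rho if signed else abs(rho)
            if val >= threshold:
                blocked = (g, float(rho))
                break
        if blocked is None:
            panel.append(f)
        else:
            rejections.append((f, blocked[0], blocked[1]))
    return SelectedPanel(panel, threshold, rejections)
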