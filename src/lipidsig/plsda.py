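"""PLS-DA fitting and VIP-score feature ranking.

Partial least squares discriminant analysis is PLS1 regression on a
mean-centered +/-1 class coding, fitted by NIPALS with deflation.  Feature
importance is the standard Wold VIP,

    VIP_k = sqrt( p * sum_a SSY_a * w_ak^2 / sum_a SSY_a ),

where ``w_a`` are the unit-norm component weights and ``SSY_a`` the
response variance explained by component ``a`` (``q_a^2 t_a' t_a``).  The
normalization implies ``sum_k VIP_k^2 = p``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import ProcessedMatrix

__all__ = ["PlsdaModel", "fit_plsda", "vip_scores", "rank_by_vip"]


@dataclass
class PlsdaModel:
    """Fitted PLS1 discriminant model.

    ``weights`` (p x A) have unit columns; ``scores`` (n x A) are mutually
    orthogonal; ``ssy`` holds per-component explained response variance.
    """

    feature_ids: list[str]
    weights: np.ndarray
    scores: np.ndarray
    loadings: np.ndarray
    q: np.ndarray
    ssy: np.ndarray
    x_mean: np.ndarray
    y_mean: float

    @property
    def n_components(self) -> int:
        return self.weights.shape[1]

    def explained_y_variance(self) -> np.ndarray:
        total = self.ssy.sum()
        return self.ssy / total if total > 0 else self.ssy


def _as_array(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, ProcessedMatrix):
        return X.values.to_numpy(dtype=float), list(map(str, X.feature_ids))
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(map(str, X.columns))
    X = np.asarray(X, dtype=float)
    return X, [f"x{i}" for i in range(X.shape[1])]


def fit_plsda(X, y, n_components: int = 2) -> PlsdaModel:
    """Fit PLS-DA by NIPALS on a centered +/-1 response.

    *X* should already be column-scaled (it is centered here regardless);
    *y* is any binary labelling.  ``n_components`` must not exceed
    ``min(n - 1, p)``.  For a univariate response each NIPALS component has
    the closed form ``w = X'y / ||X'y||`` and the algorithm is exactly
    deterministic.
    """
    Xa, feature_ids = _as_array(X)
    n, p = Xa.shape
    classes = np.unique(np.asarray(y))
    if classes.size != 2:
        raise ValueError(f"y must have exactly 2 classes, got {classes.size}")
    if n_components > min(n - 1, p):
        raise ValueError("n_components exceeds min(n - 1, p)")
    yv = np.where(np.asarray(y) == classes[1], 1.0, -1.0)
    y_mean = yv.mean()
    f = yv - y_mean
    x_mean = Xa.mean(axis=0)
    E = Xa - x_mean

    W = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    P = np.zeros((p, n_components))
    q = np.zeros(n_components)
    ssy = np.zeros(n_components)
    for a in range(n_components):
        w = E.T @ f
        norm = np.linalg.norm(w)
        if norm < 1e-12:
            raise FloatingPointError(
                f"NIPALS degenerate at component {a + 1}: X'y vanished "
                f"(residual y variance {f @ f:.3e})"
            )
        w /= norm
        t = E @ w
        tt = t @ t
        qa = (t @ f) / tt
        pa = (E.T @ t) / tt
        E = E - np.outer(t, pa)
        f = f - qa * t
        W[:, a], T[:, a], P[:, a], q[a] = w, t, pa, qa
        ssy[a] = qa**2 * tt
    return PlsdaModel(feature_ids, W, T, P, q, ssy, x_mean, y_mean)


def vip_scores(model: PlsdaModel, components: int | None = None) -> pd.Series:
    """Wold VIP per feature, over all components or the leading *components*.

    Restricting to ``components=1`` reproduces the component-1-contribution
    reading of the ranking.
    """
    A = model.n_components if components is None else components
    if not 1 <= A <= model.n_components:
        raise ValueError("components out of range")
    ssy = model.ssy[:A]
    if ssy.sum() <= 0:
        raise FloatingPointError("all components explain zero response variance")
    W2 = model.weights[:, :A] ** 2
    p = len(model.feature_ids)
    vip = np.sqrt(p * (W2 @ ssy) / ssy.sum())
    return pd.Series(vip, index=model.feature_ids, name="VIP")


def rank_by_vip(vip: pd.Series, top_n: int | None = 50) -> list[str]:
    """Feature ids in descending VIP order, ties broken by ascending id.

    Truncated at *top_n* (clamped to the number of features).
    """
    order = sorted(vip.index, key=lambda k: (-vip[k], str(k)))
    return [str(k) for k in (order if top_n is None else order[:top_n])]
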