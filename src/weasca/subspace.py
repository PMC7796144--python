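"""PCA sub-models of effect matrices and residual-augmented score plots.

Each effect matrix is summarized by a separate PCA: scores ``T_f`` and
orthonormal loadings ``P_f`` come from the singular value decomposition of
the effect matrix itself, without further centering (weighted-effect
contributions are column-centered by construction; deviation-coded
contributions on unbalanced data may not be, and are deliberately left as
estimated).  An effect of a factor with ``alpha`` levels has rank at most
``alpha - 1``, so at most that many nonzero components exist.

Score plots are augmented with the residual: projecting
``Con_f + residual`` onto the loadings scatters the observations around the
level scores, which makes the within-level spread visible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SubModel",
    "AugmentedScores",
    "fit_effect_submodel",
    "augmented_scores",
    "whole_data_pca",
]

_RANK_RTOL = 1e-12


@dataclass
class SubModel:
    """PCA of a single effect matrix.

    ``explained_percent`` holds each retained component's share of the
    effect matrix's squared Frobenius norm (percent); entries beyond the
    numerical rank are exactly zero and counted in ``n_zero_variance``.
    """

    term: str | None
    scores: np.ndarray  # (n, k)
    loadings: np.ndarray  # (m, k)
    singular_values: np.ndarray  # (k,)
    explained_percent: np.ndarray  # (k,)
    k: int
    rank: int
    total_ss: float

    @property
    def n_zero_variance(self) -> int:
        """Retained components beyond the matrix rank (zero variance)."""
        return max(self.k - self.rank, 0)


@dataclass
class AugmentedScores:
    """Residual-augmented score points with per-level summaries."""

    points: np.ndarray  # (n, k)
    group_means: dict[str, np.ndarray] = field(default_factory=dict)
    group_covariances: dict[str, np.ndarray] = field(default_factory=dict)


def fit_effect_submodel(con, k: int | None = None, term: str | None = None) -> SubModel:
    """Fit a PCA sub-model to one effect matrix via its SVD.

    Parameters
    ----------
    con
        Effect matrix (n x m) from a decomposition; used as-is.
    k
        Number of components to retain; defaults to the numerical rank.
        Components beyond the rank are returned with zero scores and
        variance (see :attr:`SubModel.n_zero_variance`).
    """
    C = np.asarray(getattr(con, "values", con), dtype=float)
    if C.ndim != 2:
        raise ValueError("effect matrix must be 2-D")
    n, m = C.shape
    U, s, Vt = np.linalg.svd(C, full_matrices=False)
    rank = int(np.sum(s > _RANK_RTOL * max(s[0], 1.0))) if s.size else 0
    if k is None:
        k = max(rank, 1)
    if not 1 <= k <= min(n, m):
        raise ValueError(f"k={k} outside [1, min(n, m)={min(n, m)}]")
    U, s, Vt = U[:, :k], s[:k].copy(), Vt[:k, :]
    s[rank:] = 0.0
    # deterministic sign: largest-magnitude loading entry positive
    for j in range(k):
        pivot = np.argmax(np.abs(Vt[j]))
        if Vt[j, pivot] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    total = float(np.sum(np.square(C)))
    shares = (
        100.0 * np.square(s) / total if total > 0 else np.zeros_like(s)
    )
    return SubModel(
        term=term,
        scores=U * s,
        loadings=Vt.T,
        singular_values=s,
        explained_percent=shares,
        k=k,
        rank=rank,
        total_ss=total,
    )


def augmented_scores(
    sm: SubModel, con, residual, labels=None
) -> AugmentedScores:
    """Project ``con + residual`` onto the sub-model loadings.

    One point per observation; with residual zero the points coincide with
    the sub-model scores.  If per-observation ``labels`` are given, group
    means (the bold points of a score plot) and group covariance matrices
    (the ellipses) are attached.
    """
    C = np.asarray(getattr(con, "values", con), dtype=float)
    R = np.asarray(getattr(residual, "values", residual), dtype=float)
    if C.shape != R.shape:
        raise ValueError(
            f"effect matrix {C.shape} and residual {R.shape} differ in shape"
        )
    if C.shape[1] != sm.loadings.shape[0]:
        raise ValueError(
            f"matrices have {C.shape[1]} features but loadings have "
            f"{sm.loadings.shape[0]}"
        )
    points = (C + R) @ sm.loadings
    out = AugmentedScores(points=points)
    if labels is not None:
        labels = np.asarray(labels)
        if labels.shape[0] != points.shape[0]:
            raise ValueError("labels length does not match observations")
        for lev in dict.fromkeys(labels.tolist()):
            pts = points[labels == lev]
            out.group_means[lev] = pts.mean(axis=0)
            out.group_covariances[lev] = (
                np.cov(pts, rowvar=False)
                if pts.shape[0] > 1
                else np.zeros((points.shape[1], points.shape[1]))
            )
    return out


def whole_data_pca(X, k: int = 2) -> SubModel:
    """PCA of the mean-centered response matrix (the "all data" summary).

    Shares are percentages of ``||X - M0||^2`` and do not depend on any
    coding scheme.
    """
    Xm = np.asarray(getattr(X, "values", X), dtype=float)
    centered = Xm - Xm.mean(axis=0, keepdims=True)
    return fit_effect_submodel(centered, k=k, term="all-data")
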