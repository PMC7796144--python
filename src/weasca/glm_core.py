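"""Multivariate general linear model fitting and effect decomposition.

The response matrix ``X`` (n observations x m features) is decomposed into

    X = M0 + sum_f Con_f + E

where ``M0`` is the intercept contribution, ``Con_f`` the effect matrix of
term ``f`` (constant within the design cells of that term) and ``E`` the
residual.  For the GLM route the parameter matrix is estimated by ordinary
least squares on a coded design matrix and each ``Con_f`` is the product of
the term's sub-design matrix with the full parameter matrix.  The classical
(cell-mean) ASCA estimator is also provided; on balanced designs the two
routes coincide.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design_coding import (
    DesignMatrix,
    FactorDesign,
    ModelSpec,
    build_design_matrix,
    sub_design_matrix,
    term_name,
)

__all__ = [
    "AliasedDesignError",
    "EffectDecomposition",
    "fit_glm",
    "decompose",
    "classical_asca_decompose",
]


class AliasedDesignError(np.linalg.LinAlgError):
    """The design matrix is rank deficient (aliased or over-parameterized)."""


@dataclass
class EffectDecomposition:
    """Additive decomposition of a response matrix into effect matrices.

    Attributes
    ----------
    M0 : (n, m) intercept contribution.
    contributions : mapping term name -> (n, m) effect matrix.
    residual : (n, m) residual matrix.
    beta_hat : (p, m) parameter matrix (``None`` for the cell-mean route).
    scheme : coding scheme tag (``"classical"`` for cell means).
    model : the fitted :class:`ModelSpec`.
    """

    M0: np.ndarray
    contributions: dict[str, np.ndarray]
    residual: np.ndarray
    beta_hat: np.ndarray | None
    scheme: str
    model: ModelSpec
    design_matrix: DesignMatrix | None = None

    @property
    def n(self) -> int:
        return self.M0.shape[0]

    @property
    def m(self) -> int:
        return self.M0.shape[1]

    def fitted(self) -> np.ndarray:
        return self.M0 + sum(self.contributions.values())

    def reconstruction(self) -> np.ndarray:
        """``M0 + sum_f Con_f + residual`` — equals X up to round-off."""
        return self.fitted() + self.residual


def _as_matrix(X) -> np.ndarray:
    arr = np.asarray(getattr(X, "values", X), dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.ndim != 2:
        raise ValueError(f"response must be 2-D, got shape {arr.shape}")
    return arr


def fit_glm(
    X, dm: DesignMatrix, allow_singular: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Ordinary least squares fit of ``X`` on a coded design matrix.

    Returns ``(beta_hat, residual)`` with ``beta_hat`` of shape (p, m) and
    ``residual = X - dm @ beta_hat``.  The solve uses a rank-revealing
    orthogonal decomposition rather than explicit normal-equation
    inversion.

    Raises
    ------
    AliasedDesignError
        If the design matrix has linearly dependent columns (or fewer rows
        than columns) and ``allow_singular`` is not set, since per-term
        contributions are then not uniquely estimable.
    """
    Xm = _as_matrix(X)
    D = dm.values
    if Xm.shape[0] != D.shape[0]:
        raise ValueError(
            f"response has {Xm.shape[0]} rows but design matrix has {D.shape[0]}"
        )
    rank = np.linalg.matrix_rank(D)
    if rank < D.shape[1] and not allow_singular:
        raise AliasedDesignError(
            f"aliased design: matrix has {D.shape[1]} columns but rank "
            f"{rank}; effect estimates are not unique "
            "(pass allow_singular=True to force a minimum-norm solution)"
        )
    beta_hat, *_ = np.linalg.lstsq(D, Xm, rcond=None)
    residual = Xm - D @ beta_hat
    return beta_hat, residual


def decompose(
    X,
    design: FactorDesign,
    model: ModelSpec,
    allow_singular: bool = False,
) -> EffectDecomposition:
    """GLM effect decomposition under the model's coding scheme.

    ``Con_f`` is the term's sub-design matrix (all other columns zeroed)
    times the full parameter matrix; ``M0`` is the intercept column times
    the intercept row of the parameter matrix.
    """
    dm = build_design_matrix(design, model)
    beta_hat, residual = fit_glm(X, dm, allow_singular=allow_singular)
    M0 = dm.values[:, :1] @ beta_hat[:1, :]
    contributions = {}
    for t in model.terms:
        name = term_name(t)
        sub = sub_design_matrix(dm, name)
        contributions[name] = sub.values @ beta_hat
    return EffectDecomposition(
        M0=M0,
        contributions=contributions,
        residual=residual,
        beta_hat=beta_hat,
        scheme=model.coding,
        model=model,
        design_matrix=dm,
    )


def _level_means(Xm: np.ndarray, labels: np.ndarray) -> dict[str, np.ndarray]:
    return {
        lev: Xm[labels == lev].mean(axis=0) for lev in np.unique(labels)
    }


def classical_asca_decompose(
    X, design: FactorDesign, model: ModelSpec
) -> EffectDecomposition:
    """Cell-mean (classical ASCA) decomposition.

    Main-effect rows are the level mean minus the grand mean; interaction
    rows are the cell mean minus both level means plus the grand mean,
    using plain observation averages regardless of balance.  On unbalanced
    designs the resulting effect matrices are generally not orthogonal and
    their naive percentages of variance can sum to more than 100%.
    """
    Xm = _as_matrix(X)
    if Xm.shape[0] != design.n:
        raise ValueError("response rows do not match design")
    grand = Xm.mean(axis=0)
    M0 = np.tile(grand, (design.n, 1))
    contributions: dict[str, np.ndarray] = {}
    for t in model.terms:
        name = term_name(t)
        con = np.empty_like(Xm)
        if len(t) == 1:
            labels = design.labels(t[0])
            means = _level_means(Xm, labels)
            for lev, mu in means.items():
                con[labels == lev] = mu - grand
        else:
            la = design.labels(t[0])
            lb = design.labels(t[1])
            means_a = _level_means(Xm, la)
            means_b = _level_means(Xm, lb)
            cells = design.cell_counts(t[0], t[1])
            for (p, q), cnt in cells.items():
                if cnt == 0:
                    raise ValueError(
                        f"empty design cell ({t[0]}={p}, {t[1]}={q}) in "
                        f"classical decomposition of {name}"
                    )
                mask = (la == p) & (lb == q)
                cell_mean = Xm[mask].mean(axis=0)
                con[mask] = cell_mean - means_a[p] - means_b[q] + grand
        contributions[name] = con
    residual = Xm - M0 - sum(contributions.values())
    return EffectDecomposition(
        M0=M0,
        contributions=contributions,
        residual=residual,
        beta_hat=None,
        scheme="classical",
        model=model,
        design_matrix=None,
    )
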