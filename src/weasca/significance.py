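"""Permutation tests for effect significance.

The observed statistic of a term is the Frobenius sum of squares of the
leading ``l`` score columns of its PCA sub-model (with ``l = "all"`` this
equals the squared Frobenius norm of the effect matrix itself).  Rows of
the response matrix are then randomly permuted against the fixed design
``N`` times, the decomposition is recomputed under the same coding scheme,
and the p-value is the fraction of permuted statistics at least as large as
the observed one:

    p(f) = #{ SS_r(f) >= SS(f) } / N .

The observed dataset is not counted among the permutations, so p = 0 is
attainable.  Because the design is fixed, the per-term effect matrix of a
permuted response is a fixed linear map applied to the permuted rows; the
map is precomputed once, which makes the loop a single matrix product per
permutation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design_coding import (
    FactorDesign,
    ModelSpec,
    build_design_matrix,
    sub_design_matrix,
    term_name,
)
from .glm_core import _as_matrix, fit_glm
from .subspace import fit_effect_submodel

__all__ = ["PermutationResult", "permutation_test"]


@dataclass
class PermutationResult:
    term: str
    observed_ss: float
    null_ss: np.ndarray  # (N,)
    p_value: float
    n_permutations: int
    n_components: int | str
    seed: int | None
    scheme: str


def _score_ss(con: np.ndarray, l: int | str) -> float:
    """Sum of squares of the first ``l`` PCA score columns of ``con``."""
    if l == "all":
        return float(np.sum(np.square(con)))
    sm = fit_effect_submodel(con, k=min(l, min(con.shape)))
    return float(np.sum(np.square(sm.singular_values)))


def permutation_test(
    X,
    design: FactorDesign,
    model: ModelSpec,
    term,
    n_permutations: int = 1000,
    n_components: int | str = "all",
    seed: int | None = None,
) -> PermutationResult:
    """Test whether ``term`` contributes non-randomly to the design.

    Parameters
    ----------
    n_permutations
        Number of random whole-row permutations of X (N >= 1).
    n_components
        ``"all"`` (default) uses every nonzero component, equivalent to the
        effect matrix's squared Frobenius norm; an integer restricts the
        statistic to the leading components of the PCA sub-model.
    seed
        Seeds a dedicated generator; identical seeds give identical
        results.
    """
    if n_permutations < 1:
        raise ValueError(f"n_permutations must be >= 1, got {n_permutations}")
    if n_components != "all" and (
        not isinstance(n_components, (int, np.integer)) or n_components < 1
    ):
        raise ValueError(f"n_components must be 'all' or a positive int")
    name = term if isinstance(term, str) else term_name(tuple(term))
    if name not in model.term_names:
        raise KeyError(f"term {name!r} not in model {model.formula()!r}")
    Xm = _as_matrix(X)
    dm = build_design_matrix(design, model)
    # effect map: Con_f = (BD/f) beta_hat with beta_hat linear in X
    beta_hat, _ = fit_glm(Xm, dm)  # full-rank check happens here
    sub = sub_design_matrix(dm, name).values
    solver = np.linalg.pinv(dm.values)  # p x n, reused for every permutation
    effect_map = sub @ solver  # n x n
    observed = _score_ss(effect_map @ Xm, n_components)
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for r in range(n_permutations):
        perm = rng.permutation(Xm.shape[0])
        null[r] = _score_ss(effect_map @ Xm[perm], n_components)
    # permutations that merely relabel within levels reproduce the observed
    # statistic up to round-off; a relative tolerance keeps such exact ties
    # on the >= side, as in the statistic's definition
    tol = 1e-9 * observed + 1e-12
    p = float(np.count_nonzero(null >= observed - tol)) / n_permutations
    return PermutationResult(
        term=name,
        observed_ss=observed,
        null_ss=null,
        p_value=p,
        n_permutations=n_permutations,
        n_components=n_components,
        seed=seed,
        scheme=model.coding,
    )
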