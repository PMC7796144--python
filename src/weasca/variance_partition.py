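"""Percentage-of-variance tables for effect decompositions.

Two estimators are provided.  The *type III* route measures a term's sum of
squares as the increase in residual sum of squares when that term alone is
dropped from the full model (all other terms retained, including an
interaction whose main effect is removed), so each effect is evaluated
after all others have been accounted for.  The *naive* route uses the
squared Frobenius norm of the effect matrix itself, which is the classical
ASCA partition; on unbalanced designs the naive percentages of
non-orthogonal effect matrices may sum to more than 100.

Both express percentages against the corrected total sum of squares
``||X - M0||^2`` with ``M0`` the column-mean matrix, so numbers are
comparable across coding schemes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design_coding import FactorDesign, ModelSpec, build_design_matrix
from .glm_core import EffectDecomposition, _as_matrix, fit_glm

__all__ = [
    "VariancePartition",
    "type3_percent_variance",
    "naive_percent_variance",
]


def _fro2(A: np.ndarray) -> float:
    return float(np.sum(np.square(A)))


def _pct(ss: float, total: float) -> float:
    # a response with zero corrected variance has nothing to partition
    return 100.0 * ss / total if total > 0 else 0.0


@dataclass
class VariancePartition:
    """Per-term sums of squares and percentages of variance.

    ``total_ss`` is the corrected total ``||X - M0||^2`` (column-mean M0).
    ``sum_percent`` adds every effect percentage plus the residual
    percentage; it equals 100 on balanced designs but not in general.
    """

    terms: list[str]
    ss: dict[str, float]
    percent: dict[str, float]
    residual_ss: float
    residual_percent: float
    total_ss: float
    method: str
    scheme: str

    @property
    def sum_percent(self) -> float:
        return float(sum(self.percent.values()) + self.residual_percent)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"term": t, "ss": self.ss[t], "percent": self.percent[t]}
            for t in self.terms
        ]
        rows.append(
            {
                "term": "residual",
                "ss": self.residual_ss,
                "percent": self.residual_percent,
            }
        )
        rows.append(
            {"term": "sum", "ss": self.total_ss, "percent": self.sum_percent}
        )
        return pd.DataFrame(rows)


def corrected_total_ss(X) -> float:
    """``||X - M0||^2`` with column-mean ``M0``."""
    Xm = _as_matrix(X)
    return _fro2(Xm - Xm.mean(axis=0, keepdims=True))


def type3_percent_variance(
    X, design: FactorDesign, model: ModelSpec
) -> VariancePartition:
    """Type III variance partition by reduced-model refits.

    For each term f the model is refit without f's columns and
    ``SS(f) = ||E_f||^2 - ||E||^2``; the percentage is ``SS(f)`` over the
    corrected total sum of squares, times 100.
    """
    Xm = _as_matrix(X)
    dm = build_design_matrix(design, model)
    _, residual = fit_glm(Xm, dm)
    rss_full = _fro2(residual)
    total = corrected_total_ss(Xm)
    ss: dict[str, float] = {}
    percent: dict[str, float] = {}
    for name in model.term_names:
        reduced = dm.drop_block(name)
        _, res_reduced = fit_glm(Xm, reduced)
        # clip tiny negative round-off: RSS can only grow when columns drop
        ss_f = max(_fro2(res_reduced) - rss_full, 0.0)
        ss[name] = ss_f
        percent[name] = _pct(ss_f, total)
    return VariancePartition(
        terms=list(model.term_names),
        ss=ss,
        percent=percent,
        residual_ss=rss_full,
        residual_percent=_pct(rss_full, total),
        total_ss=total,
        method="type3",
        scheme=model.coding,
    )


def naive_percent_variance(dec: EffectDecomposition) -> VariancePartition:
    """Norm-ratio partition: ``%Var_f = ||Con_f||^2 / ||X - M0||^2 * 100``.

    This is the partition classical ASCA reports; it is exact on balanced
    designs (where effect matrices are mutually orthogonal) and serves as a
    diagnostic of overestimation on unbalanced ones.
    """
    Xm = dec.reconstruction()
    total = _fro2(Xm - Xm.mean(axis=0, keepdims=True))
    ss = {name: _fro2(con) for name, con in dec.contributions.items()}
    percent = {name: _pct(v, total) for name, v in ss.items()}
    rss = _fro2(dec.residual)
    return VariancePartition(
        terms=list(dec.contributions),
        ss=ss,
        percent=percent,
        residual_ss=rss,
        residual_percent=_pct(rss, total),
        total_ss=total,
        method="naive",
        scheme=dec.scheme,
    )
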