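"""Coded design matrices for multifactorial general linear models.

Three coding schemes for categorical factors are supported:

``dummy``
    Reference-level 0/1 indicator coding.
``deviation``
    Sum-to-zero coding: 0/1 for the first ``alpha - 1`` levels, -1 on the
    reference (last) level.  Interaction columns are products of the
    main-effect columns.
``weighted-effect``
    Like deviation coding, but the reference level of a factor carries
    ``-n_level / n_reference`` so that every non-intercept column sums to
    zero over the observations even when the design is unbalanced.  Level
    effects then measure deviations from the observation-weighted mean.

A factor with ``alpha`` levels always occupies ``alpha - 1`` columns and a
two-way interaction of ``alpha x beta`` levels occupies
``(alpha - 1) * (beta - 1)`` columns, so every scheme yields a uniquely
estimable model on designs without empty cells.

All coding weights are built in exact rational arithmetic
(:class:`fractions.Fraction`) and converted to floating point once, so count
ratios such as -3/4 or -2/3 are reproduced bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CODING_SCHEMES",
    "FactorDesign",
    "ModelSpec",
    "DesignMatrix",
    "EmptyCellError",
    "build_design_matrix",
    "sub_design_matrix",
]

CODING_SCHEMES = ("dummy", "deviation", "weighted-effect")

_SCHEME_ALIASES = {
    "dummy": "dummy",
    "reference": "dummy",
    "deviation": "deviation",
    "dev": "deviation",
    "sum": "deviation",
    "weighted-effect": "weighted-effect",
    "weighted_effect": "weighted-effect",
    "we": "weighted-effect",
}


class EmptyCellError(ValueError):
    """A design cell required by the model has no observations."""


def normalize_scheme(scheme: str) -> str:
    try:
        return _SCHEME_ALIASES[scheme.lower()]
    except KeyError:
        raise ValueError(
            f"unknown coding scheme {scheme!r}; expected one of {CODING_SCHEMES}"
        ) from None


class FactorDesign:
    """Observation-to-level assignment for a set of categorical factors.

    Parameters
    ----------
    table
        DataFrame indexed by observation id, one column per factor, entries
        are level labels (coerced to ``str``).
    level_orders
        Optional explicit level order per factor.  Defaults to order of
        first appearance in the table.  The *last* level in the order is the
        reference level for all coding schemes.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        level_orders: Mapping[str, Sequence[str]] | None = None,
    ) -> None:
        if table.index.has_duplicates:
            dups = table.index[table.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate observation ids: {dups}")
        if table.shape[1] == 0:
            raise ValueError("design table has no factor columns")
        if table.isna().any().any():
            raise ValueError("design table contains missing level assignments")
        self._table = table.astype(str)
        self._levels: dict[str, tuple[str, ...]] = {}
        level_orders = dict(level_orders or {})
        for name in self._table.columns:
            observed = list(dict.fromkeys(self._table[name]))
            if name in level_orders:
                declared = [str(v) for v in level_orders[name]]
                missing = set(observed) - set(declared)
                if missing:
                    raise ValueError(
                        f"factor {name!r}: observed levels {sorted(missing)} "
                        "absent from declared level order"
                    )
                self._levels[name] = tuple(declared)
            else:
                self._levels[name] = tuple(observed)

    # -- basic accessors -------------------------------------------------
    @property
    def table(self) -> pd.DataFrame:
        return self._table

    @property
    def obs_ids(self) -> list:
        return list(self._table.index)

    @property
    def n(self) -> int:
        return len(self._table)

    @property
    def factor_names(self) -> list[str]:
        return list(self._table.columns)

    def levels(self, factor: str) -> tuple[str, ...]:
        self._check_factor(factor)
        return self._levels[factor]

    def labels(self, factor: str) -> np.ndarray:
        """Per-observation level labels of one factor."""
        self._check_factor(factor)
        return self._table[factor].to_numpy()

    def level_counts(self, factor: str) -> dict[str, int]:
        self._check_factor(factor)
        counts = self._table[factor].value_counts()
        return {lev: int(counts.get(lev, 0)) for lev in self._levels[factor]}

    def cell_counts(self, factor_a: str, factor_b: str) -> dict[tuple[str, str], int]:
        """Counts of observations per (level of a, level of b) cell."""
        self._check_factor(factor_a)
        self._check_factor(factor_b)
        grouped = self._table.groupby([factor_a, factor_b], observed=True).size()
        out: dict[tuple[str, str], int] = {}
        for la in self._levels[factor_a]:
            for lb in self._levels[factor_b]:
                out[(la, lb)] = int(grouped.get((la, lb), 0))
        return out

    def subset(self, obs_ids: Iterable) -> "FactorDesign":
        """Design restricted to ``obs_ids``; empty levels are dropped."""
        sub = self._table.loc[list(obs_ids)]
        orders = {
            name: [lev for lev in self._levels[name] if (sub[name] == lev).any()]
            for name in sub.columns
        }
        return FactorDesign(sub, level_orders=orders)

    def _check_factor(self, factor: str) -> None:
        if factor not in self._table.columns:
            raise KeyError(
                f"unknown factor {factor!r}; design has {self.factor_names}"
            )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        facs = ", ".join(
            f"{k}({len(v)} levels)" for k, v in self._levels.items()
        )
        return f"FactorDesign(n={self.n}, factors=[{facs}])"


Term = tuple[str, ...]


def term_name(term: Term) -> str:
    return ":".join(term)


@dataclass(frozen=True)
class ModelSpec:
    """Ordered collection of main-effect and two-way interaction terms.

    ``terms`` holds tuples of factor names: length one for a main effect,
    length two for an interaction.  Every factor used in an interaction
    must also appear as a main effect, and terms must be unique.
    """

    terms: tuple[Term, ...]
    coding: str = "weighted-effect"

    def __post_init__(self) -> None:
        object.__setattr__(self, "coding", normalize_scheme(self.coding))
        terms = tuple(tuple(t) for t in self.terms)
        object.__setattr__(self, "terms", terms)
        seen = set()
        mains = {t[0] for t in terms if len(t) == 1}
        for t in terms:
            if len(t) not in (1, 2):
                raise ValueError(
                    f"term {t!r}: only main effects and two-way interactions "
                    "are supported"
                )
            if t in seen:
                raise ValueError(f"duplicate term {term_name(t)!r}")
            seen.add(t)
            if len(t) == 2:
                for fac in t:
                    if fac not in mains:
                        raise ValueError(
                            f"interaction {term_name(t)!r} uses factor "
                            f"{fac!r} without a matching main effect"
                        )

    @classmethod
    def from_formula(cls, formula: str, coding: str = "weighted-effect") -> "ModelSpec":
        """Parse a model string such as ``"A + B + A:B"``."""
        terms: list[Term] = []
        for raw in formula.split("+"):
            piece = raw.strip()
            if not piece:
                raise ValueError(f"empty term in model formula {formula!r}")
            parts = tuple(p.strip() for p in piece.split(":"))
            if any(not p for p in parts):
                raise ValueError(f"malformed term {piece!r} in formula")
            terms.append(parts)
        return cls(tuple(terms), coding=coding)

    @property
    def term_names(self) -> list[str]:
        return [term_name(t) for t in self.terms]

    def drop(self, term: Term | str) -> "ModelSpec":
        """Model with one term removed (validation of interaction-implies-
        main is intentionally bypassed: reduced models used for type III
        sums of squares may drop a main effect while its interaction
        stays)."""
        t = _resolve_term(self, term)
        remaining = tuple(x for x in self.terms if x != t)
        out = object.__new__(ModelSpec)
        object.__setattr__(out, "terms", remaining)
        object.__setattr__(out, "coding", self.coding)
        return out

    def formula(self) -> str:
        return " + ".join(self.term_names)


def _resolve_term(model: ModelSpec, term: Term | str) -> Term:
    if isinstance(term, str):
        for t in model.terms:
            if term_name(t) == term:
                return t
        raise KeyError(f"term {term!r} not in model {model.formula()!r}")
    t = tuple(term)
    if t not in model.terms:
        raise KeyError(f"term {term_name(t)!r} not in model {model.formula()!r}")
    return t


@dataclass
class DesignMatrix:
    """Coded model matrix with named per-term column blocks.

    ``exact`` stores the same entries as :class:`fractions.Fraction`
    objects; ``values`` is its float conversion.  The intercept is always
    column 0 (block name ``"intercept"``).
    """

    values: np.ndarray
    exact: np.ndarray
    column_blocks: dict[str, range]
    column_names: list[str]
    scheme: str
    obs_ids: list = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def block(self, term: str) -> np.ndarray:
        """Float columns of one term."""
        if term not in self.column_blocks:
            raise KeyError(
                f"unknown term {term!r}; available: {list(self.column_blocks)}"
            )
        return self.values[:, self.column_blocks[term]]

    def drop_block(self, term: str) -> "DesignMatrix":
        """Design matrix with one term's columns deleted (reduced model)."""
        if term not in self.column_blocks:
            raise KeyError(f"unknown term {term!r}")
        keep = [
            j for j in range(self.p) if j not in self.column_blocks[term]
        ]
        blocks: dict[str, range] = {}
        offset = 0
        for name, rng in self.column_blocks.items():
            if name == term:
                continue
            width = rng.stop - rng.start
            blocks[name] = range(offset, offset + width)
            offset += width
        return DesignMatrix(
            values=self.values[:, keep],
            exact=self.exact[:, keep],
            column_blocks=blocks,
            column_names=[self.column_names[j] for j in keep],
            scheme=self.scheme,
            obs_ids=self.obs_ids,
        )


def _main_effect_columns(
    design: FactorDesign, factor: str, scheme: str
) -> tuple[list[list[Fraction]], list[str]]:
    levels = design.levels(factor)
    counts = design.level_counts(factor)
    used = [lev for lev in levels if counts[lev] > 0]
    if len(used) < len(levels):
        missing = [lev for lev in levels if counts[lev] == 0]
        raise EmptyCellError(
            f"factor {factor!r}: declared level(s) {missing} have no "
            "observations"
        )
    if len(used) < 2:
        raise ValueError(
            f"factor {factor!r} has a single level and cannot be coded"
        )
    ref = used[-1]
    labels = design.labels(factor)
    cols: list[list[Fraction]] = []
    names: list[str] = []
    for lev in used[:-1]:
        if scheme == "dummy":
            ref_val = Fraction(0)
        elif scheme == "deviation":
            ref_val = Fraction(-1)
        else:  # weighted-effect
            ref_val = Fraction(-counts[lev], counts[ref])
        col = [
            Fraction(1) if lab == lev else (ref_val if lab == ref else Fraction(0))
            for lab in labels
        ]
        cols.append(col)
        names.append(f"{factor}[{lev}]")
    return cols, names


def _interaction_columns(
    design: FactorDesign, fa: str, fb: str, scheme: str
) -> tuple[list[list[Fraction]], list[str]]:
    lev_a = design.levels(fa)
    lev_b = design.levels(fb)
    cells = design.cell_counts(fa, fb)
    empty = [cell for cell, cnt in cells.items() if cnt == 0]
    if empty:
        cell = empty[0]
        raise EmptyCellError(
            f"empty design cell ({fa}={cell[0]}, {fb}={cell[1]}) in modelled "
            f"interaction {fa}:{fb}"
        )
    ref_a, ref_b = lev_a[-1], lev_b[-1]
    la = design.labels(fa)
    lb = design.labels(fb)
    cols: list[list[Fraction]] = []
    names: list[str] = []
    for p in lev_a[:-1]:
        for q in lev_b[:-1]:
            if scheme in ("dummy", "deviation"):
                # product of the two main-effect codes
                def code_a(lab: str) -> Fraction:
                    if lab == p:
                        return Fraction(1)
                    if lab == ref_a and scheme == "deviation":
                        return Fraction(-1)
                    return Fraction(0)

                def code_b(lab: str) -> Fraction:
                    if lab == q:
                        return Fraction(1)
                    if lab == ref_b and scheme == "deviation":
                        return Fraction(-1)
                    return Fraction(0)

                col = [code_a(a) * code_b(b) for a, b in zip(la, lb)]
            else:
                # weighted-effect: the column is supported on the four cells
                # (p,q), (p,ref_b), (ref_a,q), (ref_a,ref_b) with weights
                # chosen so that it sums to zero over the observations.
                n_pq = cells[(p, q)]
                w = {
                    (p, q): Fraction(1),
                    (p, ref_b): Fraction(-n_pq, cells[(p, ref_b)]),
                    (ref_a, q): Fraction(-n_pq, cells[(ref_a, q)]),
                    (ref_a, ref_b): Fraction(n_pq, cells[(ref_a, ref_b)]),
                }
                col = [w.get((a, b), Fraction(0)) for a, b in zip(la, lb)]
            cols.append(col)
            names.append(f"{fa}[{p}]:{fb}[{q}]")
    return cols, names


def build_design_matrix(design: FactorDesign, model: ModelSpec) -> DesignMatrix:
    """Assemble the coded model matrix for ``model`` on ``design``.

    The intercept column of ones comes first, followed by one contiguous
    column block per term in model order.
    """
    for t in model.terms:
        for fac in t:
            if fac not in design.factor_names:
                raise KeyError(
                    f"model term {term_name(t)!r} references unknown factor "
                    f"{fac!r}; design has {design.factor_names}"
                )
    n = design.n
    exact_cols: list[list[Fraction]] = [[Fraction(1)] * n]
    names: list[str] = ["intercept"]
    blocks: dict[str, range] = {"intercept": range(0, 1)}
    offset = 1
    for t in model.terms:
        if len(t) == 1:
            cols, cnames = _main_effect_columns(design, t[0], model.coding)
        else:
            cols, cnames = _interaction_columns(design, t[0], t[1], model.coding)
        exact_cols.extend(cols)
        names.extend(cnames)
        blocks[term_name(t)] = range(offset, offset + len(cols))
        offset += len(cols)
    exact = np.empty((n, offset), dtype=object)
    for j, col in enumerate(exact_cols):
        exact[:, j] = col
    values = np.array([[float(v) for v in row] for row in exact], dtype=float)
    return DesignMatrix(
        values=values,
        exact=exact,
        column_blocks=blocks,
        column_names=names,
        scheme=model.coding,
        obs_ids=design.obs_ids,
    )


def sub_design_matrix(dm: DesignMatrix, term: str) -> DesignMatrix:
    """Design matrix with only ``term``'s columns retained.

    All other columns -- including the intercept -- are zeroed, so that
    multiplying by the full parameter matrix isolates the contribution of
    one term.
    """
    if term not in dm.column_blocks:
        raise KeyError(
            f"unknown term {term!r}; available: {list(dm.column_blocks)}"
        )
    keep = dm.column_blocks[term]
    exact = np.empty_like(dm.exact)
    exact[:] = Fraction(0)
    exact[:, keep] = dm.exact[:, keep]
    values = np.zeros_like(dm.values)
    values[:, keep] = dm.values[:, keep]
    return DesignMatrix(
        values=values,
        exact=exact,
        column_blocks=dict(dm.column_blocks),
        column_names=list(dm.column_names),
        scheme=dm.scheme,
        obs_ids=dm.obs_ids,
    )
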