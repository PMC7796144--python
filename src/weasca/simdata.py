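"""Synthetic factorial designs with spectra-like responses and known truth.

The generator emulates the structure of a multifactorial spectroscopy
experiment: categorical factors with (possibly very) unequal cell counts
and a response matrix whose rows are smooth curves — sums of Gaussian peaks
over the feature axis — plus i.i.d. Gaussian noise.  Ground-truth effect
matrices are built *inside the column space of the weighted-effect coded
design*, i.e. ``Con_f = BD/f gamma_f`` for random smooth coefficient
curves, so each term's truth satisfies the weighted zero-sum constraint and
is exactly identifiable: with zero noise the GLM decomposition recovers
every contribution to machine precision.

Two printed worked designs are also provided as fixtures: a balanced 2x3
crossed design with six observations and an unbalanced seven-observation
variant (one duplicated cell), together with their exact deviation- and
weighted-effect-coded matrices for regression tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd

from .design_coding import (
    FactorDesign,
    ModelSpec,
    build_design_matrix,
    sub_design_matrix,
    term_name,
)

__all__ = [
    "SimulationSpec",
    "GroundTruth",
    "SimulatedDataset",
    "simulate_dataset",
    "worked_example_fixture",
    "WorkedExample",
    "random_unbalanced_design",
]


@dataclass
class SimulationSpec:
    """Recipe for one synthetic dataset.

    Attributes
    ----------
    factor_names : names of the crossed factors, in order.
    cell_counts : mapping from a level-combination tuple (one level per
        factor) to its observation count; unequal counts give an
        unbalanced design.  Counts must be >= 1 for every listed cell.
    effects : mapping term formula (``"A"``, ``"A:B"``) to effect
        magnitude — the standard-deviation scale of that term's
        coefficient curves.  Magnitude 0 keeps the term in the model with
        no true contribution.
    m : number of features (wavenumber-like axis); default 200 keeps
        tests seconds-scale while remaining spectra-like.
    noise_sd : standard deviation of the i.i.d. Gaussian noise.
    baseline_scale : scale of the global mean curve M0.
    n_peaks : Gaussian peaks per generated curve.
    """

    factor_names: tuple[str, ...]
    cell_counts: dict[tuple[str, ...], int]
    effects: dict[str, float]
    m: int = 200
    noise_sd: float = 1.0
    baseline_scale: float = 5.0
    n_peaks: int = 6
    seed: int | None = None

    def model(self, coding: str = "weighted-effect") -> ModelSpec:
        return ModelSpec(
            tuple(tuple(t.split(":")) for t in self.effects), coding=coding
        )


@dataclass
class GroundTruth:
    M0: np.ndarray
    contributions: dict[str, np.ndarray]
    noise: np.ndarray

    def response(self) -> np.ndarray:
        return self.M0 + sum(self.contributions.values()) + self.noise


@dataclass
class SimulatedDataset:
    X: pd.DataFrame
    design: FactorDesign
    truth: GroundTruth
    spec: SimulationSpec


def _peak_curves(rng: np.random.Generator, rows: int, m: int, n_peaks: int) -> np.ndarray:
    """Random smooth curves: sums of Gaussian peaks on a unit feature axis."""
    x = np.linspace(0.0, 1.0, m)
    centers = rng.uniform(0.05, 0.95, size=(rows, n_peaks))
    widths = rng.uniform(0.01, 0.08, size=(rows, n_peaks))
    heights = rng.normal(0.0, 1.0, size=(rows, n_peaks))
    curves = np.einsum(
        "rp,rpm->rm",
        heights,
        np.exp(-0.5 * ((x[None, None, :] - centers[..., None]) / widths[..., None]) ** 2),
    )
    return curves


def _design_from_cells(
    factor_names: tuple[str, ...], cell_counts: dict[tuple[str, ...], int]
) -> FactorDesign:
    rows = []
    ids = []
    i = 0
    for cell, count in cell_counts.items():
        if len(cell) != len(factor_names):
            raise ValueError(
                f"cell {cell!r} does not match factors {factor_names}"
            )
        if count < 1:
            raise ValueError(f"cell {cell!r} requested with count {count} < 1")
        for _ in range(count):
            rows.append(dict(zip(factor_names, cell)))
            ids.append(f"obs{i:04d}")
            i += 1
    table = pd.DataFrame(rows, index=ids)
    return FactorDesign(table)


def simulate_dataset(spec: SimulationSpec) -> SimulatedDataset:
    """Generate (response, design, ground truth) from a recipe.

    Reproducible: the same spec (including seed) returns identical output.
    """
    design = _design_from_cells(spec.factor_names, spec.cell_counts)
    model = spec.model()
    dm = build_design_matrix(design, model)  # validates modelled cells
    rng = np.random.default_rng(spec.seed)
    M0 = np.tile(
        spec.baseline_scale * _peak_curves(rng, 1, spec.m, spec.n_peaks),
        (design.n, 1),
    )
    contributions: dict[str, np.ndarray] = {}
    for t in model.terms:
        name = term_name(t)
        block = sub_design_matrix(dm, name).values
        width = len(dm.column_blocks[name])
        gamma = spec.effects[name] * _peak_curves(rng, width, spec.m, spec.n_peaks)
        full_gamma = np.zeros((dm.p, spec.m))
        full_gamma[dm.column_blocks[name], :] = gamma
        contributions[name] = block @ full_gamma
    noise = rng.normal(0.0, spec.noise_sd, size=(design.n, spec.m))
    truth = GroundTruth(M0=M0, contributions=contributions, noise=noise)
    X = pd.DataFrame(
        truth.response(),
        index=design.obs_ids,
        columns=[f"f{j}" for j in range(spec.m)],
    )
    return SimulatedDataset(X=X, design=design, truth=truth, spec=spec)


def random_unbalanced_design(
    rng: np.random.Generator,
    n_factors: int = 2,
    max_levels: int = 4,
    max_cell: int = 5,
) -> FactorDesign:
    """Random crossed design with every cell non-empty and unequal counts."""
    names = tuple("ABC"[:n_factors])
    levels = [
        [f"{nm.lower()}{i + 1}" for i in range(rng.integers(2, max_levels + 1))]
        for nm in names
    ]
    cells: dict[tuple[str, ...], int] = {}
    grids = np.meshgrid(*[np.arange(len(l)) for l in levels], indexing="ij")
    for idx in zip(*[g.ravel() for g in grids]):
        cell = tuple(levels[k][i] for k, i in enumerate(idx))
        cells[cell] = int(rng.integers(1, max_cell + 1))
    return _design_from_cells(names, cells)


# ---------------------------------------------------------------------------
# Printed worked examples (balanced 2x3 and unbalanced 7-observation designs)
# ---------------------------------------------------------------------------


@dataclass
class WorkedExample:
    name: str
    design: FactorDesign
    deviation: np.ndarray  # exact D (Fractions)
    deviation_sub_b: np.ndarray  # exact D/B
    weighted: np.ndarray  # exact BD
    weighted_sub_b: np.ndarray  # exact BD/B
    model: ModelSpec = field(
        default_factory=lambda: ModelSpec((("A",), ("B",), ("A", "B")))
    )


def _F(rows: list[list]) -> np.ndarray:
    out = np.empty((len(rows), len(rows[0])), dtype=object)
    for i, row in enumerate(rows):
        out[i] = [Fraction(v) if not isinstance(v, Fraction) else v for v in row]
    return out


def worked_example_fixture(name: str) -> WorkedExample:
    """Exact printed design-matrix fixtures.

    ``balanced6``: 2x3 crossed design, one observation per cell; deviation
    and weighted-effect coding coincide.  ``unbalanced7``: same design with
    the (a2, b3) cell duplicated, whose weighted-effect matrix carries the
    count ratios -3/4, -2/3, -1/1 and +1/2.
    """
    F = Fraction
    if name == "balanced6":
        cells = {
            ("a1", "b1"): 1, ("a1", "b2"): 1, ("a1", "b3"): 1,
            ("a2", "b1"): 1, ("a2", "b2"): 1, ("a2", "b3"): 1,
        }
        design = _design_from_cells(("A", "B"), cells)
        D = _F([
            [1, 1, 1, 0, 1, 0],
            [1, 1, 0, 1, 0, 1],
            [1, 1, -1, -1, -1, -1],
            [1, -1, 1, 0, -1, 0],
            [1, -1, 0, 1, 0, -1],
            [1, -1, -1, -1, 1, 1],
        ])
        D_B = _F([
            [0, 0, 1, 0, 0, 0],
            [0, 0, 0, 1, 0, 0],
            [0, 0, -1, -1, 0, 0],
            [0, 0, 1, 0, 0, 0],
            [0, 0, 0, 1, 0, 0],
            [0, 0, -1, -1, 0, 0],
        ])
        return WorkedExample(
            name=name,
            design=design,
            deviation=D,
            deviation_sub_b=D_B,
            weighted=D.copy(),
            weighted_sub_b=D_B.copy(),
        )
    if name == "unbalanced7":
        cells = {
            ("a1", "b1"): 1, ("a1", "b2"): 1, ("a1", "b3"): 1,
            ("a2", "b1"): 1, ("a2", "b2"): 1, ("a2", "b3"): 2,
        }
        design = _design_from_cells(("A", "B"), cells)
        D = _F([
            [1, 1, 1, 0, 1, 0],
            [1, 1, 0, 1, 0, 1],
            [1, 1, -1, -1, -1, -1],
            [1, -1, 1, 0, -1, 0],
            [1, -1, 0, 1, 0, -1],
            [1, -1, -1, -1, 1, 1],
            [1, -1, -1, -1, 1, 1],
        ])
        D_B = _F([
            [0, 0, 1, 0, 0, 0],
            [0, 0, 0, 1, 0, 0],
            [0, 0, -1, -1, 0, 0],
            [0, 0, 1, 0, 0, 0],
            [0, 0, 0, 1, 0, 0],
            [0, 0, -1, -1, 0, 0],
            [0, 0, -1, -1, 0, 0],
        ])
        BD = _F([
            [1, 1, 1, 0, 1, 0],
            [1, 1, 0, 1, 0, 1],
            [1, 1, F(-2, 3), F(-2, 3), F(-1, 1), F(-1, 1)],
            [1, F(-3, 4), 1, 0, F(-1, 1), 0],
            [1, F(-3, 4), 0, 1, 0, F(-1, 1)],
            [1, F(-3, 4), F(-2, 3), F(-2, 3), F(1, 2), F(1, 2)],
            [1, F(-3, 4), F(-2, 3), F(-2, 3), F(1, 2), F(1, 2)],
        ])
        BD_B = _F([
            [0, 0, 1, 0, 0, 0],
            [0, 0, 0, 1, 0, 0],
            [0, 0, F(-2, 3), F(-2, 3), 0, 0],
            [0, 0, 1, 0, 0, 0],
            [0, 0, 0, 1, 0, 0],
            [0, 0, F(-2, 3), F(-2, 3), 0, 0],
            [0, 0, F(-2, 3), F(-2, 3), 0, 0],
        ])
        return WorkedExample(
            name=name,
            design=design,
            deviation=D,
            deviation_sub_b=D_B,
            weighted=BD,
            weighted_sub_b=BD_B,
        )
    raise KeyError(
        f"unknown worked example {name!r}; expected 'balanced6' or 'unbalanced7'"
    )
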