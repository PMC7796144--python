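import numpy as np
import pandas as pd
import pytest

from weasca import FactorDesign, ModelSpec, SimulationSpec, simulate_dataset

TWO_FACTOR_MODEL = ModelSpec((("A",), ("B",), ("A", "B")))


def balanced_cells(reps: int = 4, levels_a=("a1", "a2"), levels_b=("b1", "b2", "b3")):
    return {(a, b): reps for a in levels_a for b in levels_b}


@pytest.fixture
def balanced_sim():
    """Balanced 2x3 design, 4 replicates per cell, moderate effects."""
    spec = SimulationSpec(
        ("A", "B"),
        balanced_cells(),
        {"A": 2.0, "B": 1.0, "A:B": 0.5},
        m=30,
        noise_sd=1.0,
        seed=11,
    )
    return simulate_dataset(spec)


@pytest.fixture
def unbalanced_sim():
    """Unbalanced 2x3 design with strongly unequal cell counts."""
    spec = SimulationSpec(
        ("A", "B"),
        {
            ("a1", "b1"): 2, ("a1", "b2"): 6, ("a1", "b3"): 3,
            ("a2", "b1"): 7, ("a2", "b2"): 1, ("a2", "b3"): 5,
        },
        {"A": 2.0, "B": 1.0, "A:B": 0.5},
        m=30,
        noise_sd=1.0,
        seed=12,
    )
    return simulate_dataset(spec)


def grouped_design(n_groups: int, reps_per_class: int, rng: np.random.Generator):
    """Design with a grouping factor (mouse) crossed with a 2-class label."""
    rows = []
    for g in range(n_groups):
        for c in ("healthy", "tumor"):
            for _ in range(reps_per_class):
                rows.append({"mouse": f"m{g:02d}", "tissue": c})
    table = pd.DataFrame(rows, index=[f"o{i:04d}" for i in range(len(rows))])
    return FactorDesign(table)
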