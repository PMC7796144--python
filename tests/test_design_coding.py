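"""Coding-scheme correctness: printed worked matrices, zero sums, ranks."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from weasca import (
    EmptyCellError,
    FactorDesign,
    ModelSpec,
    build_design_matrix,
    sub_design_matrix,
    worked_example_fixture,
)
from weasca.simdata import _design_from_cells, random_unbalanced_design

MODEL_AB = ModelSpec((("A",), ("B",), ("A", "B")))


def model(coding):
    return ModelSpec((("A",), ("B",), ("A", "B")), coding=coding)


class TestWorkedMatrices:
    @pytest.mark.parametrize("name", ["balanced6", "unbalanced7"])
    @pytest.mark.parametrize("coding,attr", [
        ("deviation", "deviation"),
        ("weighted-effect", "weighted"),
    ])
    def test_full_matrix_exact(self, name, coding, attr):
        ex = worked_example_fixture(name)
        dm = build_design_matrix(ex.design, model(coding))
        assert dm.exact.shape == getattr(ex, attr).shape
        assert (dm.exact == getattr(ex, attr)).all()

    @pytest.mark.parametrize("name", ["balanced6", "unbalanced7"])
    @pytest.mark.parametrize("coding,attr", [
        ("deviation", "deviation_sub_b"),
        ("weighted-effect", "weighted_sub_b"),
    ])
    def test_sub_matrix_exact(self, name, coding, attr):
        ex = worked_example_fixture(name)
        dm = build_design_matrix(ex.design, model(coding))
        sub = sub_design_matrix(dm, "B")
        assert (sub.exact == getattr(ex, attr)).all()

    def test_unbalanced7_count_ratios(self):
        """The printed fractions -3/4, -2/3, -1/1, +1/2 appear verbatim."""
        ex = worked_example_fixture("unbalanced7")
        dm = build_design_matrix(ex.design, model("weighted-effect"))
        a_col = dm.exact[:, dm.column_blocks["A"]][:, 0]
        assert set(a_col[3:]) == {Fraction(-3, 4)}
        b_block = dm.exact[:, dm.column_blocks["B"]]
        assert b_block[2, 0] == Fraction(-2, 3)
        ab = dm.exact[:, dm.column_blocks["A:B"]]
        assert ab[2, 0] == Fraction(-1, 1)
        assert ab[5, 0] == ab[6, 1] == Fraction(1, 2)

    def test_balanced_we_equals_deviation(self):
        ex = worked_example_fixture("balanced6")
        we = build_design_matrix(ex.design, model("weighted-effect"))
        dev = build_design_matrix(ex.design, model("deviation"))
        assert (we.exact == dev.exact).all()


class TestColumnStructure:
    def test_column_counts(self):
        """alpha-1 columns per main effect, (alpha-1)(beta-1) per interaction."""
        rng = np.random.default_rng(0)
        design = random_unbalanced_design(rng, n_factors=2, max_levels=5)
        dm = build_design_matrix(design, MODEL_AB)
        na = len(design.levels("A"))
        nb = len(design.levels("B"))
        assert len(dm.column_blocks["A"]) == na - 1
        assert len(dm.column_blocks["B"]) == nb - 1
        assert len(dm.column_blocks["A:B"]) == (na - 1) * (nb - 1)
        assert dm.p == 1 + (na - 1) + (nb - 1) + (na - 1) * (nb - 1)

    def test_single_two_level_factor_symmetric(self):
        """Equal counts give a single +1/-1 column under every effect coding."""
        design = _design_from_cells(("A",), {("a1",): 3, ("a2",): 3})
        for coding in ("deviation", "weighted-effect"):
            dm = build_design_matrix(design, ModelSpec((("A",),), coding=coding))
            np.testing.assert_array_equal(dm.values[:, 1], [1, 1, 1, -1, -1, -1])

    def test_rows_identical_within_cell(self):
        ex = worked_example_fixture("unbalanced7")
        for coding in ("dummy", "deviation", "weighted-effect"):
            dm = build_design_matrix(ex.design, model(coding))
            np.testing.assert_array_equal(dm.values[5], dm.values[6])

    def test_sub_matrices_partition_columns(self):
        ex = worked_example_fixture("unbalanced7")
        dm = build_design_matrix(ex.design, model("weighted-effect"))
        total = sum(
            sub_design_matrix(dm, t).values for t in dm.column_blocks
        )
        np.testing.assert_array_equal(total, dm.values)

    def test_sub_matrix_intercept_only(self):
        ex = worked_example_fixture("balanced6")
        dm = build_design_matrix(ex.design, model("weighted-effect"))
        sub = sub_design_matrix(dm, "intercept")
        assert (sub.values[:, 0] == 1).all()
        assert (sub.values[:, 1:] == 0).all()


@settings(max_examples=40, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), n_factors=st.integers(1, 3))
def test_weighted_columns_sum_to_zero(seed, n_factors):
    """Every non-intercept weighted-effect column sums to exactly zero."""
    rng = np.random.default_rng(seed)
    design = random_unbalanced_design(rng, n_factors=n_factors)
    terms = [(f,) for f in design.factor_names]
    if n_factors >= 2:
        terms.append(("A", "B"))
    dm = build_design_matrix(design, ModelSpec(tuple(terms), coding="we"))
    exact_sums = dm.exact[:, 1:].sum(axis=0)
    assert all(s == 0 for s in exact_sums)
    assert np.all(np.abs(dm.values[:, 1:].sum(axis=0)) <= 1e-12)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_balanced_equivalence_random(seed):
    """WE and deviation matrices coincide whenever all cells are equal."""
    rng = np.random.default_rng(seed)
    reps = int(rng.integers(1, 5))
    na, nb = int(rng.integers(2, 4)), int(rng.integers(2, 4))
    cells = {
        (f"a{i}", f"b{j}"): reps for i in range(na) for j in range(nb)
    }
    design = _design_from_cells(("A", "B"), cells)
    we = build_design_matrix(design, model("weighted-effect"))
    dev = build_design_matrix(design, model("deviation"))
    assert (we.exact == dev.exact).all()


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_dummy_coding_full_rank(seed):
    rng = np.random.default_rng(seed)
    design = random_unbalanced_design(rng, n_factors=2)
    dm = build_design_matrix(design, ModelSpec(MODEL_AB.terms, coding="dummy"))
    assert np.linalg.matrix_rank(dm.values) == dm.p


class TestValidation:
    def test_empty_interaction_cell_named_in_error(self):
        cells = {
            ("a1", "b1"): 2, ("a1", "b2"): 2,
            ("a2", "b1"): 2,  # (a2, b2) missing
        }
        design = _design_from_cells(("A", "B"), cells)
        with pytest.raises(EmptyCellError, match=r"A=a2.*B=b2"):
            build_design_matrix(design, MODEL_AB)

    def test_empty_cell_ok_without_interaction(self):
        cells = {("a1", "b1"): 2, ("a1", "b2"): 2, ("a2", "b1"): 2}
        design = _design_from_cells(("A", "B"), cells)
        dm = build_design_matrix(design, ModelSpec((("A",), ("B",))))
        assert dm.p == 1 + 1 + 1

    def test_unknown_factor_rejected(self):
        design = _design_from_cells(("A",), {("a1",): 2, ("a2",): 2})
        with pytest.raises(KeyError, match="unknown factor"):
            build_design_matrix(design, ModelSpec((("Z",),)))

    def test_single_level_factor_rejected(self):
        design = _design_from_cells(("A",), {("a1",): 4})
        with pytest.raises(ValueError, match="single level"):
            build_design_matrix(design, ModelSpec((("A",),)))

    def test_unknown_term_in_sub_design(self):
        ex = worked_example_fixture("balanced6")
        dm = build_design_matrix(ex.design, MODEL_AB)
        with pytest.raises(KeyError, match="unknown term"):
            sub_design_matrix(dm, "C")

    def test_interaction_without_main_effect_rejected(self):
        with pytest.raises(ValueError, match="without a matching main effect"):
            ModelSpec((("A",), ("A", "B")))

    def test_duplicate_terms_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            ModelSpec((("A",), ("A",)))


class TestModelSpec:
    def test_formula_round_trip(self):
        m = ModelSpec.from_formula("A + B + C + A:B + A:C", coding="we")
        assert m.term_names == ["A", "B", "C", "A:B", "A:C"]
        assert m.formula() == "A + B + C + A:B + A:C"
        assert m.coding == "weighted-effect"

    def test_drop_keeps_interaction(self):
        m = ModelSpec.from_formula("A + B + A:B")
        reduced = m.drop("A")
        assert reduced.term_names == ["B", "A:B"]

    def test_level_order_override_moves_reference(self):
        import pandas as pd

        table = pd.DataFrame({"A": ["x", "y", "x", "y"]}, index=list("pqrs"))
        design = FactorDesign(table, level_orders={"A": ["y", "x"]})
        dm = build_design_matrix(design, ModelSpec((("A",),), coding="we"))
        # 'x' is now the reference (last) level
        assert dm.column_names[1] == "A[y]"
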