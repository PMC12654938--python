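"""Subjective, entropy, and combined weighting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from screeneval.indicators import Attribute, PerformanceMatrix
from screeneval.weighting import (
    DegenerateDataError,
    Provenance,
    WeightVector,
    WeightingError,
    combine_msn,
    entropy_weights,
    normalize,
    shift,
    subjective_weights,
    weight_change,
)

PRINT_TOL = 5e-5  # half-ULP of 4-decimal published tables


def ewm_oracle(grid):
    """Line-by-line entropy-weight computation over plain Python floats.

    Independent of the vectorised implementation: per-column proportions
    over rows, Shannon entropy scaled by 1/ln(n), weights from entropy
    deficits.  Expects an already-shifted (strictly positive) grid.
    """
    n, m = len(grid), len(grid[0])
    weights = []
    deficits = []
    for j in range(m):
        col = [grid[i][j] for i in range(n)]
        s = sum(col)
        p = [c / s for c in col]
        e = -sum(pi * math.log(pi) for pi in p if pi > 0) / math.log(n)
        deficits.append(1.0 - e)
    total = sum(deficits)
    for d in deficits:
        weights.append(d / total)
    return weights


def pmatrix(rows, ids=None):
    rows = np.asarray(rows, dtype=float)
    n, m = rows.shape
    return PerformanceMatrix(
        hospital_ids=tuple(f"h{i}" for i in range(n)),
        indicator_ids=tuple(ids or (f"X{j+1}" for j in range(m))),
        points=rows,
    )


class TestSubjectiveWeights:
    def test_reference_scheme_values(self, scheme):
        w = subjective_weights(scheme)
        assert w.provenance is Provenance.SUBJECTIVE
        assert round(w["X1"], 4) == 0.3125
        assert round(w["X8"], 4) == 0.0714
        assert round(w["X2"], 4) == 0.1071

    def test_equal_scores_give_equal_weights(self, scheme):
        quad = [ind for ind in scheme[:4]]
        quad = [
            type(ind)(id=ind.id, name=ind.name, attribute=ind.attribute,
                      assigned_score=7, bands=ind.bands)
            for ind in quad
        ]
        w = subjective_weights(quad)
        assert np.allclose(w.weights, 0.25)

    def test_empty_scheme_rejected(self):
        with pytest.raises(WeightingError):
            subjective_weights([])


class TestNormalize:
    def test_positive_negative_moderate_columns(self):
        matrix = pmatrix([[10, 10, 1], [20, 20, 2], [30, 30, 3]])
        attrs = {"X1": Attribute.POSITIVE, "X2": Attribute.NEGATIVE,
                 "X3": Attribute.MODERATE}
        norm = normalize(matrix, attrs)
        np.testing.assert_allclose(norm.values[:, 0], [0.0, 0.5, 1.0])
        np.testing.assert_allclose(norm.values[:, 1], [1.0, 0.5, 0.0])
        np.testing.assert_allclose(norm.values[:, 2], [0.0, 1.0, 0.0])

    def test_constant_column_maps_to_midpoint_with_warning(self):
        matrix = pmatrix([[5, 1], [5, 2]])
        attrs = {"X1": Attribute.POSITIVE, "X2": Attribute.POSITIVE}
        with pytest.warns(UserWarning, match="constant"):
            norm = normalize(matrix, attrs)
        np.testing.assert_allclose(norm.values[:, 0], 0.5)

    def test_single_hospital_rejected(self):
        with pytest.raises(WeightingError):
            normalize(pmatrix([[1, 2]]), {"X1": Attribute.POSITIVE,
                                          "X2": Attribute.POSITIVE})

    def test_shift_adds_constant_everywhere(self):
        matrix = pmatrix([[10, 1], [20, 2], [30, 3]])
        attrs = {"X1": Attribute.POSITIVE, "X2": Attribute.POSITIVE}
        norm = normalize(matrix, attrs)
        shifted = shift(norm)
        np.testing.assert_allclose(shifted.values, norm.values + 0.001)
        assert shifted.values.min() >= 0.001
        assert shifted.values.max() <= 1.001
        with pytest.raises(WeightingError):
            shift(shifted)


class TestEntropyWeights:
    def test_symmetric_two_column_matrix_splits_evenly(self):
        matrix = pmatrix([[1, 0], [0, 1]])
        attrs = dict.fromkeys(("X1", "X2"), Attribute.POSITIVE)
        result = entropy_weights(shift(normalize(matrix, attrs)))
        np.testing.assert_allclose(result.weights.weights, [0.5, 0.5])
        np.testing.assert_allclose(result.proportions.sum(axis=0), 1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_independent_oracle(self, seed):
        rng = np.random.default_rng(seed)
        grid = rng.uniform(0.001, 1.001, size=(3, 2))
        from screeneval.weighting import NormalizedMatrix

        nm = NormalizedMatrix(("a", "b", "c"), ("X1", "X2"), grid, shifted=True)
        ours = entropy_weights(nm).weights.weights
        expected = ewm_oracle(grid.tolist())
        np.testing.assert_allclose(ours, expected, atol=1e-12)

    def test_row_permutation_invariance(self, synthetic_matrix, scheme):
        from screeneval.indicators import attributes_of

        attrs = attributes_of(scheme)
        base = entropy_weights(shift(normalize(synthetic_matrix, attrs)))
        perm = np.random.default_rng(0).permutation(synthetic_matrix.n)
        shuffled = PerformanceMatrix(
            tuple(synthetic_matrix.hospital_ids[i] for i in perm),
            synthetic_matrix.indicator_ids,
            synthetic_matrix.points[perm],
        )
        other = entropy_weights(shift(normalize(shuffled, attrs)))
        np.testing.assert_allclose(
            base.weights.weights, other.weights.weights, atol=1e-12
        )

    def test_lower_dispersion_never_gets_larger_weight(self):
        """On two-column grids, the more concentrated column weighs less."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            spread = np.sort(rng.uniform(0, 1, size=6))
            tight = 0.5 + 0.05 * (spread - spread.mean())  # shrunk copy
            grid = np.column_stack([spread, tight]) + 0.001
            from screeneval.weighting import NormalizedMatrix

            nm = NormalizedMatrix(
                tuple(f"h{i}" for i in range(6)), ("wide", "narrow"),
                np.clip(grid, 0.001, 1.001), shifted=True,
            )
            w = entropy_weights(nm).weights
            assert w["narrow"] <= w["wide"] + 1e-12

    def test_constant_column_gets_minimal_weight(self, scheme):
        matrix = pmatrix([[35, 0, 0], [35, 6, 12], [35, 3, 7], [35, 6, 0]],
                         ids=("X1", "X3", "X9"))
        attrs = {"X1": Attribute.POSITIVE, "X3": Attribute.POSITIVE,
                 "X9": Attribute.POSITIVE}
        with pytest.warns(UserWarning):
            w = entropy_weights(shift(normalize(matrix, attrs))).weights
        assert w["X1"] == min(w.weights)
        assert w["X1"] == pytest.approx(0.0, abs=1e-12)

    def test_all_constant_matrix_is_degenerate(self):
        matrix = pmatrix([[1, 2], [1, 2]])
        attrs = dict.fromkeys(("X1", "X2"), Attribute.POSITIVE)
        with pytest.warns(UserWarning):
            shifted = shift(normalize(matrix, attrs))
        with pytest.raises(DegenerateDataError, match="equal weights"):
            entropy_weights(shifted)


class TestCombineMSN:
    def test_single_vector_is_identity(self):
        w = WeightVector(("X1", "X2"), np.array([0.3, 0.7]),
                         Provenance.SUBJECTIVE)
        combined = combine_msn([w])
        np.testing.assert_allclose(combined.weights, w.weights)
        assert combined.provenance is Provenance.COMBINED

    def test_uniform_idempotence(self):
        eq = WeightVector.equal(("X1", "X2", "X3"))
        combined = combine_msn([eq, eq])
        np.testing.assert_allclose(combined.weights, eq.weights)

    def test_order_invariance(self, ref):
        ab = combine_msn([ref.subjective, ref.objective])
        ba = combine_msn([ref.objective, ref.subjective])
        np.testing.assert_allclose(ab.weights, ba.weights, atol=1e-15)

    def test_reference_combined_values(self, ref):
        combined = combine_msn([ref.subjective, ref.objective])
        assert combined["X9"] == pytest.approx(0.2303, abs=PRINT_TOL)
        assert combined["X1"] == pytest.approx(0.0995, abs=PRINT_TOL)

    def test_mismatched_indicator_sets_rejected(self):
        a = WeightVector(("X1", "X2"), np.array([0.5, 0.5]))
        b = WeightVector(("X2", "X1"), np.array([0.5, 0.5]))
        with pytest.raises(WeightingError):
            combine_msn([a, b])

    def test_all_zero_products_degenerate(self):
        a = WeightVector(("X1", "X2"), np.array([1.0, 0.0]))
        b = WeightVector(("X1", "X2"), np.array([0.0, 1.0]))
        with pytest.raises(DegenerateDataError):
            combine_msn([a, b])


class TestWeightChange:
    def test_reference_changes(self, ref):
        table = weight_change(ref.subjective, ref.objective)
        assert table.loc["X1", "pct_change"] == pytest.approx(-92.45, abs=0.01)
        assert table.loc["X6", "pct_change"] == pytest.approx(313.43, abs=0.01)

    def test_identical_vectors_give_zero_change(self):
        w = WeightVector(("X1", "X2"), np.array([0.4, 0.6]))
        table = weight_change(w, w)
        np.testing.assert_allclose(table["pct_change"], 0.0)

    def test_zero_baseline_flagged_undefined(self):
        a = WeightVector(("X1", "X2"), np.array([0.0, 1.0]))
        b = WeightVector(("X1", "X2"), np.array([0.5, 0.5]))
        table = weight_change(a, b)
        assert not table.loc["X1", "defined"]
        assert np.isnan(table.loc["X1", "pct_change"])
        assert table.loc["X2", "defined"]


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    st.lists(
        st.lists(st.integers(min_value=0, max_value=35), min_size=4, max_size=4),
        min_size=3, max_size=8,
    )
)
def test_weight_vectors_sum_to_one_and_are_nonnegative(rows):
    """Every weighting route yields a nonnegative unit-sum vector."""
    matrix = pmatrix(rows)
    attrs = dict.fromkeys(matrix.indicator_ids, Attribute.POSITIVE)
    import warnings as _w

    with _w.catch_warnings():
        _w.simplefilter("ignore")
        shifted = shift(normalize(matrix, attrs))
        try:
            w_obj = entropy_weights(shifted).weights
        except DegenerateDataError:
            return  # fully constant matrices carry no information
    assert (w_obj.weights >= 0).all()
    assert abs(w_obj.weights.sum() - 1.0) < 1e-9
    combined = combine_msn([WeightVector.equal(matrix.indicator_ids), w_obj])
    assert abs(combined.weights.sum() - 1.0) < 1e-9
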