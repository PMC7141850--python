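"""Matrix data model and the counts/probability/weight/information algebra."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from logoplot import (
    Background,
    PositionCharacterMatrix,
    center_matrix,
    counts_to_probability,
    probability_to_information,
    probability_to_weight,
    transform_matrix,
    validate_matrix,
    weight_to_probability,
)
from logoplot.errors import (
    DegeneratePositionError,
    DispatchError,
    MatrixValidationError,
    NormalizationError,
    SemanticTypeError,
    TransformRangeError,
    ZeroProbabilityError,
)


def pcm(rows, chars="ACGT", mtype="user", **kw):
    return PositionCharacterMatrix.from_values(rows, chars, matrix_type=mtype, **kw)


# ---------------------------------------------------------------------------
# validation


class TestValidation:
    def test_zero_counts_are_legal(self):
        table = pcm(np.zeros((2, 4)), mtype="counts")
        assert validate_matrix(table) is table

    def test_negative_counts_rejected(self):
        with pytest.raises(MatrixValidationError, match="counts"):
            pcm([[1, -1, 0, 0]], mtype="counts")

    def test_probability_row_renormalized_within_tolerance(self):
        table = pcm([[0.5, 0.5, 0.0, 0.00000001]], mtype="probability")
        assert table.values.sum() == pytest.approx(1.0, abs=1e-12)

    def test_probability_row_far_from_one_errors(self):
        with pytest.raises(NormalizationError):
            pcm([[0.7, 0.7, 0.0, 0.0]], mtype="probability")

    def test_nonfinite_cell_names_position_and_character(self):
        with pytest.raises(MatrixValidationError, match=r"position 7.*'C'"):
            PositionCharacterMatrix.from_values(
                [[1.0, np.nan, 0.0, 0.0]], "ACGT", positions=[7]
            )

    def test_duplicate_character_labels_rejected(self):
        df = pd.DataFrame([[1.0, 2.0]], columns=["A", "A"])
        with pytest.raises(MatrixValidationError, match="duplicate"):
            PositionCharacterMatrix(df)

    def test_positions_must_increase(self):
        with pytest.raises(MatrixValidationError, match="increasing"):
            pcm([[1, 0, 0, 0], [0, 1, 0, 0]], positions=[3, 1])

    def test_background_must_sum_to_one(self):
        with pytest.raises(NormalizationError):
            Background({"A": 0.5, "C": 0.2})

    def test_background_entries_positive(self):
        with pytest.raises(MatrixValidationError):
            Background({"A": 1.0, "C": 0.0})


# ---------------------------------------------------------------------------
# individual transforms, frozen examples


class TestCountsToProbability:
    @pytest.mark.parametrize(
        "row, pseudocount, expected",
        [
            ([4, 0, 0, 0], 0.0, [1, 0, 0, 0]),
            ([0, 0, 0, 0], 1.0, [0.25, 0.25, 0.25, 0.25]),
            ([3, 1, 0, 0], 1.0, [0.5, 0.25, 0.125, 0.125]),
        ],
    )
    def test_laplace_smoothing(self, row, pseudocount, expected):
        out = counts_to_probability(pcm([row], mtype="counts"), pseudocount)
        assert out.matrix_type == "probability"
        np.testing.assert_allclose(out.values[0], expected, atol=1e-12)

    def test_all_zero_row_without_pseudocount_errors(self):
        with pytest.raises(DegeneratePositionError):
            counts_to_probability(pcm([[0, 0, 0, 0]], mtype="counts"), 0.0)

    def test_requires_counts_type(self, uniform_prob):
        with pytest.raises(SemanticTypeError):
            counts_to_probability(uniform_prob, 1.0)


class TestWeightTransforms:
    def test_uniform_probability_gives_zero_weights(self, uniform_prob):
        out = probability_to_weight(uniform_prob)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)

    def test_two_letter_identity(self):
        prob = pcm([[0.5, 0.5]], chars="AB", mtype="probability")
        out = probability_to_weight(prob, Background({"A": 0.5, "B": 0.5}))
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)

    def test_log_odds_example(self):
        prob = pcm([[0.5, 0.25, 0.125, 0.125]], mtype="probability")
        out = probability_to_weight(prob)
        np.testing.assert_allclose(out.values[0], [1, 0, -1, -1], atol=1e-12)

    def test_zero_probability_is_an_error_not_minus_inf(self):
        prob = pcm([[1, 0, 0, 0]], mtype="probability")
        with pytest.raises(ZeroProbabilityError, match="pseudocount"):
            probability_to_weight(prob)

    def test_inverse_example(self):
        w = pcm([[1, 0, -1, -1]], mtype="weight")
        out = weight_to_probability(w)
        np.testing.assert_allclose(out.values[0], [0.5, 0.25, 0.125, 0.125], atol=1e-12)

    def test_zero_weights_give_background(self):
        w = pcm([[0, 0, 0, 0]], mtype="weight")
        np.testing.assert_allclose(weight_to_probability(w).values[0], 0.25, atol=1e-12)

    def test_overflow_guard(self):
        w = pcm([[1500, 0, 0, 0]], mtype="weight")
        with pytest.raises(TransformRangeError):
            weight_to_probability(w)

    @settings(max_examples=50, deadline=None)
    @given(
        arrays(
            float,
            (3, 4),
            elements=st.floats(0.01, 1.0, allow_nan=False),
        )
    )
    def test_roundtrip_identity(self, raw):
        prob = raw / raw.sum(axis=1, keepdims=True)
        table = pcm(prob, mtype="probability")
        back = weight_to_probability(probability_to_weight(table))
        np.testing.assert_allclose(back.values, table.values, atol=1e-10)

    def test_roundtrip_invariant_to_row_constant(self):
        # w + const per row maps to the same probability row
        w = pcm([[1, 0, -1, -1]], mtype="weight")
        w_shift = pcm([[4, 3, 2, 2]], mtype="weight")
        np.testing.assert_allclose(
            weight_to_probability(w).values,
            weight_to_probability(w_shift).values,
            atol=1e-12,
        )


class TestInformation:
    def test_uniform_position_carries_no_information(self, uniform_prob):
        out = probability_to_information(uniform_prob)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)

    def test_conserved_dna_position_is_two_bits(self):
        prob = pcm([[1, 0, 0, 0]], mtype="probability")
        out = probability_to_information(prob)
        np.testing.assert_allclose(out.values[0], [2, 0, 0, 0], atol=1e-12)

    def test_conserved_protein_position_is_log2_20_bits(self):
        row = np.zeros(20)
        row[0] = 1.0
        prob = pcm([row], chars="ACDEFGHIKLMNPQRSTVWY", mtype="probability")
        out = probability_to_information(prob)
        assert out.values.sum() == pytest.approx(math.log2(20), abs=1e-12)

    def test_heights_sum_to_position_information(self):
        # KL form vs classic log2(C) - H form under a uniform background
        prob = pcm([[0.5, 0.25, 0.125, 0.125]], mtype="probability")
        out = probability_to_information(prob)
        p = prob.values[0]
        entropy = -(p * np.log2(p)).sum()
        assert out.values.sum() == pytest.approx(2.0 - entropy, abs=1e-12)
        np.testing.assert_allclose(out.values[0], p * (2.0 - entropy), atol=1e-12)

    def test_small_sample_correction_shrinks_and_floors(self):
        prob = pcm([[1, 0, 0, 0]], mtype="probability")
        corrected = probability_to_information(prob, n_sequences=10)
        expected = 2.0 - 3.0 / (2.0 * math.log(2) * 10)
        assert corrected.values.sum() == pytest.approx(expected, abs=1e-12)
        floored = probability_to_information(
            pcm([[0.25, 0.25, 0.25, 0.25]], mtype="probability"), n_sequences=2
        )
        assert (floored.values >= 0).all()

    @settings(max_examples=50, deadline=None)
    @given(
        arrays(float, (2, 4), elements=st.floats(0.0, 1.0, allow_nan=False)).filter(
            lambda a: (a.sum(axis=1) > 0.1).all()
        )
    )
    def test_nonnegative_under_uniform_background(self, raw):
        prob = raw / raw.sum(axis=1, keepdims=True)
        out = probability_to_information(pcm(prob, mtype="probability"))
        assert (out.values >= -1e-12).all()


class TestCenter:
    def test_hand_checked_example(self):
        out = center_matrix(pcm([[1, 0, -1, -1]], mtype="weight"))
        np.testing.assert_allclose(out.values[0], [1.25, 0.25, -0.75, -0.75], atol=1e-12)

    def test_idempotent(self):
        table = pcm(np.random.default_rng(0).normal(size=(4, 4)), mtype="weight")
        once = center_matrix(table)
        twice = center_matrix(once)
        np.testing.assert_allclose(once.values, twice.values, atol=1e-12)
        assert np.abs(once.values.mean(axis=1)).max() < 1e-12

    def test_commutes_with_row_constant_shift(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(3, 4))
        shift = rng.normal(size=(3, 1))
        a = center_matrix(pcm(vals + shift, mtype="user")).values
        b = center_matrix(pcm(vals, mtype="user")).values
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_constant_row_becomes_zero(self):
        out = center_matrix(pcm([[3.5, 3.5, 3.5, 3.5]], mtype="user"))
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)

    def test_rejected_for_probability_matrices(self, uniform_prob):
        with pytest.raises(SemanticTypeError):
            center_matrix(uniform_prob)


# ---------------------------------------------------------------------------
# dispatcher


class TestTransformMatrix:
    def test_counts_to_information_composition(self, dna_counts):
        out = transform_matrix(dna_counts, "information", pseudocount=1.0)
        manual = probability_to_information(
            counts_to_probability(dna_counts, 1.0)
        )
        np.testing.assert_array_equal(out.values, manual.values)

    def test_counts_to_information_conserved(self):
        table = pcm([[4, 0, 0, 0]], mtype="counts")
        out = transform_matrix(table, "information", pseudocount=0.0)
        np.testing.assert_allclose(out.values[0], [2, 0, 0, 0], atol=1e-12)

    def test_counts_to_weight_composed_example(self, dna_counts):
        out = transform_matrix(dna_counts, "weight", pseudocount=1.0)
        np.testing.assert_allclose(out.values[0], [1, 0, -1, -1], atol=1e-12)

    def test_identity_request_returns_validated_copy(self, uniform_prob):
        out = transform_matrix(uniform_prob, "probability")
        assert out is not uniform_prob
        np.testing.assert_array_equal(out.values, uniform_prob.values)

    def test_unsupported_pair_lists_conversions(self, uniform_prob):
        with pytest.raises(DispatchError, match="counts->probability"):
            transform_matrix(uniform_prob, "counts")

    def test_from_type_mismatch(self, dna_counts):
        with pytest.raises(DispatchError, match="from_type"):
            transform_matrix(dna_counts, "probability", from_type="weight")

    def test_center_only_for_weight_output(self, dna_counts):
        with pytest.raises(SemanticTypeError):
            transform_matrix(dna_counts, "information", center=True)
        out = transform_matrix(dna_counts, "weight", pseudocount=1.0, center=True)
        assert np.abs(out.values.mean(axis=1)).max() < 1e-12

    def test_default_pseudocount_for_counts_is_one(self, dna_counts):
        out = transform_matrix(dna_counts, "probability")
        np.testing.assert_allclose(out.values[0], [0.5, 0.25, 0.125, 0.125], atol=1e-12)

    def test_weight_to_information_routes_through_probability(self):
        w = pcm([[1, 0, -1, -1]], mtype="weight")
        out = transform_matrix(w, "information")
        prob = weight_to_probability(w)
        np.testing.assert_array_equal(
            out.values, probability_to_information(prob).values
        )

    def test_nonuniform_background_threads_through(self):
        bg = Background({"A": 0.4, "C": 0.3, "G": 0.2, "T": 0.1})
        prob = pcm([[0.4, 0.3, 0.2, 0.1]], mtype="probability")
        w = transform_matrix(prob, "weight", background=bg)
        np.testing.assert_allclose(w.values, 0.0, atol=1e-12)
        info = transform_matrix(prob, "information", background=bg)
        np.testing.assert_allclose(info.values, 0.0, atol=1e-12)
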