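import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from booltaylor import (
    TruthTable,
    average_sensitivity,
    bias,
    essential_variables,
    random_function,
    random_function_exact_ones,
    random_nondegenerate_function,
    reduce_to_essential,
)
from booltaylor.errors import InfeasibleError, InputShapeError, ParameterError


def brute_force_essential(tt):
    """Oracle: double loop over variables and all input tuples."""
    from booltaylor.functions import all_input_tuples

    ess = set()
    for i in range(tt.k):
        for x in all_input_tuples(tt.k):
            y = x.copy()
            y[i] ^= 1
            if tt.evaluate(x) != tt.evaluate(y):
                ess.add(i)
                break
    return frozenset(ess)


class TestEvaluate:
    @pytest.mark.parametrize(
        "outputs,x,expected",
        [([0, 0, 0, 1], (1, 1), 1), ([0, 0, 0, 1], (1, 0), 0), ([0, 1, 1, 0], (0, 1), 1)],
    )
    def test_two_input_examples(self, outputs, x, expected):
        assert TruthTable(2, outputs).evaluate(x) == expected

    def test_zero_arity_constant(self):
        assert TruthTable(0, [1]).evaluate(()) == 1

    def test_shape_mismatch_raises(self, and2):
        with pytest.raises(InputShapeError):
            and2.evaluate((1, 0, 1))

    def test_index_convention_first_variable_most_significant(self):
        f_x1 = TruthTable(2, [0, 0, 1, 1])  # f(x1, x2) = x1
        assert f_x1.evaluate((1, 0)) == 1
        assert f_x1.evaluate((0, 1)) == 0


class TestEssentialVariables:
    def test_projection_has_one_essential(self):
        assert essential_variables(TruthTable(2, [0, 0, 1, 1])) == {0}

    def test_constant_has_none(self):
        assert essential_variables(TruthTable(3, [0] * 8)) == frozenset()

    def test_xor_has_both(self, xor2):
        assert essential_variables(xor2) == {0, 1}

    @pytest.mark.parametrize("k", [0, 1, 2, 3])
    def test_matches_brute_force_oracle_exhaustively(self, k, all_tables):
        for tt in all_tables(k):
            assert essential_variables(tt) == brute_force_essential(tt)


class TestReduceToEssential:
    def test_projection_reduces_to_identity(self):
        red = reduce_to_essential(TruthTable(2, [0, 0, 1, 1], ("x", "y")))
        assert red.k == 1
        assert red.variable_names == ("x",)
        assert list(red.outputs) == [0, 1]

    def test_nondegenerate_unchanged(self, xor2):
        assert reduce_to_essential(xor2) is xor2

    def test_inner_and_reduces(self):
        f = TruthTable.from_callable(3, lambda t: t[1] & t[2])  # f(x,y,z) = y & z
        red = reduce_to_essential(f)
        assert red.k == 2
        from booltaylor.functions import all_input_tuples

        for x in all_input_tuples(3):
            assert red.evaluate(x[1:]) == f.evaluate(x)

    def test_idempotent_and_bias_preserving(self, rng):
        for _ in range(50):
            tt = random_function(4, 0.3, rng)
            red = reduce_to_essential(tt)
            assert bias(red).p == bias(tt).p
            again = reduce_to_essential(red)
            assert again.k == red.k
            assert np.array_equal(again.outputs, red.outputs)


class TestBias:
    def test_and2(self, and2):
        b = bias(and2)
        assert b.p == 0.25
        assert b.abs_bias_linear == 0.5
        assert b.ones_count == 1

    def test_constant_one(self):
        b = bias(TruthTable(3, [1] * 8))
        assert b.p == 1.0 and b.abs_bias_linear == 1.0 and b.abs_bias_quadratic == 1.0

    def test_balanced(self, xor2):
        b = bias(xor2)
        assert b.p == 0.5 and b.abs_bias_linear == 0.0 and b.abs_bias_quadratic == 0.0


class TestAverageSensitivity:
    @pytest.mark.parametrize(
        "outputs,k,expected",
        [([0, 1], 1, 1.0), ([0, 1, 1, 0], 2, 2.0), ([0, 0, 0, 1], 2, 1.0)],
    )
    def test_examples(self, outputs, k, expected):
        assert average_sensitivity(TruthTable(k, outputs)) == expected

    @pytest.mark.parametrize("k", [1, 2, 3, 4])
    @pytest.mark.parametrize("p", [0.1, 0.3, 0.5])
    def test_random_function_mean_tracks_2kpq(self, k, p, rng):
        reps = 10_000
        vals = np.array(
            [average_sensitivity(random_function(k, p, rng)) for _ in range(reps)]
        )
        expected = 2 * k * p * (1 - p)
        se = vals.std(ddof=1) / np.sqrt(reps)
        assert abs(vals.mean() - expected) < max(3 * se, 1e-9)


class TestGenerators:
    def test_degenerate_bias_values(self, rng):
        assert random_function(2, 0.0, rng).is_constant()
        assert list(random_function(2, 1.0, rng).outputs) == [1, 1, 1, 1]

    def test_invalid_bias_raises(self, rng):
        with pytest.raises(ParameterError):
            random_function(2, 1.5, rng)

    def test_ones_count_mean(self, rng):
        counts = [random_function(3, 0.5, rng).outputs.sum() for _ in range(10_000)]
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - 4.0) < 3 * se

    def test_exact_ones_always_exact(self, rng):
        for q in range(9):
            tt = random_function_exact_ones(3, q, rng)
            assert int(tt.outputs.sum()) == q

    def test_exact_ones_forced_constant(self, rng):
        assert random_function_exact_ones(2, 4, rng).is_constant()

    def test_exact_ones_uniform_over_subsets(self, rng):
        counts = np.zeros(4)
        n = 8000
        for _ in range(n):
            counts[np.flatnonzero(random_function_exact_ones(2, 1, rng).outputs)[0]] += 1
        freqs = counts / n
        assert np.all(np.abs(freqs - 0.25) < 4 * np.sqrt(0.25 * 0.75 / n))

    def test_exact_ones_out_of_range(self, rng):
        with pytest.raises(ParameterError):
            random_function_exact_ones(2, 5, rng)

    def test_nondegenerate_one_input(self, rng):
        seen = set()
        for _ in range(100):
            tt = random_nondegenerate_function(1, 0.5, rng)
            seen.add(tuple(tt.outputs))
        assert seen <= {(0, 1), (1, 0)}

    def test_nondegenerate_never_degenerate(self, rng):
        for _ in range(300):
            tt = random_nondegenerate_function(2, 0.5, rng)
            assert len(essential_variables(tt)) == 2

    def test_nondegenerate_infeasible_bias(self, rng):
        with pytest.raises(InfeasibleError):
            random_nondegenerate_function(2, 0.0, rng)


class TestSerialization:
    @given(k=st.integers(0, 4), data=st.data())
    @settings(max_examples=50, deadline=None)
    def test_text_round_trip(self, k, data):
        bits = data.draw(st.lists(st.integers(0, 1), min_size=1 << k, max_size=1 << k))
        tt = TruthTable(k, bits)
        back = TruthTable.from_text(tt.to_text())
        assert back.k == tt.k
        assert np.array_equal(back.outputs, tt.outputs)
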