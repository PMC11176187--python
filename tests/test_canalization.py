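import itertools

import numpy as np
import pytest

from booltaylor import (
    TruthTable,
    canalization_report,
    is_canalizing,
    is_nested_canalizing,
    random_function,
    random_ncf,
    random_ncf_with_layers,
    random_noncanalizing_core,
    random_with_exact_depth,
    random_with_exact_depth_and_bias,
    random_with_min_depth,
    reconstruct,
)
from booltaylor.canalization import _canalizing_witnesses
from booltaylor.errors import InfeasibleError, ParameterError
from booltaylor.functions import all_input_tuples
from conftest import enumerate_tables


def oracle_depth(tt):
    """Brute force: try every (variable, input) pair recursively, maximize
    the number of peeled variables."""
    if tt.is_constant():
        return 0
    best = 0
    t = tt.as_tensor()
    for i in range(tt.k):
        for a in (0, 1):
            sub = np.take(t, a, axis=i)
            if sub.min() == sub.max():
                rest = TruthTable(tt.k - 1, np.take(t, 1 - a, axis=i).reshape(-1))
                best = max(best, 1 + oracle_depth(rest))
    return best


class TestIsCanalizing:
    def test_and_witness(self, and2):
        flag, wit = is_canalizing(and2)
        assert flag and wit == (0, 0, 0)

    def test_xor_not_canalizing(self, xor2):
        assert is_canalizing(xor2) == (False, None)

    def test_constant_follows_flag(self):
        one = TruthTable(2, [1, 1, 1, 1])
        assert is_canalizing(one)[0] is False
        assert is_canalizing(one, constants_canalizing=True)[0] is True


class TestCanalizationReport:
    @pytest.mark.parametrize(
        "fn,k,depth,layers",
        [
            (lambda t: t[0] & (1 - t[1]) & (1 - t[2]) & t[3], 4, 4, (4,)),
            (lambda t: t[0] | (t[1] & t[2] & t[3]), 4, 4, (1, 3)),
            (lambda t: t[0] ^ t[1], 2, 0, ()),
            (lambda t: (t[0] & t[1]) | ((1 - t[0]) & (1 - t[1]) & t[2]), 3, 0, ()),
        ],
    )
    def test_known_structures(self, fn, k, depth, layers):
        r = canalization_report(TruthTable.from_callable(k, fn))
        assert r.depth == depth
        assert r.layers == layers

    def test_xor_core_is_the_function(self, xor2):
        r = canalization_report(xor2)
        assert np.array_equal(r.core.outputs, xor2.outputs)
        assert r.core_variables == (0, 1)

    def test_zero_function_convention(self):
        r = canalization_report(TruthTable(3, [0] * 8))
        assert r.is_constant and r.depth == 3 and not r.is_ncf
        assert np.array_equal(reconstruct(r).outputs, np.zeros(8, dtype=np.uint8))

    @pytest.mark.parametrize("k", [0, 1, 2, 3])
    def test_exhaustive_depth_oracle_and_round_trip(self, k):
        for tt in enumerate_tables(k):
            r = canalization_report(tt)
            assert np.array_equal(reconstruct(r).outputs, tt.outputs)
            assert sum(r.layers) == r.depth == len(r.order)
            if not tt.is_constant():
                assert r.depth == oracle_depth(tt)
                if r.depth < tt.k:
                    # core depends on all its variables and is non-canalizing
                    from booltaylor import essential_variables

                    assert not _canalizing_witnesses(r.core.as_tensor()) or r.core.k == 0
                    if r.core.k > 0 and len(essential_variables(tt)) == tt.k:
                        assert len(essential_variables(r.core)) == r.core.k

    def test_sampled_k4_oracle_and_round_trip(self, rng):
        for _ in range(200):
            tt = random_function(4, float(rng.uniform(0.2, 0.8)), rng)
            r = canalization_report(tt)
            assert np.array_equal(reconstruct(r).outputs, tt.outputs)
            if not tt.is_constant():
                assert r.depth == oracle_depth(tt)

    def test_depth_invariant_under_permutation_and_negation(self, rng):
        for _ in range(50):
            tt = random_function(4, 0.5, rng)
            d = canalization_report(tt).depth if not tt.is_constant() else None
            if d is None:
                continue
            perm = rng.permutation(4)
            neg = rng.integers(0, 2, size=4)
            X = all_input_tuples(4)
            out = np.empty(16, dtype=np.uint8)
            for idx, x in enumerate(X):
                y = x[perm] ^ neg.astype(np.uint8)
                out[idx] = tt.evaluate(y)
            assert canalization_report(TruthTable(4, out)).depth == d


class TestIsNestedCanalizing:
    def test_and_is_ncf(self, and2):
        assert is_nested_canalizing(and2)

    def test_xor_is_not(self, xor2):
        assert not is_nested_canalizing(xor2)

    def test_exactly_eight_of_sixteen_two_input_functions(self):
        assert sum(is_nested_canalizing(tt) for tt in enumerate_tables(2)) == 8


class TestGenerators:
    def test_noncanalizing_core_m2_is_xor_type(self, rng):
        seen = {tuple(random_noncanalizing_core(2, rng).outputs) for _ in range(50)}
        assert seen <= {(0, 1, 1, 0), (1, 0, 0, 1)}

    def test_noncanalizing_core_m1_infeasible(self, rng):
        with pytest.raises(InfeasibleError):
            random_noncanalizing_core(1, rng)

    def test_noncanalizing_core_infeasible_ones(self, rng):
        with pytest.raises(InfeasibleError):
            random_noncanalizing_core(2, rng, ones_count=4)
        with pytest.raises(InfeasibleError):
            random_noncanalizing_core(3, rng, ones_count=1)

    @pytest.mark.parametrize("d", [0, 2, 4])
    def test_exact_depth_realized(self, d, rng):
        for _ in range(30):
            tt = random_with_exact_depth(4, d, rng)
            assert canalization_report(tt).depth == d

    def test_exact_depth_k_is_ncf(self, rng):
        assert is_nested_canalizing(random_with_exact_depth(4, 4, rng))

    def test_exact_depth_k_minus_1_infeasible(self, rng):
        with pytest.raises(InfeasibleError):
            random_with_exact_depth(3, 2, rng)

    def test_exact_depth_and_bias_matches_and2_reference(self, and2, rng):
        ref = canalization_report(and2)
        for _ in range(30):
            tt = random_with_exact_depth_and_bias(2, ref.depth, 1, ref.outputs, rng)
            assert int(tt.outputs.sum()) == 1
            assert canalization_report(tt).depth == 2

    def test_exact_depth_and_bias_preserves_ncf_bias(self, rng):
        ref = random_ncf(4, rng)
        rep = canalization_report(ref)
        q = int(ref.outputs.sum())
        for _ in range(20):
            tt = random_with_exact_depth_and_bias(4, 4, q, rep.outputs, rng)
            assert int(tt.outputs.sum()) == q
            assert is_nested_canalizing(tt)

    def test_exact_depth_and_bias_infeasible_q(self, and2, rng):
        ref = canalization_report(and2)
        with pytest.raises(InfeasibleError):
            random_with_exact_depth_and_bias(2, 2, 3, ref.outputs, rng)

    def test_min_depth_realized_depths(self, rng):
        depths = {canalization_report(random_with_min_depth(4, 2, rng)).depth
                  for _ in range(200)}
        assert depths <= {2, 4}
        assert 2 in depths  # k-1 = 3 is impossible, both feasible depths occur
        d4 = {canalization_report(random_with_min_depth(4, 4, rng)).depth
              for _ in range(20)}
        assert d4 == {4}

    def test_min_depth_zero_is_nondegenerate(self, rng):
        from booltaylor import essential_variables

        for _ in range(30):
            tt = random_with_min_depth(4, 0, rng)
            assert len(essential_variables(tt)) == 4

    @pytest.mark.parametrize("layers", [(4,), (1, 3), (2, 2), (1, 1, 2), (1,)])
    def test_ncf_layer_structures_realized(self, layers, rng):
        k = sum(layers)
        for _ in range(25):
            tt = random_ncf_with_layers(k, layers, rng)
            r = canalization_report(tt)
            assert r.layers == layers
            assert r.is_ncf

    @pytest.mark.parametrize("layers", [(2, 1, 1), (3, 1), (2,)])
    def test_invalid_layer_vectors_rejected(self, layers, rng):
        with pytest.raises(ParameterError):
            random_ncf_with_layers(4, layers, rng)

    def test_random_ncf_fraction_matches_enumeration(self, rng):
        # 8 of the 16 two-input functions are NCFs
        n = 4000
        frac = np.mean(
            [is_nested_canalizing(random_function(2, 0.5, rng)) for _ in range(n)]
        )
        assert abs(frac - 0.5) < 4 * np.sqrt(0.25 / n)

    def test_report_serializes_to_json(self, and2):
        import json

        rec = json.loads(canalization_report(and2).to_json_record())
        assert rec["depth"] == 2 and rec["layers"] == [2]
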