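import numpy as np
import pytest

from booltaylor import (
    BooleanNetwork,
    TruthTable,
    approximate_network,
    continuous_extension,
    mae_profile,
    mean_approximation_error,
    random_function,
    simulate_continuous,
    taylor_truncation,
)
from booltaylor.ensembles import EnsembleSpec, generate_network
from booltaylor.errors import ParameterError
from booltaylor.functions import all_input_tuples
from conftest import enumerate_tables


class TestContinuousExtension:
    def test_and2_centred_coefficients(self, and2):
        # p1 p2 = 1/4 + (x1-1/2)/2 + (x2-1/2)/2 + (x1-1/2)(x2-1/2)
        poly = continuous_extension(and2)
        assert list(poly.coeffs) == [0.25, 0.5, 0.5, 1.0]

    def test_not_is_one_minus_p(self, negation1):
        poly = continuous_extension(negation1)
        vals = poly.evaluate(np.array([[0.0], [0.3], [1.0]]))
        assert vals == pytest.approx([1.0, 0.7, 0.0])

    def test_constant(self):
        poly = continuous_extension(TruthTable(2, [1, 1, 1, 1]))
        assert poly.evaluate(np.array([[0.2, 0.9]])) == pytest.approx([1.0])

    @pytest.mark.parametrize("k", [0, 1, 2, 3])
    def test_vertex_agreement_exhaustive(self, k):
        X = all_input_tuples(k).astype(float)
        for tt in enumerate_tables(k):
            assert np.array_equal(continuous_extension(tt).evaluate(X), tt.outputs)

    def test_vertex_agreement_sampled_k4(self, rng):
        X = all_input_tuples(4).astype(float)
        for _ in range(100):
            tt = random_function(4, float(rng.uniform(0.1, 0.9)), rng)
            assert np.array_equal(continuous_extension(tt).evaluate(X), tt.outputs)

    def test_empty_set_coefficient_is_bias(self, rng):
        tt = random_function(4, 0.3, rng)
        assert continuous_extension(tt).coeffs[0] == tt.outputs.mean()


class TestTaylorTruncation:
    def test_xor_first_order_is_constant_half(self, xor2):
        poly = taylor_truncation(continuous_extension(xor2), 1)
        vals = poly.evaluate(np.array([[0.0, 1.0], [0.9, 0.1]]))
        assert vals == pytest.approx([0.5, 0.5])

    def test_full_order_unchanged(self, and2):
        poly = continuous_extension(and2)
        assert np.array_equal(taylor_truncation(poly, 2).coeffs, poly.coeffs)

    def test_order_zero_is_bias(self, rng):
        tt = random_function(3, 0.4, rng)
        poly = taylor_truncation(continuous_extension(tt), 0)
        assert poly.evaluate(np.array([[1.0, 0.0, 1.0]]))[0] == tt.outputs.mean()

    def test_out_of_range(self, and2):
        with pytest.raises(ParameterError):
            taylor_truncation(continuous_extension(and2), 3)

    def test_truncation_nesting(self, rng):
        tt = random_function(4, 0.5, rng)
        poly = continuous_extension(tt)
        prev = taylor_truncation(poly, 0).coeffs
        for m in range(1, 5):
            cur = taylor_truncation(poly, m).coeffs
            kept = prev != 0
            assert np.array_equal(cur[kept], prev[kept])
            prev = cur


class TestContinuousNetwork:
    def test_full_order_matches_boolean_trajectory(self, rng):
        net = generate_network(EnsembleSpec(N=10, K=4, p=0.5), rng)
        cnet = approximate_network(net, 4)
        X0 = rng.integers(0, 2, size=(50, 10)).astype(np.uint8)
        cont = simulate_continuous(cnet, X0.astype(float), 10)
        boolean = X0.copy()
        for _ in range(10):
            boolean = net.step_batch(boolean)
        assert np.array_equal(cont, boolean.astype(float))

    def test_negation_order0_sticks_at_half(self, negation1):
        net = BooleanNetwork(("a",), ((0,),), (negation1,))
        cnet = approximate_network(net, 0)
        x = simulate_continuous(cnet, np.array([[0.0]]), 1)
        assert x[0, 0] == 0.5
        assert simulate_continuous(cnet, np.array([[0.0]]), 7)[0, 0] == 0.5

    def test_states_stay_in_unit_cube(self, rng):
        net = generate_network(EnsembleSpec(N=8, K=3, p=0.3), rng)
        cnet = approximate_network(net, 1)
        X = simulate_continuous(cnet, rng.random((30, 8)), 25)
        assert np.all(X >= 0) and np.all(X <= 1)


class TestMAE:
    def test_zero_when_order_covers_degree(self, rng):
        net = generate_network(EnsembleSpec(N=10, K=3, p=0.5), rng)
        assert mean_approximation_error(net, 3, n_ic=100, steps=25, rng=rng) == 0.0

    def test_identity_network_linear_exact(self, identity_network, rng):
        assert mean_approximation_error(identity_network(6), 1, n_ic=50, rng=rng) == 0.0

    def test_negation_order0_quarter(self, negation1, rng):
        net = BooleanNetwork(("a",), ((0,),), (negation1,))
        # Boolean oscillates, continuous sticks at 1/2: squared gap 0.25
        assert mean_approximation_error(net, 0, n_ic=2, steps=25, rng=rng) == 0.25

    def test_shared_initial_conditions_across_orders(self, rng):
        net = generate_network(EnsembleSpec(N=10, K=3, p=0.5), rng)
        X0 = rng.integers(0, 2, size=(100, 10)).astype(np.uint8)
        prof = mae_profile(net, (1, 2, 3), initial_states=X0, steps=25)
        assert prof[3] == 0.0
        again = mae_profile(net, (1, 2, 3), initial_states=X0, steps=25)
        assert prof == again

    def test_relabeling_invariance(self, rng):
        net = generate_network(EnsembleSpec(N=8, K=3, p=0.5), rng)
        perm = rng.permutation(8)
        inv = np.argsort(perm)
        relabeled = BooleanNetwork(
            tuple(net.names[i] for i in perm),
            tuple(tuple(int(inv[r]) for r in net.regulators[i]) for i in perm),
            tuple(net.rules[i] for i in perm),
        )
        X0 = rng.integers(0, 2, size=(200, 8)).astype(np.uint8)
        a = mae_profile(net, (1, 2), initial_states=X0, steps=25)
        b = mae_profile(relabeled, (1, 2), initial_states=X0[:, perm], steps=25)
        assert a[1] == pytest.approx(b[1]) and a[2] == pytest.approx(b[2])

    def test_mae_decreases_with_absolute_bias_first_order(self, rng):
        # directional check: strongly biased rules are easier to linearize
        vals = {}
        for p in (0.5, 0.1):
            maes = [
                mean_approximation_error(
                    generate_network(EnsembleSpec(N=12, K=3, p=p), rng),
                    1, n_ic=200, steps=25, rng=rng,
                )
                for _ in range(8)
            ]
            vals[p] = np.mean(maes)
        assert vals[0.1] < vals[0.5]
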