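"""Multilinear extensions, Taylor truncations, and the mean approximation error.

Every Boolean function has a unique square-free (multilinear) polynomial
extension to [0,1]^k that interpolates it on the hypercube vertices.  Around
the centre point p = (1/2, ..., 1/2) the extension is stored in the basis of
centred monomials prod_{i in alpha} (x_i - 1/2); the empty-set coefficient is
the output bias, and the order-m Taylor truncation simply drops all subsets
with |alpha| > m.  All coefficients are dyadic rationals, so the arithmetic
here is exact in binary floating point: the full-order approximation of a
network reproduces the Boolean trajectory bit for bit.

The continuous network applies per-node truncations clipped to [0, 1] and is
iterated synchronously; the mean approximation error (MAE) is the
per-coordinate mean squared difference between the Boolean and continuous
states after a fixed number of steps from shared random initial states.  A
value of 0.25 is the signature of a continuous system stuck at 1/2 against an
effectively random Boolean trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import sample_initial_states
from .errors import InputShapeError, ParameterError
from .functions import TruthTable
from .network import BooleanNetwork


@dataclass(frozen=True)
class MultilinearPoly:
    """Square-free polynomial on [0,1]^k in the centred-monomial basis.

    ``coeffs[s]`` is the coefficient of prod_{i in s} (x_i - 1/2), where the
    subset s is encoded with the package's MSB bitmask convention (bit k-1-i
    marks variable i).
    """

    k: int
    coeffs: np.ndarray

    def __post_init__(self):
        c = np.ascontiguousarray(np.asarray(self.coeffs, dtype=float))
        if c.shape != (1 << self.k,):
            raise InputShapeError(f"coeffs must have length 2^{self.k}")
        object.__setattr__(self, "coeffs", c)

    @property
    def subset_sizes(self) -> np.ndarray:
        """|alpha| for every subset index."""
        idx = np.arange(1 << self.k, dtype=np.uint64)
        sizes = np.zeros(1 << self.k, dtype=int)
        for i in range(self.k):
            sizes += ((idx >> np.uint64(i)) & np.uint64(1)).astype(int)
        return sizes

    def terms(self) -> list[tuple[float, tuple[int, ...]]]:
        """Non-zero (coefficient, variable indices) pairs."""
        out = []
        for s in np.flatnonzero(self.coeffs):
            vars_ = tuple(i for i in range(self.k) if (s >> (self.k - 1 - i)) & 1)
            out.append((float(self.coeffs[s]), vars_))
        return out

    def evaluate(self, X: np.ndarray) -> np.ndarray:
        """Evaluate on a (n_samples, k) matrix of values in [0, 1]."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.k:
            raise InputShapeError(f"expected (n, {self.k}) matrix, got {X.shape}")
        Y = X - 0.5
        acc = np.zeros(X.shape[0])
        for coef, vars_ in self.terms():
            term = np.full(X.shape[0], coef)
            for v in vars_:
                term = term * Y[:, v]
            acc += term
        return acc


def continuous_extension(tt: TruthTable) -> MultilinearPoly:
    """The unique multilinear interpolant, re-centred at (1/2, ..., 1/2).

    Computed by a fast axis-by-axis transform: along each variable the pair
    (f|x=0, f|x=1) becomes (mean, difference), yielding the centred-monomial
    coefficient tensor in one pass.
    """
    c = tt.outputs.astype(float).reshape((2,) * tt.k)
    for ax in range(tt.k):
        a0 = np.take(c, 0, axis=ax)
        a1 = np.take(c, 1, axis=ax)
        c = np.stack([(a0 + a1) / 2.0, a1 - a0], axis=ax)
    return MultilinearPoly(tt.k, c.reshape(-1))


def taylor_truncation(poly: MultilinearPoly, m: int) -> MultilinearPoly:
    """Drop all subsets with |alpha| > m; m = k returns the polynomial
    unchanged, m = 0 the constant equal to the output bias."""
    if not 0 <= m <= poly.k:
        raise ParameterError(f"order m={m} out of range [0, {poly.k}]")
    keep = poly.subset_sizes <= m
    return MultilinearPoly(poly.k, np.where(keep, poly.coeffs, 0.0))


@dataclass(frozen=True)
class ContinuousNetwork:
    """Clipped order-m Taylor approximation of a Boolean network."""

    n: int
    order: int
    node_regulators: tuple[tuple[int, ...], ...]
    node_terms: tuple[tuple[tuple[float, tuple[int, ...]], ...], ...]

    def step(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = np.empty_like(X)
        for j in range(self.n):
            regs = self.node_regulators[j]
            Y = X[:, list(regs)] - 0.5
            acc = np.zeros(X.shape[0])
            for coef, vars_ in self.node_terms[j]:
                term = np.full(X.shape[0], coef)
                for v in vars_:
                    term = term * Y[:, v]
                acc += term
            out[:, j] = np.clip(acc, 0.0, 1.0)
        return out


def approximate_network(net: BooleanNetwork, m: int) -> ContinuousNetwork:
    """Per-node order-m truncations of the essential-reduced rules, composed
    with clipping to [0, 1]."""
    if m < 0:
        raise ParameterError("order m must be >= 0")
    regulators, terms = [], []
    for regs, red in net.reduced_rules():
        poly = taylor_truncation(continuous_extension(red), min(m, red.k))
        regulators.append(regs)
        terms.append(tuple(poly.terms()))
    return ContinuousNetwork(net.n, m, tuple(regulators), tuple(terms))


def simulate_continuous(
    cnet: ContinuousNetwork, x0: np.ndarray, steps: int
) -> np.ndarray:
    """Synchronously iterate the clipped polynomial map ``steps`` times."""
    X = np.atleast_2d(np.asarray(x0, dtype=float))
    for _ in range(steps):
        X = cnet.step(X)
    return X if np.asarray(x0).ndim == 2 else X[0]


def boolean_trajectory_end(
    net: BooleanNetwork, X0: np.ndarray, steps: int
) -> np.ndarray:
    X = np.asarray(X0, dtype=np.uint8)
    for _ in range(steps):
        X = net.step_batch(X)
    return X


def mean_approximation_error(
    net: BooleanNetwork,
    m: int,
    n_ic: int = 1000,
    steps: int = 25,
    rng: np.random.Generator | None = None,
    initial_states: np.ndarray | None = None,
) -> float:
    """MAE of the order-m approximation from shared random initial states."""
    return mae_profile(
        net, (m,), n_ic=n_ic, steps=steps, rng=rng, initial_states=initial_states
    )[m]


def mae_profile(
    net: BooleanNetwork,
    orders,
    n_ic: int = 1000,
    steps: int = 25,
    rng: np.random.Generator | None = None,
    initial_states: np.ndarray | None = None,
) -> dict[int, float]:
    """MAE for several approximation orders from one shared set of initial
    states and one shared Boolean trajectory (variance reduction)."""
    if initial_states is None:
        rng = np.random.default_rng() if rng is None else rng
        initial_states = sample_initial_states(net.n, n_ic, rng)
    X0 = np.asarray(initial_states, dtype=np.uint8)
    B = boolean_trajectory_end(net, X0, steps).astype(float)
    out: dict[int, float] = {}
    for m in orders:
        cnet = approximate_network(net, m)
        C = simulate_continuous(cnet, X0.astype(float), steps)
        out[m] = float(np.mean((B - C) ** 2))
    return out
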