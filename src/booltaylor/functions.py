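"""Truth tables and elementary statistics of Boolean update functions.

A Boolean function f: {0,1}^k -> {0,1} is stored as the flat vector of its
2^k outputs.  The index convention is fixed throughout the package: the input
tuple (x_1, ..., x_k) maps to the index sum_i x_i * 2^(k-i), i.e. x_1 is the
most significant bit.  This convention round-trips through the rule-file
writer and the state-space encoding used by the dynamics module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InfeasibleError, InputShapeError, ParameterError, ResourceError

#: default cap on rejection-sampling attempts in all generators
MAX_REJECTIONS = 100_000


@dataclass(frozen=True)
class TruthTable:
    """A Boolean function of ``k`` named inputs as a 2^k output bit vector."""

    k: int
    outputs: np.ndarray
    variable_names: tuple[str, ...] | None = None

    def __post_init__(self):
        if self.k < 0:
            raise ParameterError(f"k must be >= 0, got {self.k}")
        out = np.ascontiguousarray(np.asarray(self.outputs), dtype=np.uint8)
        if out.ndim != 1 or out.size != 1 << self.k:
            raise InputShapeError(
                f"outputs must be a flat vector of length 2^{self.k}, got shape {out.shape}"
            )
        if out.size and out.max() > 1:
            raise InputShapeError("outputs entries must be 0 or 1")
        object.__setattr__(self, "outputs", out)
        if self.variable_names is not None:
            names = tuple(self.variable_names)
            if len(names) != self.k:
                raise InputShapeError("variable_names length must equal k")
            object.__setattr__(self, "variable_names", names)

    # -- index convention -------------------------------------------------
    @property
    def index_weights(self) -> np.ndarray:
        """Per-variable weight of the input-tuple -> index encoding (x_1 MSB)."""
        return 1 << np.arange(self.k - 1, -1, -1)

    def as_tensor(self) -> np.ndarray:
        """The outputs reshaped to a (2,)*k tensor; axis i is variable i."""
        return self.outputs.reshape((2,) * self.k)

    # -- evaluation --------------------------------------------------------
    def __call__(self, x) -> int:
        return self.evaluate(x)

    def evaluate(self, x) -> int:
        x = np.asarray(x, dtype=np.uint8)
        if x.shape != (self.k,):
            raise InputShapeError(f"expected {self.k} inputs, got shape {x.shape}")
        return int(self.outputs[int(x @ self.index_weights)])

    def evaluate_batch(self, X: np.ndarray) -> np.ndarray:
        """Evaluate on a (n_samples, k) bit matrix."""
        X = np.asarray(X)
        if X.ndim != 2 or X.shape[1] != self.k:
            raise InputShapeError(f"expected (n, {self.k}) bit matrix, got {X.shape}")
        if self.k == 0:
            return np.full(X.shape[0], self.outputs[0], dtype=np.uint8)
        return self.outputs[X.astype(np.int64) @ self.index_weights]

    # -- conveniences ------------------------------------------------------
    def is_constant(self) -> bool:
        return bool(self.outputs.min() == self.outputs.max())

    @classmethod
    def from_callable(cls, k: int, fn, variable_names=None) -> "TruthTable":
        """Tabulate a Python predicate over all 2^k input tuples (test helper)."""
        X = all_input_tuples(k)
        out = np.fromiter((fn(tuple(row)) for row in X), dtype=np.uint8, count=1 << k)
        return cls(k, out, variable_names)

    # -- plain-text serialization -----------------------------------------
    def to_text(self) -> str:
        """Serialize as ``k q`` header plus the 2^k output bit string."""
        bits = "".join(map(str, self.outputs.tolist()))
        return f"{self.k} {int(self.outputs.sum())}\n{bits}\n"

    @classmethod
    def from_text(cls, text: str) -> "TruthTable":
        lines = text.strip().split("\n")
        k, q = (int(v) for v in lines[0].split())
        out = np.frombuffer(lines[1].strip().encode(), dtype=np.uint8) - ord("0")
        tt = cls(k, out)
        if int(tt.outputs.sum()) != q:
            raise InputShapeError("ones-count in header disagrees with bit string")
        return tt


@dataclass(frozen=True)
class BiasSummary:
    """Output bias of a Boolean function and its absolute-bias transforms."""

    p: float
    abs_bias_linear: float  # 2|0.5 - p|
    abs_bias_quadratic: float  # 1 - 4p(1-p)
    ones_count: int


def all_input_tuples(k: int) -> np.ndarray:
    """All 2^k input tuples as a (2^k, k) bit matrix, in index order."""
    idx = np.arange(1 << k, dtype=np.int64)
    shifts = np.arange(k - 1, -1, -1)
    return ((idx[:, None] >> shifts) & 1).astype(np.uint8)


# ---------------------------------------------------------------------------
# elementary statistics
# ---------------------------------------------------------------------------

def essential_variables(tt: TruthTable) -> frozenset[int]:
    """Indices i such that flipping x_i changes the output for some context."""
    t = tt.as_tensor()
    ess = []
    for i in range(tt.k):
        if np.any(np.take(t, 0, axis=i) != np.take(t, 1, axis=i)):
            ess.append(i)
    return frozenset(ess)


def reduce_to_essential(tt: TruthTable) -> TruthTable:
    """Restrict to essential inputs; constants reduce to a 0-input table."""
    ess = sorted(essential_variables(tt))
    if len(ess) == tt.k:
        return tt
    indexer = tuple(slice(None) if i in ess else 0 for i in range(tt.k))
    out = tt.as_tensor()[indexer].reshape(-1)
    names = None
    if tt.variable_names is not None:
        names = tuple(tt.variable_names[i] for i in ess)
    return TruthTable(len(ess), out, names)


def bias(tt: TruthTable) -> BiasSummary:
    q = int(tt.outputs.sum())
    p = q / (1 << tt.k)
    return BiasSummary(
        p=p,
        abs_bias_linear=2.0 * abs(0.5 - p),
        abs_bias_quadratic=1.0 - 4.0 * p * (1.0 - p),
        ones_count=q,
    )


def average_sensitivity(tt: TruthTable) -> float:
    """Sum of variable influences Pr_x[f(x) != f(x ^ e_i)], x uniform.

    Calibration anchors: a random (k, p) function has expectation 2kp(1-p);
    a nested canalizing function has expectation 1.
    """
    t = tt.as_tensor()
    total = 0.0
    for i in range(tt.k):
        total += float(np.mean(np.take(t, 0, axis=i) != np.take(t, 1, axis=i)))
    return total


# ---------------------------------------------------------------------------
# unconstrained random-function generators
# ---------------------------------------------------------------------------

def random_function(k: int, p: float, rng: np.random.Generator) -> TruthTable:
    """Each of the 2^k outputs is independently 1 with probability p."""
    if not 0.0 <= p <= 1.0:
        raise ParameterError(f"bias p must lie in [0, 1], got {p}")
    return TruthTable(k, (rng.random(1 << k) < p).astype(np.uint8))


def random_function_exact_ones(k: int, q: int, rng: np.random.Generator) -> TruthTable:
    """Uniform over truth tables with exactly q ones (random Omega of size q)."""
    if not 0 <= q <= (1 << k):
        raise ParameterError(f"ones-count q must lie in [0, 2^{k}], got {q}")
    out = np.zeros(1 << k, dtype=np.uint8)
    out[rng.choice(1 << k, size=q, replace=False)] = 1
    return TruthTable(k, out)


def random_nondegenerate_function(
    k: int, p: float, rng: np.random.Generator, max_tries: int = MAX_REJECTIONS
) -> TruthTable:
    """Random (k, p) function conditioned on all k variables being essential."""
    if k < 1:
        raise ParameterError("non-degenerate functions need k >= 1")
    if not 0.0 < p < 1.0:
        raise InfeasibleError(
            f"no non-degenerate function can be drawn at p={p} with k={k}"
        )
    for _ in range(max_tries):
        tt = random_function(k, p, rng)
        if len(essential_variables(tt)) == k:
            return tt
    raise ResourceError(f"rejection cap {max_tries} exceeded (k={k}, p={p})")


def to_expression(tt: TruthTable, names: tuple[str, ...] | None = None) -> str:
    """Render as a logical expression (disjunction of minterms).

    Constant tables render as ``0``/``1``; the listed-but-irrelevant inputs of
    a constant rule are therefore not preserved by an expression round trip.
    """
    names = names or tt.variable_names or tuple(f"x{i+1}" for i in range(tt.k))
    if tt.k == 0 or tt.is_constant():
        return str(int(tt.outputs[0]))
    ones = np.flatnonzero(tt.outputs)
    rows = all_input_tuples(tt.k)[ones]
    terms = []
    for row in rows:
        lits = [n if v else f"!{n}" for n, v in zip(names, row)]
        terms.append("(" + " & ".join(lits) + ")")
    return " | ".join(terms)
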