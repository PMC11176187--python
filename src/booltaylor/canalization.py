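"""Canalization detection, layer decomposition, and constrained generators.

A Boolean function is *canalizing* if some variable x_i has an input a that
forces the output to b irrespective of all other inputs.  Iterating this on
the subfunction obtained when no canalizing variable receives its canalizing
input peels off variables in *layers* (maximal sets of simultaneously
canalizing variables, which always share their canalized output); the total
number of peeled variables is the *canalizing depth*, and depth = k makes the
function *nested canalizing* (NCF).  The decomposition into extended
monomial layers plus a non-canalizing core is unique (standard monomial
form), which is what makes the layer structure (k_1, ..., k_r) well defined;
for a non-degenerate function on k >= 2 variables the last layer of an NCF
always has k_r >= 2.

Conventions (documented, deliberately chosen):

* Constant functions are by default *not* canalizing; ``is_canalizing`` takes
  a ``constants_canalizing`` flag because some analyses count them as
  canalizing (the probability-of-canalization grids use the flag).
* The all-zero function has no standard monomial form; its report is defined
  by convention as depth k with a single layer (all inputs a_i = 0, outputs
  b_i = 0) and flagged ``is_constant``.  The constant-1 function follows the
  standard form with depth 0.
* When a single remaining variable is its own canalizing witness with both
  inputs (the identity/negation case), the witness with a = 0 is recorded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .errors import InfeasibleError, ParameterError, ResourceError
from .functions import (
    MAX_REJECTIONS,
    TruthTable,
    all_input_tuples,
    essential_variables,
    random_function,
    random_function_exact_ones,
    random_nondegenerate_function,
    reduce_to_essential,
)


@dataclass(frozen=True)
class CanalizationReport:
    """Canalizing depth, layer structure and cascade data of a function.

    ``order``, ``inputs`` and ``outputs`` list the peeled variables sigma(1..d)
    with their canalizing inputs a_i and canalized outputs b_i, flattened in
    peel order; ``layers`` gives the sizes (k_1, ..., k_r) of the peel stages.
    ``core`` is the first non-canalizing remainder, a function of the
    ``core_variables`` (original indices, ascending).  Reconstructing the
    cascade reproduces the source truth table exactly.
    """

    k: int
    depth: int
    layers: tuple[int, ...]
    order: tuple[int, ...]
    inputs: tuple[int, ...]
    outputs: tuple[int, ...]
    core: TruthTable
    core_variables: tuple[int, ...]
    is_constant: bool = False

    @property
    def is_canalizing(self) -> bool:
        return self.depth > 0 and not self.is_constant

    @property
    def is_ncf(self) -> bool:
        return self.depth == self.k and not self.is_constant

    def to_json_record(self) -> str:
        return json.dumps(
            {
                "k": self.k,
                "depth": self.depth,
                "layers": list(self.layers),
                "order": list(self.order),
                "inputs": list(self.inputs),
                "outputs": list(self.outputs),
                "core_variables": list(self.core_variables),
                "core_bits": "".join(map(str, self.core.outputs.tolist())),
                "is_constant": self.is_constant,
            }
        )


def _canalizing_witnesses(tensor: np.ndarray) -> list[tuple[int, int, int]]:
    """All (axis, input a, output b) with f|_{x_axis=a} constant; f non-constant."""
    out = []
    for i in range(tensor.ndim):
        for a in (0, 1):
            sub = np.take(tensor, a, axis=i)
            if sub.min() == sub.max():
                out.append((i, a, int(sub.flat[0])))
    return out


def is_canalizing(
    tt: TruthTable, constants_canalizing: bool = False
) -> tuple[bool, tuple[int, int, int] | None]:
    """Whether some (variable, input) pair fixes the output; with a witness.

    Returns ``(flag, witness)``; the witness is ``(i, a, b)`` or ``None``.
    Constant functions follow ``constants_canalizing`` and carry no witness.
    """
    if tt.is_constant():
        return constants_canalizing, None
    wit = _canalizing_witnesses(tt.as_tensor())
    if wit:
        i, a, b = min(wit)
        return True, (i, a, b)
    return False, None


def canalization_report(tt: TruthTable) -> CanalizationReport:
    """Greedy layer peeling to the unique standard monomial form."""
    k = tt.k
    if tt.is_constant():
        val = int(tt.outputs[0])
        if val == 0 and k > 0:
            # all-zero function: defined-by-convention report (depth k)
            return CanalizationReport(
                k=k,
                depth=k,
                layers=(k,),
                order=tuple(range(k)),
                inputs=(0,) * k,
                outputs=(0,) * k,
                core=TruthTable(0, np.array([0], dtype=np.uint8)),
                core_variables=(),
                is_constant=True,
            )
        return CanalizationReport(
            k=k,
            depth=0,
            layers=(),
            order=(),
            inputs=(),
            outputs=(),
            core=TruthTable(0, np.array([val], dtype=np.uint8)),
            core_variables=(),
            is_constant=True,
        )

    tensor = tt.as_tensor()
    remaining = list(range(k))
    layers: list[int] = []
    order: list[int] = []
    inputs: list[int] = []
    outputs: list[int] = []
    while True:
        if tensor.min() == tensor.max():
            # fully peeled: the remainder is the 0-variable constant "core"
            core = TruthTable(0, np.array([int(tensor.flat[0])], dtype=np.uint8))
            remaining = []
            break
        wit = _canalizing_witnesses(tensor)
        if not wit:
            core = TruthTable(len(remaining), tensor.reshape(-1))
            break
        # one witness per variable; prefer a = 0 (identity/negation tie-break)
        per_var: dict[int, tuple[int, int]] = {}
        for i, a, b in sorted(wit):
            per_var.setdefault(i, (a, b))
        layer_vars = sorted(per_var)
        layers.append(len(layer_vars))
        # restrict every layer variable to its non-canalizing input
        for i in layer_vars:
            a, b = per_var[i]
            order.append(remaining[i])
            inputs.append(a)
            outputs.append(b)
        for pos, i in enumerate(layer_vars):
            a, _ = per_var[i]
            tensor = np.take(tensor, 1 - a, axis=i - pos)
        for i in reversed(layer_vars):
            remaining.pop(i)
    return CanalizationReport(
        k=k,
        depth=len(order),
        layers=tuple(layers),
        order=tuple(order),
        inputs=tuple(inputs),
        outputs=tuple(outputs),
        core=core,
        core_variables=tuple(remaining),
    )


def reconstruct(report: CanalizationReport) -> TruthTable:
    """Rebuild the truth table from a report's cascade (round-trip check)."""
    return assemble_cascade(
        report.k,
        report.order,
        report.inputs,
        report.outputs,
        report.core,
        report.core_variables,
    )


def assemble_cascade(
    k: int,
    order: tuple[int, ...] | list[int],
    inputs,
    outputs,
    core: TruthTable,
    core_variables,
) -> TruthTable:
    """Fill a truth table from a canalizing cascade plus a core function."""
    X = all_input_tuples(k)
    out = np.empty(1 << k, dtype=np.uint8)
    mask = np.ones(1 << k, dtype=bool)
    for v, a, b in zip(order, inputs, outputs):
        sel = mask & (X[:, v] == a)
        out[sel] = b
        mask &= X[:, v] != a
    if mask.any():
        sub = X[np.flatnonzero(mask)][:, list(core_variables)]
        out[mask] = core.evaluate_batch(sub)
    return TruthTable(k, out)


def is_nested_canalizing(tt: TruthTable) -> bool:
    """All k listed variables eventually become canalizing (depth = k).

    Functions with a non-essential variable are never nested canalizing (that
    variable cannot canalize), and neither are constants; exactly 8 of the 16
    two-input functions qualify.
    """
    if tt.k == 0 or tt.is_constant():
        return False
    return canalization_report(tt).depth == tt.k


# ---------------------------------------------------------------------------
# constrained random generators
# ---------------------------------------------------------------------------

def random_noncanalizing_core(
    m: int,
    rng: np.random.Generator,
    ones_count: int | None = None,
    max_tries: int = MAX_REJECTIONS,
) -> TruthTable:
    """Random non-canalizing function with all m variables essential.

    ``m = 1`` is infeasible (both non-degenerate 1-input functions are
    canalizing), as are ones-counts in {0, 1, 2^m - 1, 2^m} for m >= 1.
    ``m = 0`` with ``ones_count`` in {0, 1} returns the empty (constant) core.
    """
    if m == 0:
        if ones_count is None:
            ones_count = int(rng.integers(0, 2))
        if ones_count not in (0, 1):
            raise ParameterError("a 0-variable core needs ones_count in {0, 1}")
        return TruthTable(0, np.array([ones_count], dtype=np.uint8))
    if m == 1:
        raise InfeasibleError("every non-degenerate 1-variable function is canalizing")
    if ones_count is not None and not 2 <= ones_count <= (1 << m) - 2:
        raise InfeasibleError(
            f"no non-canalizing function on {m} variables has {ones_count} ones"
        )
    for _ in range(max_tries):
        if ones_count is None:
            tt = random_function(m, 0.5, rng)
        else:
            tt = random_function_exact_ones(m, ones_count, rng)
        if tt.is_constant():
            continue
        if _canalizing_witnesses(tt.as_tensor()):
            continue
        if len(essential_variables(tt)) != m:
            continue
        return tt
    raise ResourceError(f"rejection cap {max_tries} exceeded (m={m}, q={ones_count})")


def _validate_depth(k: int, d: int) -> None:
    if not 0 <= d <= k:
        raise InfeasibleError(f"depth {d} invalid for k={k}")
    if d == k - 1:
        raise InfeasibleError(
            "exact depth k-1 is impossible: a 1-variable core is always canalizing"
        )


def _random_cascade_frame(k: int, d: int, rng: np.random.Generator):
    """Random variable order and canalizing inputs for a depth-d cascade."""
    order = tuple(int(v) for v in rng.permutation(k)[:d])
    inputs = tuple(int(a) for a in rng.integers(0, 2, size=d))
    core_vars = tuple(sorted(set(range(k)) - set(order)))
    return order, inputs, core_vars


def random_with_exact_depth(k: int, d: int, rng: np.random.Generator) -> TruthTable:
    """Random function with canalizing depth exactly d (unbiased core)."""
    _validate_depth(k, d)
    if d == 0:
        return random_noncanalizing_core(k, rng)
    order, inputs, core_vars = _random_cascade_frame(k, d, rng)
    outputs = tuple(int(b) for b in rng.integers(0, 2, size=d))
    if d == k:
        core = TruthTable(0, np.array([1 - outputs[-1]], dtype=np.uint8))
    else:
        core = random_noncanalizing_core(k - d, rng)
    return assemble_cascade(k, order, inputs, outputs, core, core_vars)


def random_with_exact_depth_and_bias(
    k: int,
    d: int,
    q: int,
    b_sequence,
    rng: np.random.Generator,
) -> TruthTable:
    """Random function with depth exactly d, ones-count exactly q, and the
    reference canalized-output sequence b_1..b_d (in peel/cascade order).

    The cascade region for step i holds 2^(k-i) states, so the core must carry
    ``q - sum_{i: b_i = 1} 2^(k-i)`` ones; infeasible combinations raise.
    """
    _validate_depth(k, d)
    b_sequence = tuple(int(b) for b in b_sequence)
    if len(b_sequence) != d:
        raise ParameterError("b_sequence must have length d")
    if d == 0:
        tt = random_noncanalizing_core(k, rng, ones_count=q)
        return tt
    q_cascade = sum((1 << (k - i - 1)) for i, b in enumerate(b_sequence) if b)
    q_core = q - q_cascade
    order, inputs, core_vars = _random_cascade_frame(k, d, rng)
    if d == k:
        if q_core != 1 - b_sequence[-1]:
            raise InfeasibleError(
                f"ones-count {q} unreachable with b-sequence {b_sequence} at depth k"
            )
        core = TruthTable(0, np.array([q_core], dtype=np.uint8))
    else:
        if not 2 <= q_core <= (1 << (k - d)) - 2:
            raise InfeasibleError(
                f"core ones-count {q_core} infeasible for a non-canalizing "
                f"{k - d}-variable core"
            )
        core = random_noncanalizing_core(k - d, rng, ones_count=q_core)
    return assemble_cascade(k, order, inputs, b_sequence, core, core_vars)


def random_with_min_depth(k: int, d_min: int, rng: np.random.Generator) -> TruthTable:
    """Random function with canalizing depth >= d_min (core may be canalizing).

    ``d_min = 0`` reduces to an unrestricted non-degenerate function.
    """
    if not 0 <= d_min <= k:
        raise ParameterError(f"d_min {d_min} invalid for k={k}")
    if d_min == 0:
        return random_nondegenerate_function(k, 0.5, rng)
    order, inputs, core_vars = _random_cascade_frame(k, d_min, rng)
    outputs = tuple(int(b) for b in rng.integers(0, 2, size=d_min))
    if d_min == k:
        core = TruthTable(0, np.array([1 - outputs[-1]], dtype=np.uint8))
    else:
        core = random_nondegenerate_function(k - d_min, 0.5, rng)
    return assemble_cascade(k, order, inputs, outputs, core, core_vars)


def random_ncf(k: int, rng: np.random.Generator) -> TruthTable:
    """Random nested canalizing function (uniform cascade: random order,
    inputs and independent canalized outputs)."""
    return random_with_exact_depth(k, k, rng)


def random_ncf_with_layers(
    k: int, layer_structure, rng: np.random.Generator
) -> TruthTable:
    """Random NCF with the exact layer structure (k_1, ..., k_r).

    Canalized outputs are constant within a layer and alternate between
    consecutive layers, which is what keeps the requested layer boundaries
    intact in the standard monomial form; sigma and the a_i are uniform.
    """
    layer_structure = tuple(int(v) for v in layer_structure)
    if not layer_structure or any(v < 1 for v in layer_structure):
        raise ParameterError("layer sizes must be positive")
    if sum(layer_structure) != k:
        raise ParameterError(f"layer sizes must sum to k={k}")
    if k >= 2 and layer_structure[-1] < 2:
        raise ParameterError("the last layer of an NCF with k >= 2 must have size >= 2")
    order, inputs, _ = _random_cascade_frame(k, k, rng)
    b0 = int(rng.integers(0, 2))
    outputs: list[int] = []
    for li, size in enumerate(layer_structure):
        outputs.extend([(b0 + li) % 2] * size)
    core = TruthTable(0, np.array([1 - outputs[-1]], dtype=np.uint8))
    return assemble_cascade(k, order, inputs, tuple(outputs), core, ())
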