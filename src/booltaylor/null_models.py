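"""Constrained rule-randomizations of a reference network (null models).

Every null model keeps the reference wiring diagram (essential regulators)
and replaces each update rule by a random function of the same degree:

* ``unconstrained`` — any non-constant random function;
* ``type1`` — additionally matches the rule's ones-count q (bias);
* ``type2`` — matches the rule's exact canalizing depth d (arbitrary bias);
* ``type3`` — matches degree, depth, the canalized-output sequence b_1..b_d
  and the core's ones-count, hence the bias as well.

Rules are essential-reduced before matching (a couple of percent of listed
regulators in curated models are inert, and keeping them would bias the
comparison).  External parameters (f_i = x_i) are copied unchanged — in
particular they are never replaced by the equally-constrained negation — and
constant rules, which have no degrees of freedom, are copied too.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .canalization import (
    canalization_report,
    random_with_exact_depth,
    random_with_exact_depth_and_bias,
)
from .errors import InfeasibleError, ParameterError, ResourceError
from .functions import (
    MAX_REJECTIONS,
    TruthTable,
    essential_variables,
    random_function,
    random_function_exact_ones,
)
from .network import BooleanNetwork, external_parameters

NULL_MODEL_TYPES = ("unconstrained", "type1", "type2", "type3")


@dataclass(frozen=True)
class NullModelSpec:
    """Which characteristics of the reference rules a null model matches."""

    model_type: str
    require_nondegenerate: bool = False

    def __post_init__(self):
        if self.model_type not in NULL_MODEL_TYPES:
            raise ParameterError(
                f"model_type must be one of {NULL_MODEL_TYPES}, got {self.model_type!r}"
            )

    @property
    def matches(self) -> dict[str, bool]:
        t = self.model_type
        return {
            "degree": True,
            "bias": t in ("type1", "type3"),
            "depth": t in ("type2", "type3"),
        }


def _replacement_rule(
    red: TruthTable,
    spec: NullModelSpec,
    rng: np.random.Generator,
    node_name: str,
) -> TruthTable:
    k = red.k
    t = spec.model_type
    try:
        if t == "unconstrained":
            for _ in range(MAX_REJECTIONS):
                g = random_function(k, 0.5, rng)
                if g.is_constant():
                    continue
                if spec.require_nondegenerate and len(essential_variables(g)) != k:
                    continue
                return g
            raise ResourceError("rejection cap exceeded")
        if t == "type1":
            q = int(red.outputs.sum())
            for _ in range(MAX_REJECTIONS):
                g = random_function_exact_ones(k, q, rng)
                if spec.require_nondegenerate and len(essential_variables(g)) != k:
                    continue
                return g
            raise ResourceError("rejection cap exceeded")
        report = canalization_report(red)
        if t == "type2":
            return random_with_exact_depth(k, report.depth, rng)
        return random_with_exact_depth_and_bias(
            k, report.depth, int(red.outputs.sum()), report.outputs, rng
        )
    except (InfeasibleError, ResourceError) as exc:
        raise type(exc)(f"node {node_name!r}: {exc}") from exc


def null_model(
    net: BooleanNetwork,
    spec: NullModelSpec | str,
    rng: np.random.Generator,
) -> BooleanNetwork:
    """One random null network matching ``spec`` against the reduced rules."""
    if isinstance(spec, str):
        spec = NullModelSpec(spec)
    ext = external_parameters(net)
    regulators, rules = [], []
    for j, (regs, red) in enumerate(net.reduced_rules()):
        regulators.append(regs)
        if j in ext or red.k == 0:
            rules.append(red)
            continue
        rules.append(_replacement_rule(red, spec, rng, net.names[j]))
    return BooleanNetwork(net.names, tuple(regulators), tuple(rules))


def null_ensemble(
    net: BooleanNetwork,
    spec: NullModelSpec | str,
    n_models: int,
    rng: np.random.Generator,
) -> tuple[list[BooleanNetwork], pd.DataFrame]:
    """Independent null models plus a per-rule constraint-audit table.

    The provenance table reports, for every model and node, the reference and
    realized degree, ones-count and canalizing depth.
    """
    if isinstance(spec, str):
        spec = NullModelSpec(spec)
    if n_models < 1:
        raise ParameterError("n_models must be >= 1")
    reference = net.reduced_rules()
    models, records = [], []
    for model_id in range(n_models):
        m = null_model(net, spec, rng)
        models.append(m)
        for j, (regs, red) in enumerate(reference):
            new = m.rules[j]
            records.append(
                {
                    "model": model_id,
                    "node": net.names[j],
                    "type": spec.model_type,
                    "k": red.k,
                    "q_ref": int(red.outputs.sum()),
                    "q_new": int(new.outputs.sum()),
                    "d_ref": canalization_report(red).depth,
                    "d_new": canalization_report(new).depth,
                }
            )
    return models, pd.DataFrame.from_records(records)
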