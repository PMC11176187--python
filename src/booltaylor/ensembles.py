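"""Random-network generators: N-K Kauffman families and a pseudo-biological
ensemble.

The Kauffman-style families share one wiring model — every node receives
exactly K distinct regulators other than itself, and the whole digraph must
be strongly connected (otherwise the dynamics decouple); wirings failing the
connectivity check are regenerated from scratch, which preserves the uniform
conditional distribution.  Rule families:

* ``kauffman`` — i.i.d. outputs with bias p;
* ``kauffman_nondegenerate`` — as above, conditioned on all inputs essential;
* ``min_depth`` — canalizing depth at least d (cascade with a free core);
* ``ncf_layers`` — nested canalizing with a prescribed layer structure.

The pseudo-biological generator emulates the broad statistics of curated
regulatory-network models: sparse in-degrees (mean about 2.5, capped at 10),
a large fraction of nested canalizing rules, and a few external parameters
(constant inputs modelled as self-identities).  It is a synthetic stand-in,
not a reproduction of any curated corpus.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .canalization import random_ncf, random_ncf_with_layers, random_with_min_depth
from .errors import ParameterError, ResourceError
from .functions import TruthTable, random_function, random_nondegenerate_function
from .network import BooleanNetwork

_IDENTITY_RULE = TruthTable(1, np.array([0, 1], dtype=np.uint8))

FAMILIES = ("kauffman", "kauffman_nondegenerate", "min_depth", "ncf_layers")


@dataclass(frozen=True)
class EnsembleSpec:
    """Parameters of one random-network family."""

    N: int
    K: int
    family: str = "kauffman"
    p: float = 0.5
    d_min: int | None = None
    layer_structure: tuple[int, ...] | None = None
    replicates: int = 1

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ParameterError(f"unknown family {self.family!r}")
        if self.N <= self.K:
            raise ParameterError("need N > K for a simple K-in-regular digraph")
        if self.family == "min_depth" and self.d_min is None:
            raise ParameterError("min_depth family needs d_min")
        if self.family == "ncf_layers":
            if self.layer_structure is None:
                raise ParameterError("ncf_layers family needs a layer structure")
            if sum(self.layer_structure) != self.K:
                raise ParameterError("layer structure must sum to K")


def random_regular_digraph(
    N: int, K: int, rng: np.random.Generator, max_tries: int = 10_000
) -> tuple[tuple[int, ...], ...]:
    """Per-node regulator tuples of a strongly connected, simple, K-in-regular
    digraph (no self-loops, no duplicate edges)."""
    if not 1 <= K < N:
        raise ParameterError(f"need N > K >= 1, got N={N}, K={K}")
    for _ in range(max_tries):
        regulators = []
        for j in range(N):
            choices = np.concatenate([np.arange(j), np.arange(j + 1, N)])
            regulators.append(tuple(int(v) for v in rng.choice(choices, K, replace=False)))
        g = nx.DiGraph((i, j) for j, regs in enumerate(regulators) for i in regs)
        g.add_nodes_from(range(N))
        if nx.is_strongly_connected(g):
            return tuple(regulators)
    raise ResourceError(f"no strongly connected wiring found in {max_tries} tries")


def _family_rule(spec: EnsembleSpec, rng: np.random.Generator):
    if spec.family == "kauffman":
        return random_function(spec.K, spec.p, rng)
    if spec.family == "kauffman_nondegenerate":
        return random_nondegenerate_function(spec.K, spec.p, rng)
    if spec.family == "min_depth":
        return random_with_min_depth(spec.K, spec.d_min, rng)
    return random_ncf_with_layers(spec.K, spec.layer_structure, rng)


def generate_network(spec: EnsembleSpec, rng: np.random.Generator) -> BooleanNetwork:
    """One network: regular strongly connected wiring, independent rules."""
    regulators = random_regular_digraph(spec.N, spec.K, rng)
    names = tuple(f"x{j+1}" for j in range(spec.N))
    rules = tuple(_family_rule(spec, rng) for _ in range(spec.N))
    return BooleanNetwork(names, regulators, rules)


def generate_ensemble(
    spec: EnsembleSpec, rng: np.random.Generator
) -> list[BooleanNetwork]:
    return [generate_network(spec, rng) for _ in range(spec.replicates)]


def shifted_poisson_degree_sampler(
    mean_degree: float = 2.5, max_degree: int = 10
):
    """1 + Poisson(mean - 1), re-drawn until <= max_degree (mean ~= 2.5)."""
    if mean_degree <= 1:
        raise ParameterError("mean_degree must exceed 1")

    def sample(rng: np.random.Generator) -> int:
        while True:
            k = 1 + int(rng.poisson(mean_degree - 1))
            if k <= max_degree:
                return k

    return sample


def pseudo_biological_network(
    N: int,
    rng: np.random.Generator,
    degree_sampler=None,
    ncf_fraction: float = 0.95,
    n_external: int = 0,
) -> BooleanNetwork:
    """Synthetic stand-in for a curated regulatory-network model.

    ``n_external`` nodes get the self-identity rule; the remaining nodes draw
    an in-degree from ``degree_sampler`` (default: shifted Poisson with mean
    2.5 capped at 10) and a rule that is a random NCF with probability
    ``ncf_fraction``, otherwise a random non-degenerate unbiased function.
    Self-regulation is allowed for non-external nodes, as in curated models.
    """
    if not 0 <= n_external <= N:
        raise ParameterError("need 0 <= n_external <= N")
    if not 0.0 <= ncf_fraction <= 1.0:
        raise ParameterError("ncf_fraction must lie in [0, 1]")
    degree_sampler = degree_sampler or shifted_poisson_degree_sampler()
    names = tuple(f"x{j+1}" for j in range(N))
    ext = set(int(v) for v in rng.choice(N, size=n_external, replace=False))
    regulators, rules = [], []
    for j in range(N):
        if j in ext:
            regulators.append((j,))
            rules.append(_IDENTITY_RULE)
            continue
        k = min(degree_sampler(rng), N)
        regs = tuple(int(v) for v in rng.choice(N, size=k, replace=False))
        regulators.append(regs)
        if rng.random() < ncf_fraction:
            rules.append(random_ncf(k, rng))
        else:
            rules.append(random_nondegenerate_function(k, 0.5, rng))
    return BooleanNetwork(names, tuple(regulators), tuple(rules))
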