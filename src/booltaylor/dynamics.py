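"""Attractor analysis and dynamics metrics of synchronous Boolean networks.

States are encoded as integers with node 0 the most significant bit, matching
the truth-table index convention.  Attractor identity is the lexicographically
minimal rotation of the cycle, which makes deduplication across trajectories
deterministic.  The basin entropy uses the natural logarithm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .errors import ResourceError
from .functions import average_sensitivity
from .network import BooleanNetwork, external_parameters

#: default cap on exact state-space enumeration
EXACT_STATE_CAP = 20


@dataclass(frozen=True)
class AttractorSet:
    """Attractors (canonical cycles of integer-coded states), their lengths
    and basin counts; ``mode`` records whether basins are exact sizes or
    sampled hits over ``n_initial`` initial conditions."""

    n: int
    attractors: tuple[tuple[int, ...], ...]
    basin_counts: np.ndarray
    mode: str  # "exact" | "sampled"
    n_initial: int

    @property
    def s(self) -> int:
        return len(self.attractors)

    @property
    def lengths(self) -> np.ndarray:
        return np.array([len(a) for a in self.attractors], dtype=int)

    def states_as_bits(self, attractor_index: int) -> np.ndarray:
        shifts = np.arange(self.n - 1, -1, -1)
        arr = np.array(self.attractors[attractor_index], dtype=np.int64)
        return ((arr[:, None] >> shifts) & 1).astype(np.uint8)

    def to_json(self) -> str:
        return json.dumps(
            {
                "n": self.n,
                "mode": self.mode,
                "n_initial": self.n_initial,
                "attractors": [
                    ["".join(map(str, row.tolist())) for row in self.states_as_bits(i)]
                    for i in range(self.s)
                ],
                "basin_counts": [int(b) for b in self.basin_counts],
            }
        )


def _canonical_cycle(cycle: list[int]) -> tuple[int, ...]:
    """Rotate the cycle to start at its minimal state."""
    i = int(np.argmin(cycle))
    return tuple(cycle[i:] + cycle[:i])


def _state_bits(states: np.ndarray, n: int) -> np.ndarray:
    shifts = np.arange(n - 1, -1, -1)
    return ((np.asarray(states, dtype=np.int64)[:, None] >> shifts) & 1).astype(np.uint8)


def _pack_bits(X: np.ndarray) -> np.ndarray:
    n = X.shape[1]
    weights = (1 << np.arange(n - 1, -1, -1)).astype(np.int64)
    return X.astype(np.int64) @ weights


def successor_table(net: BooleanNetwork) -> np.ndarray:
    """The full synchronous map as an integer array of length 2^n."""
    states = _state_bits(np.arange(1 << net.n), net.n)
    return _pack_bits(net.step_batch(states))


def exact_attractors(net: BooleanNetwork, cap: int = EXACT_STATE_CAP) -> AttractorSet:
    """Exhaustive state-space decomposition into basins of attraction."""
    n = net.n
    if n > cap:
        raise ResourceError(
            f"n={n} exceeds the exact-mode cap ({cap}); use sampled_attractors"
        )
    succ = successor_table(net)
    basin = np.full(1 << n, -1, dtype=np.int64)
    attractors: list[tuple[int, ...]] = []
    for s in range(1 << n):
        if basin[s] != -1:
            continue
        path: list[int] = []
        pos: dict[int, int] = {}
        cur = s
        while basin[cur] == -1 and cur not in pos:
            pos[cur] = len(path)
            path.append(cur)
            cur = int(succ[cur])
        if basin[cur] != -1:
            b = int(basin[cur])
        else:
            cycle = path[pos[cur]:]
            attractors.append(_canonical_cycle(cycle))
            b = len(attractors) - 1
        basin[path] = b
    counts = np.bincount(basin, minlength=len(attractors))
    return AttractorSet(n, tuple(attractors), counts, "exact", 1 << n)


def sample_initial_states(
    n: int, n_ic: int, rng: np.random.Generator
) -> np.ndarray:
    """``n_ic`` distinct initial states as a bit matrix; all 2^n states when
    the state space is no larger than the request (sampling without
    replacement, per the study procedure)."""
    if n <= 25 and (1 << n) <= n_ic:
        return _state_bits(np.arange(1 << n), n)
    if n <= 25:
        ints = rng.choice(1 << n, size=n_ic, replace=False)
        return _state_bits(ints, n)
    # large state space: collisions are vanishingly rare; sample and top up
    seen: set[int] = set()
    rows = []
    while len(rows) < n_ic:
        X = rng.integers(0, 2, size=(n_ic - len(rows), n), dtype=np.uint8)
        for row in X:
            key = hash(row.tobytes())
            if key not in seen:
                seen.add(key)
                rows.append(row)
    return np.array(rows, dtype=np.uint8)


def sampled_attractors(
    net: BooleanNetwork,
    n_ic: int = 1000,
    rng: np.random.Generator | None = None,
) -> AttractorSet:
    """Attractors reached from ``n_ic`` distinct random initial states.

    Each trajectory is iterated until a repeated state; the cycle between the
    first and second visit of the repeat state is the attractor.  The number
    of attractors found is a lower bound of the true count.
    """
    rng = np.random.default_rng() if rng is None else rng
    n = net.n
    X0 = sample_initial_states(n, n_ic, rng)
    n_ic = X0.shape[0]
    state_to_attractor: dict[int, int] = {}
    attractor_index: dict[tuple[int, ...], int] = {}
    attractors: list[tuple[int, ...]] = []
    active = list(range(n_ic))
    X = X0.copy()
    histories: list[list[int]] = [[] for _ in range(n_ic)]
    positions: list[dict[int, int]] = [{} for _ in range(n_ic)]
    basin_of: np.ndarray = np.full(n_ic, -1, dtype=int)
    codes = _pack_bits(X)
    while active:
        still = []
        for t in active:
            c = int(codes[t])
            if c in state_to_attractor:
                basin_of[t] = state_to_attractor[c]
                for s in histories[t]:
                    state_to_attractor.setdefault(s, basin_of[t])
                continue
            if c in positions[t]:
                cycle = histories[t][positions[t][c]:]
                key = _canonical_cycle(cycle)
                if key not in attractor_index:
                    attractor_index[key] = len(attractors)
                    attractors.append(key)
                b = attractor_index[key]
                basin_of[t] = b
                for s in histories[t]:
                    state_to_attractor.setdefault(s, b)
                continue
            positions[t][c] = len(histories[t])
            histories[t].append(c)
            still.append(t)
        if not still:
            break
        idx = np.array(still, dtype=int)
        X[idx] = net.step_batch(X[idx])
        codes[idx] = _pack_bits(X[idx])
        active = still
    counts = np.bincount(basin_of, minlength=len(attractors))
    return AttractorSet(n, tuple(attractors), counts, "sampled", n_ic)


def attractor_metrics(aset: AttractorSet) -> dict[str, float]:
    """Mean length, steady-state proportion (plain and basin-weighted),
    basin entropy (natural log) and attractor count."""
    L = aset.lengths
    B = aset.basin_counts.astype(float)
    w = B / B.sum()
    steady = (L == 1).astype(float)
    return {
        "n_attractors": float(aset.s),
        "mean_length": float(L.mean()),
        "prop_steady": float(steady.mean()),
        "mean_length_weighted": float((w * L).sum()),
        "prop_steady_weighted": float((w * steady).sum()),
        "basin_entropy": float(-(w * np.log(w)).sum()),
    }


def attractors_per_external_configuration(
    net: BooleanNetwork, cap: int = EXACT_STATE_CAP
) -> float:
    """Exact attractor count divided by the 2^c external-parameter
    configurations; each configuration retains at least one attractor."""
    c = len(external_parameters(net))
    return exact_attractors(net, cap=cap).s / (1 << c)


def network_average_sensitivity(net: BooleanNetwork) -> float:
    """Mean over nodes of the rules' average sensitivity (Derrida coefficient).

    Computed on the rules as listed; non-essential inputs have zero influence,
    so reduction would not change the value.
    """
    return float(np.mean([average_sensitivity(rule) for rule in net.rules]))
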