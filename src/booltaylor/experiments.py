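"""Experiment runners producing tidy result tables.

Each runner generates its own networks from an explicit seed, shares the
initial conditions (and the Boolean reference trajectory) across
approximation orders within a network, and returns pandas DataFrames keyed by
condition; the per-row seeds make every table reproducible.  Replicate
counts are parameters everywhere — the study-scale values (100 networks per
condition, 1000 initial states, 25 steps) are the defaults of the analysis
scripts, while tests run reduced sizes.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .approximation import mae_profile
from .canalization import is_canalizing, is_nested_canalizing
from .dynamics import attractor_metrics, exact_attractors, network_average_sensitivity
from .ensembles import EnsembleSpec, generate_network
from .functions import random_function
from .network import BooleanNetwork
from .null_models import NullModelSpec, null_ensemble, null_model
from .pipeline import dynamical_predictors, paired_comparison, spearman_screen


def _spawn(rng_or_seed) -> np.random.Generator:
    if isinstance(rng_or_seed, np.random.Generator):
        return rng_or_seed
    return np.random.default_rng(rng_or_seed)


def network_mae_record(
    net: BooleanNetwork,
    orders: Sequence[int],
    n_ic: int,
    steps: int,
    rng: np.random.Generator,
    with_dynamics: bool = False,
) -> dict[str, float]:
    rec: dict[str, float] = {
        "mean_avg_sensitivity": network_average_sensitivity(net),
    }
    profile = mae_profile(net, orders, n_ic=n_ic, steps=steps, rng=rng)
    for m, v in profile.items():
        rec[f"mae_order{m}"] = v
    if with_dynamics:
        rec.update(attractor_metrics(exact_attractors(net)))
    return rec


def mae_bias_degree_grid(
    K_values: Sequence[int] = (2, 3, 4, 5),
    p_values: Sequence[float] = (0.1, 0.2, 0.3, 0.4, 0.5),
    reps: int = 100,
    orders: Sequence[int] = (1, 2, 3, 4),
    N: int = 15,
    n_ic: int = 1000,
    steps: int = 25,
    seed: int | np.random.Generator = 0,
    family: str = "kauffman",
    with_dynamics: bool = False,
) -> pd.DataFrame:
    """MAE of K-regular strongly connected networks across a (K, p) grid.

    One row per network with its per-order MAE values, mean average
    sensitivity and (optionally) exact attractor metrics.
    """
    rng = _spawn(seed)
    rows = []
    for K in K_values:
        for p in p_values:
            for rep in range(reps):
                spec = EnsembleSpec(N=N, K=K, family=family, p=p)
                net = generate_network(spec, rng)
                rec = network_mae_record(net, orders, n_ic, steps, rng, with_dynamics)
                rec.update({"K": K, "p": p, "rep": rep})
                rows.append(rec)
    return pd.DataFrame(rows)


def mae_by_min_depth(
    depths: Sequence[int] = (0, 1, 2, 4),
    reps: int = 100,
    orders: Sequence[int] = (1, 2, 3, 4),
    N: int = 15,
    K: int = 4,
    n_ic: int = 1000,
    steps: int = 25,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """MAE of networks whose rules have a minimal canalizing depth.

    Depth 0 means no canalization requirement (non-degenerate unbiased
    rules); realized depths may exceed the minimum because the cascade core
    is left free.
    """
    rng = _spawn(seed)
    rows = []
    for d in depths:
        for rep in range(reps):
            if d == 0:
                spec = EnsembleSpec(N=N, K=K, family="kauffman_nondegenerate", p=0.5)
            else:
                spec = EnsembleSpec(N=N, K=K, family="min_depth", d_min=d)
            net = generate_network(spec, rng)
            rec = network_mae_record(net, orders, n_ic, steps, rng)
            rec.update({"d_min": d, "rep": rep})
            rows.append(rec)
    return pd.DataFrame(rows)


def mae_by_layer_structure(
    layer_structures: Sequence[tuple[int, ...]] = ((4,), (3, 1), (2, 2), (1, 3)),
    reps: int = 100,
    orders: Sequence[int] = (1, 2, 3, 4),
    N: int = 15,
    n_ic: int = 1000,
    steps: int = 25,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """MAE of networks governed entirely by NCFs with a fixed layer structure.

    Structures whose last layer would have size 1 are normalized the way the
    cascade realizes them (e.g. (3, 1) -> (4), (1, 2, 1) -> (1, 3)); pass
    valid structures to avoid the implied merge.
    """
    rng = _spawn(seed)
    rows = []
    for layers in layer_structures:
        layers = tuple(layers)
        realized = layers if layers[-1] >= 2 or sum(layers) == 1 else (
            layers[:-2] + (layers[-2] + layers[-1],)
        )
        K = sum(layers)
        for rep in range(reps):
            spec = EnsembleSpec(N=N, K=K, family="ncf_layers", layer_structure=realized)
            net = generate_network(spec, rng)
            rec = network_mae_record(net, orders, n_ic, steps, rng)
            rec.update({"layers": "-".join(map(str, layers)), "rep": rep})
            rows.append(rec)
    return pd.DataFrame(rows)


def canalization_probability_grid(
    k_values: Sequence[int] = (1, 2, 3, 4, 5),
    p_values: Sequence[float] = (0.1, 0.2, 0.3, 0.4, 0.5),
    n_functions: int = 1000,
    seed: int | np.random.Generator = 0,
    constants_canalizing: bool = True,
) -> pd.DataFrame:
    """Probability that a random (k, p) function is canalizing / nested
    canalizing, per grid cell (constants count as canalizing by default,
    matching the usual presentation of these grids)."""
    rng = _spawn(seed)
    rows = []
    for k in k_values:
        for p in p_values:
            canal = 0
            ncf = 0
            for _ in range(n_functions):
                tt = random_function(k, p, rng)
                if is_canalizing(tt, constants_canalizing=constants_canalizing)[0]:
                    canal += 1
                if is_nested_canalizing(tt):
                    ncf += 1
            rows.append(
                {
                    "k": k,
                    "p": p,
                    "prob_canalizing": canal / n_functions,
                    "prob_ncf": ncf / n_functions,
                    "n_functions": n_functions,
                }
            )
    return pd.DataFrame(rows)


def null_model_mae_comparison(
    corpus: Sequence[BooleanNetwork],
    types: Sequence[str] = ("unconstrained", "type1", "type2", "type3"),
    orders: Sequence[int] = (1, 2, 3),
    n_ic: int = 1000,
    steps: int = 25,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """MAE of each corpus network and one null model per type, plus paired
    two-sided Wilcoxon tests per (type, order)."""
    rng = _spawn(seed)
    rows = []
    for i, net in enumerate(corpus):
        profile = mae_profile(net, orders, n_ic=n_ic, steps=steps, rng=rng)
        for m, v in profile.items():
            rows.append({"network": i, "model": "reference", "order": m, "mae": v})
        for t in types:
            nm = null_model(net, NullModelSpec(t), rng)
            profile = mae_profile(nm, orders, n_ic=n_ic, steps=steps, rng=rng)
            for m, v in profile.items():
                rows.append({"network": i, "model": t, "order": m, "mae": v})
    table = pd.DataFrame(rows)
    tests = []
    ref = table[table.model == "reference"]
    for t in types:
        for m in orders:
            a = ref[ref.order == m].sort_values("network")["mae"].to_numpy()
            b = table[(table.model == t) & (table.order == m)].sort_values("network")[
                "mae"
            ].to_numpy()
            rec = paired_comparison(a, b)
            rec.update({"model": t, "order": m})
            tests.append(rec)
    return table, pd.DataFrame(tests)


def null_model_attractor_variability(
    corpus: Sequence[BooleanNetwork],
    types: Sequence[str] = ("type1", "type2", "type3"),
    n_models: int = 100,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Mean and standard deviation, across each null ensemble, of the exact
    attractor count per external-parameter configuration (corpus networks
    must be small enough for exact mode)."""
    from .dynamics import attractors_per_external_configuration

    rng = _spawn(seed)
    rows = []
    for i, net in enumerate(corpus):
        for t in types:
            models, _ = null_ensemble(net, NullModelSpec(t), n_models, rng)
            vals = np.array(
                [attractors_per_external_configuration(m) for m in models]
            )
            rows.append(
                {
                    "network": i,
                    "type": t,
                    "mean_attractors_per_config": float(vals.mean()),
                    "sd_attractors_per_config": float(vals.std(ddof=1)),
                    "n_models": n_models,
                }
            )
    return pd.DataFrame(rows)


def dynamics_mae_correlation(table: pd.DataFrame, orders=(1, 2, 3)) -> pd.DataFrame:
    """Spearman correlations between per-network MAE columns and the
    dynamics-related columns of a grid table."""
    mae_cols = [f"mae_order{m}" for m in orders if f"mae_order{m}" in table]
    dyn_cols = [
        c
        for c in (
            "mean_avg_sensitivity",
            "n_attractors",
            "mean_length",
            "prop_steady",
            "basin_entropy",
        )
        if c in table
    ]
    return spearman_screen(table, mae_cols + dyn_cols).loc[dyn_cols, mae_cols]
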