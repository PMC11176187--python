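"""Which network properties predict approximability?

Assembles, for a pseudo-biological corpus, a per-network table of structural
predictors (degree, bias, canalization, motif counts), dynamical predictors
(attractors, steady states, basin entropy) and MAE values (orders 1-3); then
runs a Spearman rank-correlation screen and traces LASSO regularization
paths for each MAE order until nine predictors are active.

Desk scale: 20 networks of 12 nodes, sampled dynamics with 300 initial
states, MAE from 300 initial states and 25 steps.
"""

import pathlib

import numpy as np
import pandas as pd

from booltaylor import mae_profile, spearman_screen, structural_predictors
from booltaylor.ensembles import pseudo_biological_network
from booltaylor.pipeline import dynamical_predictors, lasso_path, standardize

OUT = pathlib.Path(__file__).resolve().parent.parent / "results"
SEED = 20240615


def main():
    rng = np.random.default_rng(SEED)
    rows = []
    for i in range(20):
        net = pseudo_biological_network(12, rng, n_external=int(rng.integers(0, 2)))
        rec = {"network": i}
        rec.update(structural_predictors(net))
        rec.update(dynamical_predictors(net, mode="sampled", n_ic=300, rng=rng))
        for m, v in mae_profile(net, (1, 2, 3), n_ic=300, steps=25, rng=rng).items():
            rec[f"mae_order{m}"] = v
        rows.append(rec)
    table = pd.DataFrame(rows).set_index("network")
    OUT.mkdir(exist_ok=True)
    table.to_csv(OUT / "predictor_table.csv")

    predictors = [
        c for c in table.columns
        if not c.startswith("mae_order") and c != "dynamics_mode"
        and table[c].nunique() > 1
    ]
    screen = spearman_screen(table, predictors + [f"mae_order{m}" for m in (1, 2, 3)])
    screen.to_csv(OUT / "predictor_spearman.csv")
    print("Spearman correlation of each predictor with the MAE (by order):")
    print(screen.loc[predictors, [f"mae_order{m}" for m in (1, 2, 3)]].round(3))

    X = standardize(table[predictors].to_numpy())
    path_rows = []
    for m in (1, 2, 3):
        y = standardize(table[[f"mae_order{m}"]].to_numpy()).ravel()
        path = lasso_path(X, y, predictor_names=predictors, n_nonzero_stop=9)
        final = pd.Series(path.coefficients[:, -1], index=predictors)
        active = final[final != 0].sort_values(key=np.abs, ascending=False)
        print(f"\norder-{m} LASSO: {len(active)} active predictors at "
              f"alpha={path.alphas[-1]:.4g}:")
        print(active.round(3))
        for alpha, coefs in zip(path.alphas, path.coefficients.T):
            for name, c in zip(predictors, coefs):
                path_rows.append(
                    {"order": m, "alpha": alpha, "predictor": name, "beta": c}
                )
    pd.DataFrame(path_rows).to_csv(OUT / "lasso_paths.csv", index=False)


if __name__ == "__main__":
    main()
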