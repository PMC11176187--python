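"""Statistical layer: predictor extraction, rank-correlation screens, paired
Wilcoxon comparisons, and LASSO regularization paths.

The LASSO solves min_beta (1/N) ||y - X beta||_2^2 + alpha ||beta||_1 by
cyclic coordinate descent on standardized inputs.  Note the 1/N (not 1/(2N))
scaling of the quadratic term: it shifts the alpha axis by a factor of two
relative to scikit-learn's convention, and all coefficients become zero for
alpha >= 2 max_j |x_j^T y| / N.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .canalization import canalization_report, is_nested_canalizing
from .dynamics import (
    attractor_metrics,
    exact_attractors,
    network_average_sensitivity,
    sampled_attractors,
)
from .errors import InputShapeError, ParameterError
from .functions import average_sensitivity, bias
from .network import BooleanNetwork, wiring_diagram


# ---------------------------------------------------------------------------
# predictors
# ---------------------------------------------------------------------------

def count_ffls(g: nx.DiGraph) -> int:
    """Ordered feed-forward triples i->j, j->k, i->k (no self-loops counted)."""
    A = nx.to_numpy_array(g, nodelist=sorted(g.nodes), weight=None)
    np.fill_diagonal(A, 0)
    return int(((A @ A) * A).sum())

def count_simple_cycles(g: nx.DiGraph, length: int) -> int:
    """Simple directed cycles of exactly the given length."""
    g2 = nx.DiGraph(g)
    g2.remove_edges_from(nx.selfloop_edges(g2))
    return sum(1 for c in nx.simple_cycles(g2, length_bound=length) if len(c) == length)


def structural_predictors(net: BooleanNetwork) -> dict[str, float]:
    """Structure- and rule-level network properties (means over reduced rules,
    motif counts over the essential wiring diagram)."""
    reduced = net.reduced_rules()
    biases = [bias(red) for _, red in reduced]
    ks = np.array([red.k for _, red in reduced], dtype=float)
    pq = np.array([b.p * (1 - b.p) for b in biases])
    depth_ratio = [
        canalization_report(red).depth / red.k for _, red in reduced if red.k >= 1
    ]
    g = wiring_diagram(net).to_networkx()
    return {
        "n_nodes": float(net.n),
        "mean_degree": float(ks.mean()),
        "mean_bias_product": float(pq.mean()),
        "mean_abs_bias": float(np.mean([b.abs_bias_linear for b in biases])),
        "cov_biasproduct_degree": float(np.cov(pq, ks, ddof=0)[0, 1]),
        "mean_norm_canalizing_depth": float(np.mean(depth_ratio)) if depth_ratio else 0.0,
        "prop_ncf": float(np.mean([is_nested_canalizing(red) for _, red in reduced])),
        "n_ffl": float(count_ffls(g)),
        "n_3loops": float(count_simple_cycles(g, 3)),
        "n_4loops": float(count_simple_cycles(g, 4)),
        "mean_avg_sensitivity": float(
            np.mean([average_sensitivity(red) for _, red in reduced])
        ),
    }


def dynamical_predictors(
    net: BooleanNetwork,
    mode: str = "exact",
    n_ic: int = 1000,
    rng: np.random.Generator | None = None,
) -> dict[str, float]:
    """Attractor-based properties; mode ``exact`` enumerates the state space,
    ``sampled`` follows trajectories from random initial states."""
    if mode == "exact":
        aset = exact_attractors(net)
    elif mode == "sampled":
        aset = sampled_attractors(net, n_ic=n_ic, rng=rng)
    else:
        raise ParameterError("mode must be 'exact' or 'sampled'")
    rec = attractor_metrics(aset)
    rec["dynamics_mode"] = 0.0 if mode == "exact" else 1.0
    return rec


# ---------------------------------------------------------------------------
# screens and tests
# ---------------------------------------------------------------------------

def spearman_screen(table: pd.DataFrame, columns=None) -> pd.DataFrame:
    """Spearman rank-correlation matrix (average ranks for ties).

    Constant columns yield NaN entries and a warning — never a silent 0.
    """
    cols = list(columns) if columns is not None else list(table.columns)
    if len(table) < 3:
        raise InputShapeError("need at least 3 rows for a rank correlation")
    data = table[cols].to_numpy(dtype=float)
    constant = [c for i, c in enumerate(cols) if np.ptp(data[:, i]) == 0]
    if constant:
        warnings.warn(f"constant columns yield undefined correlations: {constant}")
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        rho = stats.spearmanr(data).statistic
    if np.ndim(rho) == 0:  # spearmanr collapses the 2-column case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    out = pd.DataFrame(rho, index=cols, columns=cols)
    np.fill_diagonal(out.values, 1.0)
    for c in constant:
        out.loc[c, :] = np.nan
        out.loc[:, c] = np.nan
    return out


def paired_comparison(mae_a, mae_b) -> dict[str, float]:
    """Two-sided Wilcoxon signed-rank test on paired per-network values.

    Zero differences are discarded (the classic 'wilcox' convention); an
    all-zero difference vector is flagged degenerate instead of tested.
    """
    a = np.asarray(mae_a, dtype=float)
    b = np.asarray(mae_b, dtype=float)
    if a.shape != b.shape:
        raise InputShapeError("paired vectors must have equal length")
    if np.all(a == b):
        return {"statistic": np.nan, "p_value": np.nan, "n": len(a), "degenerate": True}
    res = stats.wilcoxon(a, b, alternative="two-sided", zero_method="wilcox")
    return {
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "n": int(len(a)),
        "degenerate": False,
    }


# ---------------------------------------------------------------------------
# LASSO
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LassoPath:
    """Coefficients along a decreasing alpha grid, reported down to the first
    alpha at which ``n_nonzero_stop`` predictors are active."""

    alphas: np.ndarray  # decreasing
    coefficients: np.ndarray  # (n_predictors, n_alphas)
    predictor_names: tuple[str, ...]
    n_nonzero_stop: int

    @property
    def n_nonzero(self) -> np.ndarray:
        return (self.coefficients != 0).sum(axis=0)


def _check_standardized(M: np.ndarray, what: str) -> None:
    mean = M.mean(axis=0)
    sd = M.std(axis=0)
    if np.any(np.abs(mean) > 1e-8) or np.any(np.abs(sd - 1) > 1e-6):
        raise ParameterError(
            f"{what} must be standardized to mean 0 and sd 1 before the fit"
        )


def standardize(M: np.ndarray) -> np.ndarray:
    """Column-wise (x - mean) / sd; population (ddof=0) standard deviation."""
    M = np.asarray(M, dtype=float)
    sd = M.std(axis=0)
    if np.any(sd == 0):
        raise ParameterError("cannot standardize a constant column")
    return (M - M.mean(axis=0)) / sd


def lasso_coordinate_descent(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float,
    beta0: np.ndarray | None = None,
    tol: float = 1e-12,
    max_iter: int = 100_000,
) -> np.ndarray:
    """Minimize (1/N)||y - X beta||^2 + alpha ||beta||_1 by cyclic coordinate
    descent (soft-thresholding updates)."""
    N, d = X.shape
    beta = np.zeros(d) if beta0 is None else beta0.copy()
    col_sq = (X**2).sum(axis=0)
    r = y - X @ beta
    for _ in range(max_iter):
        delta = 0.0
        for j in range(d):
            if col_sq[j] == 0:
                continue
            rho = X[:, j] @ r + col_sq[j] * beta[j]
            new = np.sign(rho) * max(abs(rho) - alpha * N / 2.0, 0.0) / col_sq[j]
            if new != beta[j]:
                r += X[:, j] * (beta[j] - new)
                delta = max(delta, abs(new - beta[j]))
                beta[j] = new
        if delta < tol:
            break
    return beta


def lasso_subgradient_gap(X: np.ndarray, y: np.ndarray, beta: np.ndarray, alpha: float) -> float:
    """Max violation of the stationarity conditions of the 1/N-scaled objective."""
    N = X.shape[0]
    grad = -(2.0 / N) * X.T @ (y - X @ beta)
    gap = 0.0
    for j, b in enumerate(beta):
        if b != 0:
            gap = max(gap, abs(grad[j] + alpha * np.sign(b)))
        else:
            gap = max(gap, max(abs(grad[j]) - alpha, 0.0))
    return float(gap)


def lasso_path(
    X: np.ndarray,
    y: np.ndarray,
    predictor_names=None,
    n_nonzero_stop: int = 9,
    n_alphas: int = 120,
    alpha_min_ratio: float = 1e-3,
) -> LassoPath:
    """Regularization path on a log-spaced decreasing alpha grid, starting at
    the smallest alpha with an all-zero solution and stopping at the first
    alpha where ``n_nonzero_stop`` coefficients are non-zero (or at the grid
    end if that never happens)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise InputShapeError("X must be (N, d) with len(y) == N")
    _check_standardized(X, "predictor columns")
    _check_standardized(y[:, None], "the response")
    N, d = X.shape
    names = tuple(predictor_names) if predictor_names is not None else tuple(
        f"x{j}" for j in range(d)
    )
    if len(names) != d:
        raise InputShapeError("predictor_names length must match X columns")
    alpha_max = 2.0 * np.abs(X.T @ y).max() / N
    grid = np.geomspace(alpha_max, alpha_max * alpha_min_ratio, n_alphas)
    betas = []
    beta = np.zeros(d)
    kept_alphas = []
    for alpha in grid:
        beta = lasso_coordinate_descent(X, y, alpha, beta0=beta)
        betas.append(beta.copy())
        kept_alphas.append(alpha)
        if int((beta != 0).sum()) >= n_nonzero_stop:
            break
    return LassoPath(
        alphas=np.array(kept_alphas),
        coefficients=np.array(betas).T,
        predictor_names=names,
        n_nonzero_stop=n_nonzero_stop,
    )
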