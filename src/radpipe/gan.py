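"""Gene association network reconstruction from time-course expression.

The pipeline mirrors the regularized dynamical partial-correlation
approach for graphical Gaussian models: replicate trajectories are
averaged per gene, time points receive trapezoid quadrature weights, the
weighted correlation matrix is shrunk toward the identity with the
analytic shrinkage intensity

    lambda* = sum_{i!=j} Var_hat(r_ij) / sum_{i!=j} r_ij^2 ,

partial correlations come from the inverse of the shrunken correlation
matrix, and a two-component mixture (null correlation density with
effective degrees of freedom kappa vs a uniform alternative) converts
each partial correlation into a posterior edge probability
(1 - local fdr).  Edges with posterior >= 0.95 form the network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import networkx as nx
from scipy import optimize, special

__all__ = [
    "trapezoid_weights",
    "average_replicates",
    "dynamical_correlation",
    "shrink_correlation",
    "partial_correlations",
    "EdgePosteriorModel",
    "fit_edge_posteriors",
    "build_network",
    "first_neighborhood",
    "reconstruct_network",
]


def trapezoid_weights(times) -> np.ndarray:
    """Trapezoid-rule time weights, normalized to sum to 1.

    Interior weight (t_{k+1} - t_{k-1})/2; end weights half the adjacent
    spacing.  Times must be strictly increasing.
    """
    t = np.asarray(times, dtype=float)
    if t.size < 2:
        raise ValueError("need at least two time points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing (no duplicates)")
    w = np.empty_like(t)
    w[0] = (t[1] - t[0]) / 2.0
    w[-1] = (t[-1] - t[-2]) / 2.0
    if t.size > 2:
        w[1:-1] = (t[2:] - t[:-2]) / 2.0
    return w / w.sum()


def average_replicates(expr: pd.DataFrame, design: pd.DataFrame, condition: str = "treated") -> pd.DataFrame:
    """Average replicates per time point for one condition.

    Returns a genes x times DataFrame (columns are the sorted distinct
    times of that condition).
    """
    design = design.loc[expr.columns]
    sel = design["condition"] == condition
    if not sel.any():
        raise ValueError(f"no samples with condition {condition!r}")
    times = np.unique(design.loc[sel, "time_h"].to_numpy(float))
    cols = {}
    for t in times:
        samples = design.index[sel & (design["time_h"] == t)]
        cols[t] = expr[samples].mean(axis=1)
    return pd.DataFrame(cols, index=expr.index)


def _weighted_standardize(X: np.ndarray, w: np.ndarray):
    """Weighted column standardization (population weighted variance)."""
    m = w @ X
    Xc = X - m
    v = w @ (Xc * Xc)
    zero = v <= 0
    sd = np.sqrt(np.where(zero, 1.0, v))
    return Xc / sd, zero


def dynamical_correlation(trajectories: pd.DataFrame, weights=None) -> pd.DataFrame:
    """Weighted correlation of mean trajectories (genes x times input).

    Each trajectory is centered by its weighted mean; r_ij is the
    weighted inner product over times divided by the weighted norms.
    Genes with zero weighted variance get zero correlations (warning).
    """
    X = trajectories.to_numpy(float).T  # times x genes
    times = trajectories.columns.to_numpy(float)
    w = trapezoid_weights(times) if weights is None else np.asarray(weights, float)
    Xs, zero = _weighted_standardize(X, w)
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} gene(s) with zero weighted variance; correlations set to 0",
            stacklevel=2,
        )
        Xs[:, zero] = 0.0
    R = (Xs * w[:, None]).T @ Xs
    np.fill_diagonal(R, np.where(zero, 0.0, 1.0))
    R = np.clip((R + R.T) / 2.0, -1.0, 1.0)
    return pd.DataFrame(R, index=trajectories.index, columns=trajectories.index)


def shrink_correlation(data, weights=None):
    """Shrunken correlation matrix R* = (1-lambda*) R + lambda* I.

    ``data`` is observations x variables (e.g. times x genes, with
    trapezoid weights, or i.i.d. samples x genes with uniform weights).
    The variance of each correlation is estimated from the weighted
    empirical variance of the standardized cross-products:

        Var_hat(r_ij) = sw/(1-sw) * sum_k w_k (c_kij - r_ij)^2,
        c_kij = xs_ki * xs_kj,  sw = sum w_k^2,

    which for uniform weights reduces to the usual squared standard
    error of a mean.  Returns ``(R_star, lambda_star)``; lambda* is
    clipped to [0, 1] and set to 1 when all off-diagonal r vanish.
    """
    if isinstance(data, pd.DataFrame):
        X = data.to_numpy(float)
        index = data.columns
    else:
        X = np.asarray(data, float)
        index = None
    n, p = X.shape
    if n < 3:
        raise ValueError("need at least 3 effective observations")
    w = np.full(n, 1.0 / n) if weights is None else np.asarray(weights, float) / np.sum(weights)
    Xs, zero = _weighted_standardize(X, w)
    if zero.any():
        Xs[:, zero] = 0.0
    R = (Xs * w[:, None]).T @ Xs
    np.fill_diagonal(R, 1.0)
    R = np.clip((R + R.T) / 2.0, -1.0, 1.0)

    sw = float(w @ w)
    factor = sw / (1.0 - sw)
    # var_hat_ij = factor * sum_k w_k (xs_ki xs_kj - r_ij)^2, vectorized:
    # sum_k w_k c^2 - 2 r sum_k w_k c + r^2 = E_w[c^2] - r^2
    Ewc2 = (Xs * Xs * w[:, None]).T @ (Xs * Xs)
    var_hat = factor * (Ewc2 - R * R)
    off = ~np.eye(p, dtype=bool)
    denom = float(np.sum(R[off] ** 2))
    lam = 1.0 if denom == 0.0 else float(np.clip(np.sum(var_hat[off]) / denom, 0.0, 1.0))
    R_star = (1.0 - lam) * R + lam * np.eye(p)
    if index is not None:
        R_star = pd.DataFrame(R_star, index=index, columns=index)
    return R_star, lam


def partial_correlations(R_star):
    """Partial correlations from a (shrunken) correlation matrix.

    p_ij = -Omega_ij / sqrt(Omega_ii * Omega_jj) with Omega the inverse
    of R*.  Raises on singular input, advising shrinkage.
    """
    if isinstance(R_star, pd.DataFrame):
        index = R_star.index
        R = R_star.to_numpy(float)
    else:
        index = None
        R = np.asarray(R_star, float)
    try:
        omega = np.linalg.inv(R)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "correlation matrix is singular; apply shrinkage (lambda* > 0) first"
        ) from err
    d = np.sqrt(np.abs(np.diag(omega)))
    P = -omega / np.outer(d, d)
    np.fill_diagonal(P, 1.0)
    P = (P + P.T) / 2.0
    if index is not None:
        P = pd.DataFrame(P, index=index, columns=index)
    return P


def partial_to_correlation(P):
    """Inverse of :func:`partial_correlations`.

    Negate the off-diagonal partial correlations, invert, and rescale to
    unit diagonal; ``partial_to_correlation(partial_correlations(R))``
    recovers R exactly for positive-definite correlation matrices.
    """
    if isinstance(P, pd.DataFrame):
        index = P.index
        M = P.to_numpy(float)
    else:
        index = None
        M = np.asarray(P, float)
    K = -M.copy()
    np.fill_diagonal(K, 1.0)
    S = np.linalg.inv(K)
    d = np.sqrt(np.abs(np.diag(S)))
    R = S / np.outer(d, d)
    R = (R + R.T) / 2.0
    if index is not None:
        R = pd.DataFrame(R, index=index, columns=index)
    return R


@dataclass
class EdgePosteriorModel:
    """Two-component mixture over partial correlations.

    eta0: null proportion; kappa: effective degrees of freedom of the
    null correlation density
    f0(p; kappa) = (1-p^2)^((kappa-3)/2) * Gamma(kappa/2) /
                   (sqrt(pi) * Gamma((kappa-1)/2));
    the alternative is Uniform(-1, 1).
    """

    eta0: float
    kappa: float
    loglik: float = np.nan

    def null_density(self, p) -> np.ndarray:
        p = np.asarray(p, float)
        k = self.kappa
        lognorm = special.gammaln(k / 2.0) - 0.5 * np.log(np.pi) - special.gammaln((k - 1.0) / 2.0)
        inside = np.clip(1.0 - p * p, 1e-300, None)
        return np.exp(lognorm + (k - 3.0) / 2.0 * np.log(inside))

    def posterior(self, p) -> np.ndarray:
        """Posterior probability of a true edge: 1 - local fdr."""
        p = np.asarray(p, float)
        f0 = self.null_density(p)
        fa = 0.5
        f = self.eta0 * f0 + (1.0 - self.eta0) * fa
        return np.clip((1.0 - self.eta0) * fa / np.maximum(f, 1e-300), 0.0, 1.0)


def _offdiag_values(P) -> np.ndarray:
    M = P.to_numpy(float) if isinstance(P, pd.DataFrame) else np.asarray(P, float)
    iu = np.triu_indices_from(M, k=1)
    return M[iu]


def fit_edge_posteriors(P, kappa_max: float = 1e5) -> EdgePosteriorModel:
    """Fit (eta0, kappa) by maximum likelihood on all off-diagonal p_ij.

    kappa is constrained > 3 (finite variance of the null), eta0 to
    [1e-4, 1].  Raises RuntimeError on optimizer failure.
    """
    p = np.clip(_offdiag_values(P), -1 + 1e-12, 1 - 1e-12)
    if p.size < 100:
        warnings.warn(
            f"only {p.size} off-diagonal entries; mixture fit may be unstable", stacklevel=2
        )

    def negll(theta):
        eta0, kappa = theta
        m = EdgePosteriorModel(eta0, kappa)
        f = eta0 * m.null_density(p) + (1.0 - eta0) * 0.5
        return -np.sum(np.log(np.maximum(f, 1e-300)))

    kappa_init = float(np.clip(1.0 / max(np.mean(p * p), 1e-12), 3.5, kappa_max))
    best = None
    for x0 in ([0.95, kappa_init], [0.8, kappa_init], [0.99, max(10.0, kappa_init / 2)]):
        res = optimize.minimize(
            negll,
            x0=x0,
            method="L-BFGS-B",
            bounds=[(1e-4, 1.0), (3.0 + 1e-6, kappa_max)],
        )
        if res.success and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise RuntimeError("edge posterior mixture fit did not converge")
    eta0, kappa = best.x
    return EdgePosteriorModel(float(eta0), float(kappa), loglik=-float(best.fun))


def build_network(P, model: EdgePosteriorModel, threshold: float = 0.95) -> nx.Graph:
    """Undirected network of edges with posterior >= threshold.

    Nodes are all genes tested; isolated nodes are retained and flagged
    via the node attribute ``isolated``.
    """
    if isinstance(P, pd.DataFrame):
        genes = list(P.index)
        M = P.to_numpy(float)
    else:
        M = np.asarray(P, float)
        genes = [f"V{i + 1}" for i in range(M.shape[0])]
    G = nx.Graph()
    G.add_nodes_from(genes)
    iu, ju = np.triu_indices(len(genes), k=1)
    pc = M[iu, ju]
    prob = model.posterior(pc)
    keep = prob >= threshold
    for i, j, r, pr in zip(iu[keep], ju[keep], pc[keep], prob[keep]):
        G.add_edge(genes[i], genes[j], pcor=float(r), prob=float(pr))
    for node in G.nodes:
        G.nodes[node]["isolated"] = G.degree(node) == 0
    return G


def first_neighborhood(network: nx.Graph, gene: str) -> nx.Graph:
    """Induced subgraph on the closed neighborhood of ``gene``."""
    if gene not in network:
        raise ValueError(f"gene {gene!r} not in network")
    nodes = {gene} | set(network.neighbors(gene))
    return network.subgraph(nodes).copy()


def reconstruct_network(
    expr: pd.DataFrame,
    design: pd.DataFrame | None = None,
    condition: str = "treated",
    threshold: float = 0.95,
):
    """End-to-end reconstruction convenience wrapper.

    With a design, replicate trajectories of ``condition`` are averaged
    and time points weighted by the trapezoid rule; without one, columns
    are treated as i.i.d. samples with uniform weights.  Returns
    ``(network, P, lambda_star, model)``.
    """
    if design is not None:
        traj = average_replicates(expr, design, condition=condition)
        weights = trapezoid_weights(traj.columns.to_numpy(float))
        R_star, lam = shrink_correlation(traj.T, weights=weights)
    else:
        R_star, lam = shrink_correlation(expr.T)
    P = partial_correlations(R_star)
    model = fit_edge_posteriors(P)
    G = build_network(P, model, threshold=threshold)
    return G, P, lam, model
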