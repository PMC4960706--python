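"""Linear-quadratic clonogenic survival fitting and proliferation analysis.

Colony counts per dish are modelled as Poisson with mean
``cells_seeded * PE_e * S(D)`` where ``S(D) = exp(-(alpha*D + beta*D^2))``
is the linear-quadratic surviving fraction and PE_e the per-experiment
plating efficiency.  (alpha, beta) are estimated by maximum likelihood
with the plating efficiencies profiled out in closed form; both
parameters are constrained non-negative.  Curves are compared with a
deviance-based extra-sum-of-squares F-test (a likelihood-ratio chi-square
is available), and doubling times come from semi-log regression of cell
counts on time in the exponential growth window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln

__all__ = [
    "SurvivalFit",
    "CurveComparison",
    "fit_lq",
    "survival_fraction",
    "compare_curves",
    "doubling_time",
]


@dataclass
class SurvivalFit:
    """Maximum-likelihood linear-quadratic fit."""

    alpha: float  # per Gy
    beta: float  # per Gy^2
    pe: dict  # plating efficiency per experiment id
    loglik: float
    n_params: int
    at_bound: bool = False  # alpha or beta pinned at the 0 bound
    loglik_init: float = field(default=np.nan, repr=False)


@dataclass
class CurveComparison:
    statistic: float
    df_num: int
    df_den: float
    p_value: float
    method: str = "deviance-F"


def survival_fraction(dose, alpha: float, beta: float):
    d = np.asarray(dose, float)
    return np.exp(-(alpha * d + beta * d * d))


def _validate_counts(counts: pd.DataFrame) -> pd.DataFrame:
    required = {"experiment", "dose", "cells", "colonies"}
    if not required.issubset(counts.columns):
        raise ValueError(f"counts table must have columns {sorted(required)}")
    if (counts["colonies"] < 0).any() or (counts["cells"] <= 0).any() or (counts["dose"] < 0).any():
        raise ValueError("colonies >= 0, cells > 0, dose >= 0 required")
    doses = np.unique(counts["dose"])
    if len(doses) < 3 or 0.0 not in doses:
        raise ValueError("need >= 3 distinct doses including dose 0")
    for exp, grp in counts.groupby("experiment"):
        if not (grp["dose"] == 0).any():
            raise ValueError(f"experiment {exp!r} lacks a dose-0 dish (PE unidentifiable)")
    if counts["colonies"].sum() == 0:
        raise ValueError("all colony counts are zero; nothing to fit")
    return counts


def _profile_pe(counts: pd.DataFrame, alpha: float, beta: float) -> dict:
    """ML plating efficiencies given (alpha, beta): PE_e = sum k / sum cells*S."""
    s = survival_fraction(counts["dose"].to_numpy(float), alpha, beta)
    pe = {}
    for exp, grp in counts.groupby("experiment"):
        idx = grp.index
        denom = float((grp["cells"].to_numpy(float) * s[counts.index.get_indexer(idx)]).sum())
        pe[exp] = float(grp["colonies"].sum()) / max(denom, 1e-300)
    return pe


def _poisson_loglik(counts: pd.DataFrame, alpha: float, beta: float, pe: dict) -> float:
    d = counts["dose"].to_numpy(float)
    k = counts["colonies"].to_numpy(float)
    cells = counts["cells"].to_numpy(float)
    pevec = counts["experiment"].map(pe).to_numpy(float)
    mu = np.maximum(cells * pevec * survival_fraction(d, alpha, beta), 1e-300)
    return float(np.sum(k * np.log(mu) - mu - gammaln(k + 1.0)))


def _init_lq(counts: pd.DataFrame) -> tuple[float, float]:
    """Log-linear least squares on observed surviving fractions."""
    pe0 = {}
    for exp, grp in counts.groupby("experiment"):
        z = grp[grp["dose"] == 0]
        pe0[exp] = max(float(z["colonies"].sum()) / float(z["cells"].sum()), 1e-6)
    d = counts["dose"].to_numpy(float)
    cells = counts["cells"].to_numpy(float)
    k = counts["colonies"].to_numpy(float)
    pevec = counts["experiment"].map(pe0).to_numpy(float)
    sf = np.maximum(k, 0.5) / (cells * pevec)  # 0.5-count continuity floor
    mask = d > 0
    if mask.sum() < 2:
        return 0.1, 0.01
    X = np.column_stack([d[mask], d[mask] ** 2])
    coef, *_ = np.linalg.lstsq(X, -np.log(sf[mask]), rcond=None)
    return float(max(coef[0], 0.0)), float(max(coef[1], 0.0))


def fit_lq(counts: pd.DataFrame) -> SurvivalFit:
    """Poisson maximum-likelihood linear-quadratic fit.

    Maximizes sum [k log mu - mu] over (alpha, beta, {PE_e}) with
    alpha, beta >= 0; plating efficiencies are profiled out exactly.
    Initialized from the log-linear least-squares solution.
    """
    counts = _validate_counts(counts.reset_index(drop=True))

    def negll(theta):
        a, b = theta
        pe = _profile_pe(counts, a, b)
        return -_poisson_loglik(counts, a, b, pe)

    x0 = _init_lq(counts)
    ll_init = -negll(x0)
    res = optimize.minimize(
        negll, x0=x0, method="L-BFGS-B", bounds=[(0.0, None), (0.0, None)]
    )
    if not res.success:  # pragma: no cover - Nelder-Mead fallback
        res = optimize.minimize(negll, x0=x0, method="Nelder-Mead")
    alpha, beta = (float(max(v, 0.0)) for v in res.x)
    pe = _profile_pe(counts, alpha, beta)
    ll = _poisson_loglik(counts, alpha, beta, pe)
    n_exp = counts["experiment"].nunique()
    return SurvivalFit(
        alpha=alpha,
        beta=beta,
        pe=pe,
        loglik=ll,
        n_params=2 + n_exp,
        at_bound=bool(alpha < 1e-9 or beta < 1e-9),
        loglik_init=ll_init,
    )


def _saturated_loglik(counts: pd.DataFrame) -> float:
    k = counts["colonies"].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(k > 0, k * np.log(np.maximum(k, 1.0)) - k, 0.0)
    return float(np.sum(term - gammaln(k + 1.0)))


def _deviance(counts: pd.DataFrame, loglik: float) -> float:
    return 2.0 * (_saturated_loglik(counts) - loglik)


def _fit_joint(countsA: pd.DataFrame, countsB: pd.DataFrame):
    """Shared (alpha, beta), separate per-line/per-experiment PEs."""
    a = countsA.reset_index(drop=True).copy()
    b = countsB.reset_index(drop=True).copy()
    a["experiment"] = "A::" + a["experiment"].astype(str)
    b["experiment"] = "B::" + b["experiment"].astype(str)
    merged = pd.concat([a, b], ignore_index=True)
    fit = fit_lq(merged)
    return fit, merged


def compare_curves(countsA: pd.DataFrame, countsB: pd.DataFrame, method: str = "deviance") -> CurveComparison:
    """Test whether two survival curves share (alpha, beta).

    ``method='deviance'`` (default): extra-sum-of-squares F on Poisson
    deviance, F = [(Dev_joint - Dev_sep)/2] / [Dev_sep/df_sep] with
    df_sep = n_dishes - n_params_sep, p from F(2, df_sep).
    ``method='lr'``: likelihood-ratio chi-square with 2 df.
    """
    fitA = fit_lq(countsA)
    fitB = fit_lq(countsB)
    fitJ, merged = _fit_joint(countsA, countsB)
    ll_sep = fitA.loglik + fitB.loglik
    dev_sep = _deviance(merged, ll_sep)
    dev_joint = _deviance(merged, fitJ.loglik)
    n = len(merged)
    n_params_sep = fitA.n_params + fitB.n_params
    df_sep = n - n_params_sep
    if df_sep <= 0:
        raise ValueError("no residual degrees of freedom for the separate model")
    extra = max(dev_joint - dev_sep, 0.0)
    if method == "deviance":
        scale = dev_sep / df_sep
        F = extra / 2.0 / max(scale, 1e-300) if extra > 0 else 0.0
        p = float(stats.f.sf(F, 2, df_sep)) if F > 0 else 1.0
        return CurveComparison(float(F), 2, float(df_sep), p, method="deviance-F")
    elif method == "lr":
        p = float(stats.chi2.sf(extra, 2)) if extra > 0 else 1.0
        return CurveComparison(float(extra), 2, np.inf, p, method="likelihood-ratio")
    raise ValueError("method must be 'deviance' or 'lr'")


def doubling_time(growth: pd.DataFrame, window: tuple[float, float] | None = None) -> float:
    """Doubling time (h) by semi-log regression in the growth window.

    OLS of ln(count) on time within ``window`` (inclusive); T_d = ln 2 /
    slope.  Raises on a non-positive slope (no exponential growth).
    """
    required = {"time", "count"}
    if not required.issubset(growth.columns):
        raise ValueError(f"growth table must have columns {sorted(required)}")
    g = growth
    if window is not None:
        lo, hi = window
        g = growth[(growth["time"] >= lo) & (growth["time"] <= hi)]
    if len(g) < 2:
        raise ValueError("need at least two time points in the window")
    if (g["count"] <= 0).any():
        raise ValueError("cell counts must be positive within the fitted window")
    t = g["time"].to_numpy(float)
    y = np.log(g["count"].to_numpy(float))
    slope, _ = np.polyfit(t, y, 1)
    if slope <= 0:
        raise ValueError("no exponential growth: non-positive slope")
    return float(np.log(2.0) / slope)
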