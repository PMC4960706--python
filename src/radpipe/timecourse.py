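"""Spline time-course differential expression with empirical-Bayes moderation.

The treated-vs-control time-course model regresses each gene's log2
expression on ``[1, B_1..B_K, x, x*B_1..x*B_K]`` where B is a K=3 df
natural cubic spline in time and x indicates the treated condition.  The
tested null is that all treatment coefficients (offset gamma_0 and shape
gamma_1..gamma_K) vanish; a shape-only test is available.  Gene-wise
residual variances are shrunk toward an inverse-chi-square prior whose
hyperparameters (d0, s0^2) are estimated by moment matching on the log
variances, giving a moderated F statistic with q and d0 + d_g degrees of
freedom.  p-values are Benjamini-Hochberg adjusted across genes.

Also here: the static two-group moderated t contrast with the
|log2FC| > 0.5 and FDR < 0.05 rule, and the early/late responder
classification on per-time fold changes (FC > 2.0 or < 0.5 within the
first day -> early; within days 2-4 -> late).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import benjamini_hochberg, estimate_variance_prior, moderate_variances
from .splines import SplineBasis, natural_spline_basis

__all__ = [
    "SplineFits",
    "validate_design",
    "fit_spline_model",
    "moderated_f_test",
    "timecourse_de",
    "static_de",
    "classify_early_late",
]


@dataclass
class SplineFits:
    """Per-gene OLS results for the full and null spline models."""

    genes: list
    coefficients: pd.DataFrame  # genes x [b0, b1..bK, g0, g1..gK]
    rss_full: np.ndarray
    rss_null: np.ndarray
    df_resid: int
    q: int  # number of tested coefficients
    basis: SplineBasis = field(repr=False, default=None)


def validate_design(expr: pd.DataFrame, design: pd.DataFrame) -> None:
    if expr.isna().any().any():
        raise ValueError("expression matrix contains missing values")
    missing = set(expr.columns) - set(design.index)
    if missing:
        raise ValueError(f"samples absent from design: {sorted(missing)[:5]} ...")
    conds = set(design["condition"])
    if conds != {"control", "treated"}:
        raise ValueError(f"conditions must be control/treated, got {sorted(conds)}")
    t_ctrl = set(design.loc[design["condition"] == "control", "time_h"])
    t_trt = set(design.loc[design["condition"] == "treated", "time_h"])
    if t_ctrl != t_trt:
        raise ValueError("both conditions must share the identical set of time points")


def fit_spline_model(
    expr: pd.DataFrame,
    design: pd.DataFrame,
    basis: SplineBasis | None = None,
    test: str = "all",
) -> SplineFits:
    """Gene-wise OLS of log2 expression on the spline treatment design.

    ``test='all'`` tests the joint null gamma_0 = ... = gamma_K = 0
    (q = K+1); ``test='shape'`` leaves the treatment offset in the null
    model and tests only the shape coefficients (q = K).
    """
    validate_design(expr, design)
    design = design.loc[expr.columns]
    t = design["time_h"].to_numpy(float)
    if basis is None:
        basis = natural_spline_basis(np.unique(t), df=3)
    K = basis.df
    B = basis.evaluate(t)
    x = (design["condition"].to_numpy() == "treated").astype(float)
    ones = np.ones_like(x)
    X_full = np.column_stack([ones, B, x, x[:, None] * B])
    if test == "all":
        X_null = np.column_stack([ones, B])
        q = K + 1
    elif test == "shape":
        X_null = np.column_stack([ones, B, x])
        q = K
    else:
        raise ValueError("test must be 'all' or 'shape'")

    rank = np.linalg.matrix_rank(X_full)
    if rank < X_full.shape[1]:
        # identify near-collinear columns via the R factor of a QR decomposition
        r = np.abs(np.diag(np.linalg.qr(X_full, mode="r")))
        bad = list(np.flatnonzero(r < 1e-10 * r.max()))
        raise ValueError(f"rank-deficient design matrix; collinear columns {bad}")

    Y = expr.to_numpy(float).T  # samples x genes
    coef_full, _, _, _ = np.linalg.lstsq(X_full, Y, rcond=None)
    resid_full = Y - X_full @ coef_full
    rss_full = np.einsum("ij,ij->j", resid_full, resid_full)
    coef_null, _, _, _ = np.linalg.lstsq(X_null, Y, rcond=None)
    resid_null = Y - X_null @ coef_null
    rss_null = np.einsum("ij,ij->j", resid_null, resid_null)

    names = (
        ["b0"] + [f"b{k + 1}" for k in range(K)] + ["g0"] + [f"g{k + 1}" for k in range(K)]
    )
    coefficients = pd.DataFrame(coef_full.T, index=expr.index, columns=names)
    return SplineFits(
        genes=list(expr.index),
        coefficients=coefficients,
        rss_full=rss_full,
        rss_null=rss_null,
        df_resid=Y.shape[0] - X_full.shape[1],
        q=q,
        basis=basis,
    )


def moderated_f_test(fits: SplineFits, d0: float | None = None, s0_sq: float | None = None) -> pd.DataFrame:
    """Moderated F-test of the treatment coefficients for every gene.

    Hyperparameters are estimated from the residual variances unless both
    ``d0`` and ``s0_sq`` are forced (``d0=0`` recovers the ordinary
    per-gene F-test; ``d0=inf`` pools all variances to ``s0_sq``).
    Returns a per-gene table with F, p_value, fdr, s2, and the fitted
    coefficients; prior parameters are stored in ``DataFrame.attrs``.
    """
    n_genes = len(fits.genes)
    if n_genes < 50:
        warnings.warn(
            f"only {n_genes} genes; hyperparameter estimation may be unstable",
            stacklevel=2,
        )
    d = float(fits.df_resid)
    if d <= 0:
        raise ValueError("no residual degrees of freedom")
    s2 = fits.rss_full / d
    if d0 is None:
        if n_genes < 2:
            d0, s0_sq = 0.0, None  # too few genes to estimate a prior
        else:
            d0, s0_est = estimate_variance_prior(s2, d)
            if s0_sq is None:
                s0_sq = s0_est
    elif s0_sq is None and d0 not in (0,):
        _, s0_sq = estimate_variance_prior(s2, d)
    s2_post = moderate_variances(s2, d, d0, s0_sq if s0_sq is not None else 1.0)
    q = fits.q
    F = (fits.rss_null - fits.rss_full) / q / np.maximum(s2_post, 1e-300)
    F = np.maximum(F, 0.0)
    if np.isinf(d0):
        p = stats.chi2.sf(q * F, q)
    else:
        p = stats.f.sf(F, q, d0 + d)
    table = fits.coefficients.copy()
    table.insert(0, "F", F)
    table.insert(1, "p_value", p)
    table.insert(2, "fdr", benjamini_hochberg(p))
    table["s2"] = s2
    table["df_resid"] = d
    table.attrs["d0"] = float(d0)
    table.attrs["s0_sq"] = float(s0_sq) if s0_sq is not None else None
    table.attrs["q"] = q
    return table


def timecourse_de(
    expr: pd.DataFrame,
    design: pd.DataFrame,
    fdr_threshold: float = 0.05,
    df: int = 3,
    test: str = "all",
    d0: float | None = None,
) -> pd.DataFrame:
    """Temporal differential expression: basis + fit + moderated F + BH.

    Returns the full per-gene statistics table with a boolean ``de``
    column (fdr < ``fdr_threshold``).
    """
    times = np.unique(design.loc[expr.columns, "time_h"].to_numpy(float))
    basis = natural_spline_basis(times, df=df)
    fits = fit_spline_model(expr, design, basis=basis, test=test)
    table = moderated_f_test(fits, d0=d0)
    table["de"] = table["fdr"] < fdr_threshold
    return table


def static_de(
    exprA: pd.DataFrame,
    exprB: pd.DataFrame,
    lfc_threshold: float = 0.5,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Two-group moderated t contrast (A minus B) with the joint rule
    |log2FC| > lfc_threshold AND fdr < fdr_threshold (both strict).
    """
    if not exprA.index.equals(exprB.index):
        raise ValueError("the two groups must contain the same genes in the same order")
    nA, nB = exprA.shape[1], exprB.shape[1]
    if nA < 2 or nB < 2:
        raise ValueError("need at least two samples per group to estimate variance")
    A = exprA.to_numpy(float)
    Bv = exprB.to_numpy(float)
    log2fc = A.mean(axis=1) - Bv.mean(axis=1)
    d = nA + nB - 2
    rss = ((A - A.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (Bv - Bv.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s2 = rss / d
    d0, s0_sq = estimate_variance_prior(s2, d)
    s2_post = moderate_variances(s2, d, d0, s0_sq)
    se = np.sqrt(s2_post * (1.0 / nA + 1.0 / nB))
    tstat = log2fc / np.maximum(se, 1e-300)
    if np.isinf(d0):
        p = 2.0 * stats.norm.sf(np.abs(tstat))
    else:
        p = 2.0 * stats.t.sf(np.abs(tstat), d0 + d)
    fdr = benjamini_hochberg(p)
    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "fc": 2.0 ** log2fc,
            "t": tstat,
            "p_value": p,
            "fdr": fdr,
            "de": (np.abs(log2fc) > lfc_threshold) & (fdr < fdr_threshold),
        },
        index=exprA.index,
    )
    table.attrs["d0"] = d0
    table.attrs["s0_sq"] = s0_sq
    return table


def classify_early_late(
    expr: pd.DataFrame,
    design: pd.DataFrame,
    de_genes,
    fc_high: float = 2.0,
    fc_low: float = 0.5,
    day1_max_h: float = 24.0,
    late_max_h: float = 96.0,
) -> pd.DataFrame:
    """Early/late responder classification for temporally DE genes.

    FC(t) = 2^(mean treated log2 at t - mean control log2 at t).  A gene
    is early iff FC crosses the (fc_high, fc_low) window strictly at any
    t <= 24 h, late iff it does so at any t in (24, 96] h.  Returns a
    table with early/late flags and one ``fc_<t>h`` column per time.
    """
    de_genes = list(de_genes)
    missing = set(de_genes) - set(expr.index)
    if missing:
        raise ValueError(f"DE genes absent from expression matrix: {sorted(missing)[:5]}")
    validate_design(expr, design)
    design = design.loc[expr.columns]
    times = np.unique(design["time_h"].to_numpy(float))
    sub = expr.loc[de_genes]
    fc = {}
    for t in times:
        trt = design.index[(design["condition"] == "treated") & (design["time_h"] == t)]
        ctl = design.index[(design["condition"] == "control") & (design["time_h"] == t)]
        diff = sub[trt].mean(axis=1) - sub[ctl].mean(axis=1)
        fc[t] = 2.0 ** diff
    fc_mat = pd.DataFrame(fc, index=de_genes)
    crossing = (fc_mat > fc_high) | (fc_mat < fc_low)
    early_cols = [t for t in times if t <= day1_max_h]
    late_cols = [t for t in times if day1_max_h < t <= late_max_h]
    out = pd.DataFrame(index=pd.Index(de_genes, name="gene"))
    out["early"] = crossing[early_cols].any(axis=1) if early_cols else False
    out["late"] = crossing[late_cols].any(axis=1) if late_cols else False
    for t in times:
        out[f"fc_{t:g}h"] = fc_mat[t]
    return out
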