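"""Copy-number/expression integration and qPCR relative quantification.

Genes are assigned the call (-1 loss, 0 neutral, +1 gain) of the
half-open segment [start, end) containing their midpoint; concordant
genes are gains that are up-regulated (log2FC > +0.5) or losses that are
down-regulated (log2FC < -0.5) among the statically DE genes.  The
DDCt computation gives relative expression RQ = 2^(-DDCt) against
reference genes and a calibrator sample, validated against array fold
changes by Spearman's rho > 0.5 (strict).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

__all__ = [
    "map_genes_to_calls",
    "concordant_genes",
    "ddct_relative_expression",
    "validate_platforms",
]


def _check_segments(segments: pd.DataFrame) -> None:
    required = {"chrom", "start", "end", "call"}
    if not required.issubset(segments.columns):
        raise ValueError(f"segments must have columns {sorted(required)}")
    if (segments["start"] >= segments["end"]).any():
        raise ValueError("segments must satisfy start < end")
    for chrom, grp in segments.groupby("chrom"):
        g = grp.sort_values("start")
        if (g["start"].to_numpy()[1:] < g["end"].to_numpy()[:-1]).any():
            raise ValueError(f"overlapping segments on {chrom}")


def map_genes_to_calls(genes: pd.DataFrame, segments: pd.DataFrame) -> pd.DataFrame:
    """Per-gene copy-number call from segment containment of the midpoint.

    ``genes`` needs columns gene, chrom, midpoint.  Containment is
    half-open: midpoint == start is inside, midpoint == end is not.
    Genes covered by no segment get call 0 and ``in_segment=False``.
    """
    required = {"gene", "chrom", "midpoint"}
    if not required.issubset(genes.columns):
        raise ValueError(f"genes must have columns {sorted(required)}")
    _check_segments(segments)
    calls = np.zeros(len(genes), dtype=int)
    covered = np.zeros(len(genes), dtype=bool)
    genes = genes.reset_index(drop=True)
    for chrom, seg in segments.groupby("chrom"):
        seg = seg.sort_values("start")
        idx = genes.index[genes["chrom"] == chrom]
        if len(idx) == 0:
            continue
        mids = genes.loc[idx, "midpoint"].to_numpy()
        starts = seg["start"].to_numpy()
        ends = seg["end"].to_numpy()
        segcalls = seg["call"].to_numpy()
        pos = np.searchsorted(starts, mids, side="right") - 1
        ok = (pos >= 0) & (mids < ends[np.clip(pos, 0, len(ends) - 1)])
        calls[idx[ok]] = segcalls[pos[ok]]
        covered[idx[ok]] = True
    out = genes[["gene", "chrom", "midpoint"]].copy()
    out["call"] = calls
    out["in_segment"] = covered
    return out


def concordant_genes(de_table: pd.DataFrame, calls: pd.DataFrame) -> pd.DataFrame:
    """Concordance of static DE with copy-number calls.

    gain_up: call +1 and DE with log2FC > +0.5; loss_down: call -1 and
    DE with log2FC < -0.5; other DE genes with a non-neutral call are
    discordant; everything else neutral.  Inner join on gene id (a
    warning lists dropped genes).
    """
    de = de_table.copy()
    de.index.name = "gene"
    callmap = calls.set_index("gene")["call"]
    common = de.index.intersection(callmap.index)
    dropped = len(de.index) - len(common)
    if dropped:
        missing = sorted(set(de.index) - set(common))
        warnings.warn(
            f"{dropped} gene(s) without copy-number call dropped: {missing[:5]} ...",
            stacklevel=2,
        )
    de = de.loc[common]
    call = callmap.loc[common].astype(int)
    log2fc = de["log2fc"].to_numpy(float)
    flagged = de["de"].to_numpy(bool)
    status = np.full(len(common), "neutral", dtype=object)
    gain_up = (call.to_numpy() == 1) & flagged & (log2fc > 0.5)
    loss_down = (call.to_numpy() == -1) & flagged & (log2fc < -0.5)
    discordant = (call.to_numpy() != 0) & flagged & ~gain_up & ~loss_down
    status[discordant] = "discordant"
    status[gain_up] = "gain_up"
    status[loss_down] = "loss_down"
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "fc": 2.0 ** log2fc,
            "call": call.to_numpy(),
            "de": flagged,
            "status": status,
        },
        index=pd.Index(common, name="gene"),
    )


def ddct_relative_expression(
    ct: pd.DataFrame,
    target: str,
    references,
    calibrator: str,
) -> pd.Series:
    """Relative expression RQ = 2^(-DDCt) per sample.

    ``ct`` is a samples x assays table of Ct values.  DCt = Ct_target -
    mean(Ct_references); DDCt = DCt_sample - DCt_calibrator.  Samples
    with any missing Ct are skipped with a warning.
    """
    references = list(references)
    for col in [target, *references]:
        if col not in ct.columns:
            raise ValueError(f"assay {col!r} missing from Ct table")
    if calibrator not in ct.index:
        raise ValueError(f"calibrator sample {calibrator!r} missing")
    needed = ct[[target, *references]]
    ok = needed.notna().all(axis=1)
    if not ok.loc[calibrator]:
        raise ValueError("calibrator has missing Ct values")
    skipped = list(ct.index[~ok])
    if skipped:
        warnings.warn(f"samples with missing Ct skipped: {skipped}", stacklevel=2)
    dct = ct.loc[ok, target] - ct.loc[ok, references].mean(axis=1)
    ddct = dct - dct.loc[calibrator]
    rq = 2.0 ** (-ddct)
    rq.name = f"RQ_{target}"
    return rq


def validate_platforms(rq_foldchanges, array_foldchanges):
    """Spearman correlation of qPCR vs array fold changes.

    Returns ``(rho, passed)`` with passed = rho > 0.5 (strict).  A
    constant vector makes rho undefined -> (nan, False).
    """
    a = np.asarray(rq_foldchanges, float)
    b = np.asarray(array_foldchanges, float)
    if a.size != b.size or a.size < 3:
        raise ValueError("need at least 3 paired values")
    if np.all(a == a[0]) or np.all(b == b[0]):
        warnings.warn("constant fold-change vector; Spearman rho undefined", stacklevel=2)
        return float("nan"), False
    rho = float(spearmanr(a, b).statistic)
    return rho, bool(rho > 0.5)
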