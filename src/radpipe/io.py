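"""TSV readers/writers for the pipeline's tabular interchange formats.

Conventions: expression TSV has the gene id in the first column and one
column per sample; the design TSV has columns sample, condition, time_h,
replicate; genomic intervals are 0-based half-open [start, end).
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "read_expression",
    "write_expression",
    "read_design",
    "write_design",
    "read_table",
    "write_table",
    "read_edges",
    "write_edges",
]


def read_expression(path) -> pd.DataFrame:
    expr = pd.read_csv(path, sep="\t", index_col=0)
    if expr.isna().any().any():
        raise ValueError(f"missing values in expression matrix {path}")
    return expr


def write_expression(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene")


def read_design(path) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t")
    required = {"sample", "condition", "time_h", "replicate"}
    if not required.issubset(design.columns):
        raise ValueError(f"design must have columns {sorted(required)}")
    return design.set_index("sample")


def write_design(design: pd.DataFrame, path) -> None:
    design.to_csv(path, sep="\t", index_label="sample")


def read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_table(table: pd.DataFrame, path, index: bool = False, index_label=None) -> None:
    table.to_csv(path, sep="\t", index=index, index_label=index_label)


def write_edges(network, path) -> None:
    """Edge list TSV: gene_a, gene_b, pcor, prob."""
    rows = [
        (a, b, data.get("pcor", float("nan")), data.get("prob", float("nan")))
        for a, b, data in network.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "pcor", "prob"]).to_csv(
        path, sep="\t", index=False
    )


def read_edges(path):
    import networkx as nx

    table = pd.read_csv(path, sep="\t")
    G = nx.Graph()
    for _, row in table.iterrows():
        G.add_edge(row["gene_a"], row["gene_b"], pcor=row.get("pcor"), prob=row.get("prob"))
    return G
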