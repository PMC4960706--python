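"""Gene-set over-representation analysis.

One-sided Fisher's exact test per set (upper hypergeometric tail of the
query/set overlap within a fixed universe), after restricting set
membership to the universe and keeping only sets with 20..600 universe
genes (inclusive), with Benjamini-Hochberg adjustment across the tested
sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from scipy.stats import hypergeom
import pandas as pd

from ._stats import benjamini_hochberg

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "filter_sets",
    "fisher_enrichment",
]


@dataclass
class GeneSetCollection:
    """Named gene sets with descriptions (GMT-compatible)."""

    sets: dict = field(default_factory=dict)  # name -> list of genes
    descriptions: dict = field(default_factory=dict)  # name -> str

    @classmethod
    def from_dict(cls, mapping: dict) -> "GeneSetCollection":
        """From ``{name: (description, genes)}`` or ``{name: genes}``."""
        coll = cls()
        for name, value in mapping.items():
            if isinstance(value, tuple) and len(value) == 2:
                desc, genes = value
            else:
                desc, genes = "", value
            coll.add(name, list(genes), desc)
        return coll

    def add(self, name: str, genes: list, description: str = "") -> None:
        if name in self.sets:
            raise ValueError(f"duplicate set name {name!r}")
        if not genes:
            raise ValueError(f"set {name!r} has no members")
        self.sets[name] = list(dict.fromkeys(genes))
        self.descriptions[name] = description

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file (name TAB description TAB genes...); tolerant of
    a missing description field."""
    coll = GeneSetCollection()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) >= 3:
                name, desc, genes = parts[0], parts[1], parts[2:]
            elif len(parts) == 2:
                name, desc, genes = parts[0], "", parts[1:]
            else:
                continue
            genes = [g for g in genes if g]
            if genes:
                coll.add(name, genes, desc)
    return coll


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in collection:
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc] + list(collection.sets[name])) + "\n")


def filter_sets(
    collection: GeneSetCollection,
    universe,
    min_size: int = 20,
    max_size: int = 600,
) -> GeneSetCollection:
    """Universe-intersected size filter (inclusive bounds).

    Membership is intersected with the universe FIRST, then sets with
    min_size <= |set & universe| <= max_size are kept (with the
    intersected membership).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    out = GeneSetCollection()
    for name in collection:
        members = [g for g in collection.sets[name] if g in universe]
        if min_size <= len(members) <= max_size:
            out.add(name, members, collection.descriptions.get(name, ""))
    return out


def fisher_enrichment(query, universe, collection: GeneSetCollection) -> pd.DataFrame:
    """One-sided Fisher's exact test of over-representation per set.

    p = P(X >= n_hits) for X hypergeometric with population |universe|,
    n_set successes and |query| draws; BH adjustment across tested sets.
    Query genes outside the universe are dropped with a warning.
    Returns a table sorted by p-value with columns set, n_set, n_hits,
    p_value, fdr, hit_genes.
    """
    universe = set(universe)
    query = list(dict.fromkeys(query))
    outside = [g for g in query if g not in universe]
    if outside:
        warnings.warn(
            f"{len(outside)} query gene(s) outside the universe were dropped", stacklevel=2
        )
        query = [g for g in query if g in universe]
    qset = set(query)
    M, N = len(universe), len(qset)
    rows = []
    for name in collection:
        members = set(collection.sets[name]) & universe
        n_set = len(members)
        hits = sorted(members & qset)
        n_hits = len(hits)
        if N == 0 or n_hits == 0:
            p = 1.0
        else:
            p = float(hypergeom.sf(n_hits - 1, M, n_set, N))
        rows.append((name, n_set, n_hits, min(p, 1.0), ",".join(hits)))
    table = pd.DataFrame(rows, columns=["set", "n_set", "n_hits", "p_value", "hit_genes"])
    table["fdr"] = benjamini_hochberg(table["p_value"].to_numpy()) if len(table) else []
    table = table[["set", "n_set", "n_hits", "p_value", "fdr", "hit_genes"]]
    return table.sort_values(["p_value", "set"], kind="mergesort").reset_index(drop=True)
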