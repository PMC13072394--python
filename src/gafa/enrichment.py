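"""Hypergeometric over-representation analysis against GMT gene sets.

For a query gene list and an annotated set of size K drawn from a
universe of size M, the one-sided enrichment p-value is the upper
hypergeometric tail P(X >= overlap) with n = |query| draws; p-values
are Benjamini-Hochberg adjusted across the collection.  The universe
is the set of genes surviving QC in the expression matrix, not the
whole genome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = ["GeneSetCollection", "read_gmt", "write_gmt", "ora_hypergeometric"]


@dataclass
class GeneSetCollection:
    sets: dict[str, set[str]]
    universe: set[str]

    def restricted(self) -> dict[str, set[str]]:
        """Sets intersected with the universe, empty ones dropped."""
        out = {}
        for name, genes in self.sets.items():
            inter = genes & self.universe
            if inter:
                out[name] = inter
        return out


def read_gmt(path: str | Path, universe: set[str] | None = None) -> GeneSetCollection:
    """Parse a GMT file (name TAB description TAB gene...)."""
    sets: dict[str, set[str]] = {}
    all_genes: set[str] = set()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line has {len(fields)} fields, needs >= 3")
        name = fields[0]
        if name in sets:
            raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
        genes = {g for g in fields[2:] if g}
        sets[name] = genes
        all_genes |= genes
    return GeneSetCollection(sets=sets, universe=universe if universe is not None else all_genes)


def write_gmt(col: GeneSetCollection, path: str | Path) -> Path:
    path = Path(path)
    lines = [
        "\t".join([name, "na"] + sorted(genes)) for name, genes in col.sets.items()
    ]
    path.write_text("\n".join(lines) + "\n")
    return path


def ora_hypergeometric(query: set[str], col: GeneSetCollection) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of a query against each set.

    Query genes outside the universe are dropped with a warning; an
    empty query after intersection is an error.  Returns rows
    (set_name, overlap_count, set_size, query_size, universe_size,
    p_value, p_adj) sorted by p-value.
    """
    query = set(query)
    dropped = query - col.universe
    if dropped:
        warnings.warn(f"{len(dropped)} query genes outside the universe dropped")
    query &= col.universe
    if not query:
        raise ValueError("query is empty after intersection with the universe")
    M = len(col.universe)
    n = len(query)
    rows = []
    for name, genes in col.restricted().items():
        K = len(genes)
        overlap = len(genes & query)
        p = float(hypergeom.sf(overlap - 1, M, K, n))
        rows.append((name, overlap, K, n, M, min(p, 1.0)))
    res = pd.DataFrame(
        rows,
        columns=["set_name", "overlap_count", "set_size", "query_size", "universe_size", "p_value"],
    )
    res["p_adj"] = multipletests(res["p_value"], method="fdr_bh")[1]
    return res.sort_values("p_value", kind="stable").reset_index(drop=True)
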