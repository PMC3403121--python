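"""Hypergeometric gene-set enrichment for (expanded) temporal blocks.

A query gene set (typically the genes of an expanded temporal block) is
tested against every term of a user-supplied GMT collection: the one-sided
enrichment p-value is the upper hypergeometric tail of the observed
overlap given the universe size, the term size within the universe and
the query size.  Benjamini-Hochberg controls the FDR across terms.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["read_gmt", "write_gmt", "hypergeom_enrichment"]


def read_gmt(path: str | Path) -> dict[str, dict]:
    """Read a tab-separated gene-set collection (term, description, members)."""
    collections: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line (needs >= 3 fields): {line!r}")
            term, description, *members = fields
            collections[term] = {
                "description": description,
                "genes": set(members),
            }
    return collections


def write_gmt(collections: Mapping[str, Mapping], path: str | Path) -> None:
    with open(path, "w") as fh:
        for term, rec in collections.items():
            members = "\t".join(sorted(rec["genes"]))
            fh.write(f"{term}\t{rec.get('description', '')}\t{members}\n")


def hypergeom_enrichment(
    query: Iterable[str],
    collections: Mapping[str, Mapping],
    universe: Iterable[str],
    fdr_alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment with Benjamini-Hochberg control.

    Parameters
    ----------
    query:
        Gene set under test; must be contained in ``universe``.
    collections:
        Mapping term -> {"description", "genes"}; term genes are
        intersected with the universe before testing.
    universe:
        Background gene set (typically all genes after prefiltering).
    fdr_alpha:
        FDR level for the ``significant`` flag.

    Returns
    -------
    DataFrame with one row per term: ``term``, ``description``,
    ``term_size`` (within the universe), ``overlap``, ``p``,
    ``p_adjusted``, ``significant``; sorted by adjusted then raw p.
    """
    query = set(query)
    universe = set(universe)
    if not collections:
        raise ValueError("empty gene-set collection")
    outside = sorted(query - universe)
    if outside:
        raise ValueError(f"query genes missing from the universe: {outside}")
    N, n = len(universe), len(query)
    rows = []
    for term, rec in collections.items():
        term_genes = set(rec["genes"]) & universe
        K = len(term_genes)
        k = len(term_genes & query)
        # upper tail: P(overlap >= k) under sampling n genes from N
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append(
            {
                "term": term,
                "description": rec.get("description", ""),
                "term_size": K,
                "overlap": k,
                "p": min(p, 1.0),
            }
        )
    table = pd.DataFrame(rows)
    _, adj, _, _ = multipletests(table["p"].to_numpy(), method="fdr_bh")
    table["p_adjusted"] = adj
    table["significant"] = table["p_adjusted"] < fdr_alpha
    table = table.sort_values(
        ["p_adjusted", "p", "term"], kind="mergesort"
    ).reset_index(drop=True)
    return table
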