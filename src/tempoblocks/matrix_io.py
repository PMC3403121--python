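"""Readers and writers for expression matrices, block reports and block networks.

The universal input is a genes x time-points real matrix stored as a
delimited text table (first column: gene ID, header row: ordered time
labels).  Temporal-block reports are JSON; networks are exported as SIF or
GraphML.  All round-trips are loss-free (exact for IDs and indices, to
floating-point precision for real values).

Time windows are 0-based and inclusive, ``[start, end]``, throughout the
package; I/O keeps the user's time labels for display but internal index
math always uses the canonical 0..n_times-1 positions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import networkx as nx

__all__ = [
    "MatrixFormatError",
    "ExpressionMatrix",
    "read_expression_matrix",
    "write_expression_matrix",
    "write_blocks",
    "read_blocks",
    "write_biclusters",
    "read_biclusters",
    "write_network",
    "read_network",
]


class MatrixFormatError(ValueError):
    """Structured parse/validation error for expression-matrix input."""


@dataclass
class ExpressionMatrix:
    """A genes x time-points real-valued matrix with ordered labels.

    Parameters
    ----------
    gene_ids:
        Unique row identifiers, in file order.
    time_points:
        Column labels in temporal order; internal index ``t`` refers to
        position ``t`` of this list.
    values:
        Array of shape ``(n_genes, n_times)``; finite after the
        missing-value policy has been applied.
    """

    gene_ids: list[str]
    time_points: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.time_points = [str(t) for t in self.time_points]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise MatrixFormatError("values must be a 2-D array")
        if self.values.shape != (len(self.gene_ids), len(self.time_points)):
            raise MatrixFormatError(
                f"shape mismatch: values {self.values.shape} vs "
                f"{len(self.gene_ids)} genes x {len(self.time_points)} time points"
            )
        seen: set[str] = set()
        for g in self.gene_ids:
            if g in seen:
                raise MatrixFormatError(f"duplicate gene ID: {g!r}")
            seen.add(g)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_times(self) -> int:
        return len(self.time_points)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.gene_ids, columns=self.time_points
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            gene_ids=list(map(str, frame.index)),
            time_points=list(map(str, frame.columns)),
            values=frame.to_numpy(dtype=float),
        )

    def subset_genes(self, indices: Sequence[int]) -> "ExpressionMatrix":
        indices = list(indices)
        return ExpressionMatrix(
            gene_ids=[self.gene_ids[i] for i in indices],
            time_points=list(self.time_points),
            values=self.values[indices, :],
        )


def _sep_for(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_expression_matrix(
    path: str | Path, missing_policy: str = "drop_gene"
) -> ExpressionMatrix:
    """Parse a delimited expression table.

    ``missing_policy`` is one of ``drop_gene`` (remove genes with any
    missing cell, the default) or ``fill_row_mean`` (impute by the gene's
    row mean).  Non-numeric cells raise :class:`MatrixFormatError` naming
    the offending row and column; duplicate gene IDs raise an error naming
    the ID.
    """
    if missing_policy not in ("drop_gene", "fill_row_mean"):
        raise ValueError(f"unknown missing_policy: {missing_policy!r}")
    raw = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=str)
    raw.index = raw.index.map(str)
    dup = raw.index[raw.index.duplicated()]
    if len(dup):
        raise MatrixFormatError(f"duplicate gene ID: {dup[0]!r}")
    def _parse(cell):
        # float() is correctly rounded, unlike pandas' fast parser
        if cell is None or (isinstance(cell, float) and np.isnan(cell)):
            return np.nan
        try:
            return float(cell)
        except ValueError:
            return None

    parsed = raw.map(_parse)
    bad = parsed.isna() & raw.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise MatrixFormatError(
            f"non-numeric cell at gene {raw.index[r]!r}, "
            f"time point {raw.columns[c]!r}: {raw.iat[r, c]!r}"
        )
    numeric = parsed
    values = parsed.to_numpy(dtype=float)
    missing = ~np.isfinite(values)
    if missing.any():
        if missing_policy == "drop_gene":
            keep = ~missing.any(axis=1)
            numeric = numeric.loc[keep]
            values = values[keep]
        else:
            row_mean = np.nanmean(np.where(np.isfinite(values), values, np.nan), axis=1)
            full_missing = ~np.isfinite(row_mean)
            if full_missing.any():  # nothing to impute from
                numeric = numeric.loc[~full_missing]
                values = values[~full_missing]
                row_mean = row_mean[~full_missing]
            idx = np.where(np.isfinite(values), values, row_mean[:, None])
            values = idx
    return ExpressionMatrix(
        gene_ids=list(numeric.index),
        time_points=list(map(str, numeric.columns)),
        values=values,
    )


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write the matrix as a delimited table (``.csv`` => comma, else tab).

    Floats are serialised with 17 significant digits, so a write/read
    round-trip is bitwise exact for double precision.
    """
    matrix.to_frame().to_csv(path, sep=_sep_for(path), float_format="%.17g")


# -- temporal-block and bicluster reports -----------------------------------


def _block_record(block, gene_ids: Sequence[str], block_id: int) -> dict:
    n = len(gene_ids)
    base = getattr(block, "base", None)
    b = base if base is not None else block
    for g in b.genes:
        if not 0 <= g < n:
            raise MatrixFormatError(f"block references unknown gene index {g}")
    rec = {
        "id": block_id,
        "genes": [gene_ids[g] for g in sorted(b.genes)],
        "start": int(b.start),
        "end": int(b.end),
        "disorder_span": list(b.disorder_span) if b.disorder_span else None,
        "async_ending": {
            gene_ids[g]: list(win) for g, win in sorted(b.async_ending.items())
        },
        "expanded": base is not None,
    }
    if base is not None:
        for g in block.genes_expanded:
            if not 0 <= g < n:
                raise MatrixFormatError(f"block references unknown gene index {g}")
        rec["genes_expanded"] = [gene_ids[g] for g in sorted(block.genes_expanded)]
        rec["correlation_threshold"] = block.p
        rec["linkage"] = block.linkage
    return rec


def write_blocks(blocks: Iterable, path: str | Path, gene_ids: Sequence[str]) -> None:
    """Write a structured JSON report, one record per (expanded) block.

    Windows are stored 0-based with inclusive ``[start, end]``.
    """
    records = [_block_record(b, gene_ids, i) for i, b in enumerate(blocks)]
    with open(path, "w") as fh:
        json.dump({"blocks": records}, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_blocks(path: str | Path, gene_ids: Sequence[str]) -> list:
    """Re-read a block report written by :func:`write_blocks`."""
    from .blocks import TemporalBlock, ExpandedTemporalBlock

    index = {g: i for i, g in enumerate(gene_ids)}
    with open(path) as fh:
        payload = json.load(fh)
    out = []
    for rec in payload["blocks"]:
        block = TemporalBlock(
            genes=frozenset(index[g] for g in rec["genes"]),
            start=rec["start"],
            end=rec["end"],
            disorder_span=tuple(rec["disorder_span"]) if rec["disorder_span"] else None,
            async_ending={
                index[g]: tuple(win) for g, win in rec["async_ending"].items()
            },
        )
        if rec.get("expanded"):
            block = ExpandedTemporalBlock(
                base=block,
                genes_expanded=frozenset(index[g] for g in rec["genes_expanded"]),
                p=rec["correlation_threshold"],
                linkage=rec["linkage"],
            )
        out.append(block)
    return out


def write_biclusters(biclusters: Iterable, path: str | Path, gene_ids: Sequence[str]) -> None:
    records = []
    n = len(gene_ids)
    for i, bc in enumerate(biclusters):
        for g in bc.genes:
            if not 0 <= g < n:
                raise MatrixFormatError(f"bicluster references unknown gene index {g}")
        records.append(
            {
                "id": i,
                "genes": [gene_ids[g] for g in sorted(bc.genes)],
                "start": int(bc.start),
                "end": int(bc.end),
                "reference_gene": gene_ids[bc.reference_gene],
                "pattern_type": bc.pattern_type,
                "epsilon": bc.epsilon,
            }
        )
    with open(path, "w") as fh:
        json.dump({"biclusters": records}, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_biclusters(path: str | Path, gene_ids: Sequence[str]) -> list:
    from .ebb import Bicluster

    index = {g: i for i, g in enumerate(gene_ids)}
    with open(path) as fh:
        payload = json.load(fh)
    return [
        Bicluster(
            genes=frozenset(index[g] for g in rec["genes"]),
            start=rec["start"],
            end=rec["end"],
            reference_gene=index[rec["reference_gene"]],
            pattern_type=rec["pattern_type"],
            epsilon=rec["epsilon"],
        )
        for rec in payload["biclusters"]
    ]


# -- network export ----------------------------------------------------------


def write_network(net, path: str | Path, format: str = "SIF") -> None:
    """Export a temporal block network.

    SIF rows are ``source<TAB>CPM<TAB>target`` (isolated nodes are written
    as a bare node name, per SIF convention); GraphML carries the link
    strength as the ``weight`` edge attribute.
    """
    graph: nx.DiGraph = net if isinstance(net, nx.Graph) else net.graph
    fmt = format.upper()
    if fmt == "SIF":
        with open(path, "w") as fh:
            for u, v, data in graph.edges(data=True):
                fh.write(f"{u}\tCPM\t{v}\n")
            for node in graph.nodes:
                if graph.degree(node) == 0:
                    fh.write(f"{node}\n")
    elif fmt == "GRAPHML":
        nx.write_graphml(graph, path)
    else:
        raise ValueError(f"unsupported network format: {format!r}")


def read_network(path: str | Path) -> nx.DiGraph:
    """Read a GraphML network back (used for round-trip verification)."""
    return nx.read_graphml(path)
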