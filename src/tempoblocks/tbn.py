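"""Directed temporal block network from partial-correlation link strength.

Two temporal blocks ``B1 = (G1, T1)`` and ``B2 = (G2, T2)`` may be linked
``B1 -> B2`` only when ``min T1 <= min T2 <= max T1 + 1`` (the target
starts inside, or immediately after, the source window).  The link weight
is the mean over source genes of the best conservatively-conditioned
partial correlation to a target gene,

    LS(B1, B2) = (1/|G1|) * sum_{X in G1} max_{Y in G2}
                 min_{Z in G2, Z != X, Y}  PR(X, Y | Z)

with all profiles restricted to the shared evaluation period
``[min T1, min(max T1, max T2)]``.  The minimum over conditioning genes Z
demands that the X-Y association survive the removal of any other target
gene's linear effect, so conduction through a third target gene does not
masquerade as a direct relation.  Edges are kept when LS exceeds the
threshold strictly (default 0.9); the signed value is thresholded, with
an absolute-value option.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations
from typing import Sequence

import numpy as np
import networkx as nx

from .blocks import TemporalBlock
from .matrix_io import ExpressionMatrix

__all__ = [
    "partial_correlation",
    "link_strength",
    "build_network",
    "TemporalBlockNetwork",
    "node_label",
]

_DEGENERATE = 1.0 - 1e-12  # |corr| at or above this conditions away nothing


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.corrcoef(x, y)[0, 1])


def partial_correlation(x, y, z) -> float:
    """First-order partial correlation PR(X, Y | Z).

    ``PR = (C_XY - C_XZ * C_YZ) / (sqrt(1 - C_XZ^2) * sqrt(1 - C_YZ^2))``.
    Returns NaN when the conditioning is undefined (|C_XZ| = 1 or
    |C_YZ| = 1); the caller decides how to treat it.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    z = np.asarray(z, float)
    if not (x.shape == y.shape == z.shape) or x.ndim != 1:
        raise ValueError("profiles must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("profiles must have length >= 3")
    for v, name in ((x, "x"), (y, "y"), (z, "z")):
        if np.ptp(v) == 0:
            raise ValueError(f"profile {name} is constant")
    cxy, cxz, cyz = _pearson(x, y), _pearson(x, z), _pearson(y, z)
    if abs(cxz) >= _DEGENERATE or abs(cyz) >= _DEGENERATE:
        return float("nan")
    return (cxy - cxz * cyz) / np.sqrt((1 - cxz**2) * (1 - cyz**2))


def _pc_from_corr(corr: np.ndarray, xi: int, yi: int, zi: int) -> float:
    cxy, cxz, cyz = corr[xi, yi], corr[xi, zi], corr[yi, zi]
    if abs(cxz) >= _DEGENERATE or abs(cyz) >= _DEGENERATE:
        return float("nan")
    return (cxy - cxz * cyz) / np.sqrt((1 - cxz**2) * (1 - cyz**2))


def _evaluation_period(b1: TemporalBlock, b2: TemporalBlock) -> tuple[int, int]:
    return (b1.start, min(b1.end, b2.end))


def admissible(b1: TemporalBlock, b2: TemporalBlock) -> bool:
    """Temporal admissibility of a directed link b1 -> b2."""
    return b1.start <= b2.start <= b1.end + 1


def link_strength(b1: TemporalBlock, b2: TemporalBlock, matrix) -> float:
    """Signed link strength of b1 -> b2 over their shared evaluation period.

    Degenerate conditioning genes (|C| = 1 with X or Y) are skipped in the
    inner minimum; a pair with no usable conditioning gene (|G2| <= 2, or
    all Z degenerate) falls back to the plain Pearson correlation C_X,Y.
    With a singleton target block the result is the mean plain correlation.
    """
    V = matrix.values if isinstance(matrix, ExpressionMatrix) else np.asarray(matrix, float)
    t0, t1 = _evaluation_period(b1, b2)
    if t1 - t0 + 1 < 3:
        raise ValueError(
            f"evaluation period [{t0}, {t1}] has fewer than 3 time points"
        )
    genes = sorted(set(b1.genes) | set(b2.genes))
    pos = {g: i for i, g in enumerate(genes)}
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(V[genes, t0 : t1 + 1])
    corr = np.atleast_2d(corr)
    g2 = sorted(b2.genes)
    totals = []
    for X in sorted(b1.genes):
        xi = pos[X]
        best = -np.inf
        for Y in g2:
            yi = pos[Y]
            if X == Y:
                pair = 1.0
            else:
                conditioned = [
                    _pc_from_corr(corr, xi, yi, pos[Z])
                    for Z in g2
                    if Z != X and Z != Y
                ]
                conditioned = [v for v in conditioned if not np.isnan(v)]
                pair = min(conditioned) if conditioned else corr[xi, yi]
            if not np.isnan(pair):
                best = max(best, pair)
        totals.append(best if np.isfinite(best) else np.nan)
    return float(np.nanmean(totals))


@dataclass
class TemporalBlockNetwork:
    """Directed graph over temporal blocks with link-strength edge weights."""

    graph: nx.DiGraph
    threshold: float
    blocks: list[TemporalBlock] = field(default_factory=list)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def node_label(block_id: int, block: TemporalBlock) -> str:
    """Node label "k - [f, t]": block id plus its time segmentation."""
    return f"{block_id} - [{block.start}, {block.end}]"


def build_network(
    blocks: Sequence[TemporalBlock],
    matrix,
    threshold: float = 0.9,
    omit_same_start: bool = False,
    use_absolute: bool = False,
) -> TemporalBlockNetwork:
    """Evaluate every temporally admissible ordered pair and keep strong links.

    ``omit_same_start`` suppresses edges between blocks sharing a start
    column (a rendering choice that focuses the network on asynchronous
    relations); ``use_absolute`` thresholds |LS| instead of the signed
    value.  Stored edge weights are always the signed link strength.
    """
    graph = nx.DiGraph()
    blocks = list(blocks)
    for i, b in enumerate(blocks):
        graph.add_node(node_label(i, b), start=b.start, end=b.end,
                       n_genes=len(b.genes))
    for i, j in permutations(range(len(blocks)), 2):
        b1, b2 = blocks[i], blocks[j]
        if not admissible(b1, b2):
            continue
        if omit_same_start and b1.start == b2.start:
            continue
        t0, t1 = _evaluation_period(b1, b2)
        if t1 - t0 + 1 < 3:
            continue
        ls = link_strength(b1, b2, matrix)
        if np.isnan(ls):
            continue
        value = abs(ls) if use_absolute else ls
        if value > threshold:
            graph.add_edge(node_label(i, b1), node_label(j, b2), weight=float(ls))
    return TemporalBlockNetwork(graph=graph, threshold=threshold, blocks=blocks)
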