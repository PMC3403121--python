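"""Boundary-gene estimation, temporal-block assembly and block expansion.

A gene is on the temporal boundary at time ``t`` when its bicluster
*start* events at ``t`` outweigh its *continuation* events:

    R(g, t) = |{biclusters containing g whose window starts at t}|
              / max(1, |{biclusters containing g at t that started earlier}|)

with ``R(g, 0) := 0`` at the global first column (every window trivially
"starts" there) and boundary membership decided strictly, ``R > theta``
(default ``theta = 1``).

Temporal blocks partition the segmented region of the matrix into
cell-disjoint sub-matrices.  Assembly is gene-wise: each maximal run of
consecutive boundary time points of a gene opens a segment that extends to
the column before the gene's next boundary run (or to the global last
column), and genes sharing an identical (start, end) segment form one
block.  This makes the four membership conditions hold by construction:

(a) every member is a boundary gene at the block start;
(b) no member is boundary at start-1 (unless start is the first column);
(c) no member is boundary at the block end (unless end is the last column);
(d) every member is boundary at end+1 (unless end is the last column);

and maximality/cell-disjointness follow from the runs being maximal and
per-gene disjoint.  A *disorder period* is recorded when members are
boundary again at consecutive columns after the start; an *asynchronous
ending* is recorded per gene for the trailing sub-window not covered by
any of its biclusters.  A segment lying entirely inside its own boundary
run (possible only at the global right edge) represents a reorganization
with no observed aftermath and is not emitted as a block.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .ebb import Bicluster
from .matrix_io import ExpressionMatrix

__all__ = [
    "BoundaryProfile",
    "TemporalBlock",
    "ExpandedTemporalBlock",
    "boundary_scores",
    "assemble_blocks",
    "validate_block",
    "expand_block",
    "boundary_gene_counts",
    "refined_boundary_counts",
    "local_peak_times",
]


@dataclass
class BoundaryProfile:
    """The R score matrix and the per-time boundary gene sets BG(t)."""

    R: np.ndarray  # (n_genes, n_times), >= 0
    theta: float
    BG: list[set[int]] = field(default_factory=list)

    def __post_init__(self):
        self.R = np.asarray(self.R, dtype=float)
        if not self.BG:
            self.BG = [
                set(np.flatnonzero(self.R[:, t] > self.theta).tolist())
                for t in range(self.R.shape[1])
            ]

    @property
    def n_genes(self) -> int:
        return self.R.shape[0]

    @property
    def n_times(self) -> int:
        return self.R.shape[1]

    def boundary_runs(self, gene: int) -> list[tuple[int, int]]:
        """Maximal runs [first, last] of consecutive boundary times of a gene."""
        times = [t for t in range(self.n_times) if gene in self.BG[t]]
        runs: list[tuple[int, int]] = []
        for t in times:
            if runs and t == runs[-1][1] + 1:
                runs[-1] = (runs[-1][0], t)
            else:
                runs.append((t, t))
        return runs


@dataclass(frozen=True)
class TemporalBlock:
    """A cell-disjoint sub-matrix assembled from boundary genes.

    ``disorder_span`` is the inclusive sub-window ``[start, d]`` over which
    member genes keep appearing on the boundary (recorded only when it
    extends past the start column); ``async_ending`` maps member genes to
    the inclusive trailing sub-window of the block not covered by any of
    their biclusters.
    """

    genes: frozenset[int]
    start: int
    end: int
    disorder_span: tuple[int, int] | None = None
    async_ending: dict[int, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self):
        if self.end < self.start:
            raise ValueError("block window must satisfy start <= end")
        if not self.genes:
            raise ValueError("block gene set must be non-empty")

    @property
    def window(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def has_disorder(self) -> bool:
        return self.disorder_span is not None

    def key(self) -> tuple:
        return (self.start, self.end, tuple(sorted(self.genes)))


@dataclass(frozen=True)
class ExpandedTemporalBlock:
    """A temporal block enlarged with correlated genes over its own window."""

    base: TemporalBlock
    genes_expanded: frozenset[int]
    p: float
    linkage: str = "any"

    def __post_init__(self):
        if not self.genes_expanded >= self.base.genes:
            raise ValueError("expanded gene set must contain the base genes")

    @property
    def genes(self) -> frozenset[int]:
        return self.genes_expanded

    @property
    def start(self) -> int:
        return self.base.start

    @property
    def end(self) -> int:
        return self.base.end

    @property
    def window(self) -> tuple[int, int]:
        return self.base.window


def boundary_scores(
    biclusters: Sequence[Bicluster],
    n_genes: int,
    n_times: int,
    theta: float = 1.0,
) -> BoundaryProfile:
    """Score every (gene, time) cell by start events over continuation events."""
    if theta < 0:
        raise ValueError("theta must be >= 0")
    S = np.zeros((n_genes, n_times))
    C = np.zeros((n_genes, n_times))
    for bc in biclusters:
        if bc.end >= n_times or bc.start < 0:
            raise IndexError(f"bicluster window {bc.window} exceeds {n_times} columns")
        for g in bc.genes:
            if not 0 <= g < n_genes:
                raise IndexError(f"bicluster gene index {g} out of range")
            S[g, bc.start] += 1
            if bc.end > bc.start:
                C[g, bc.start + 1 : bc.end + 1] += 1
    R = S / np.maximum(1.0, C)
    if n_times:
        R[:, 0] = 0.0  # no earlier time exists at the global first column
    return BoundaryProfile(R=R, theta=theta)


def _gene_coverage_end(
    gene: int, start: int, end: int, biclusters: Sequence[Bicluster]
) -> int:
    """Last column within [start, end] covered by any bicluster of the gene."""
    last = start - 1
    for bc in biclusters:
        if gene in bc.genes and bc.start <= end and bc.end >= start:
            last = max(last, min(bc.end, end))
    return last


def assemble_blocks(
    profile: BoundaryProfile,
    biclusters: Sequence[Bicluster],
    n_genes: int,
    n_times: int,
) -> list[TemporalBlock]:
    """Assemble the cell-disjoint temporal blocks from a boundary profile."""
    if profile.n_genes != n_genes or profile.n_times != n_times:
        raise ValueError(
            f"profile shape {(profile.n_genes, profile.n_times)} does not match "
            f"{(n_genes, n_times)}"
        )
    # per-gene segments: boundary-run start -> column before next run
    segments: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for g in range(n_genes):
        runs = profile.boundary_runs(g)
        for i, (rs, re) in enumerate(runs):
            seg_end = runs[i + 1][0] - 1 if i + 1 < len(runs) else n_times - 1
            if seg_end <= re:
                # window entirely inside the boundary run: a reorganization
                # with no observed aftermath (global right edge); not a block
                continue
            segments.setdefault((rs, seg_end), []).append((g, re))
    blocks: list[TemporalBlock] = []
    for (start, end), members in sorted(segments.items()):
        genes = frozenset(g for g, _ in members)
        d_end = max(re for _, re in members)
        disorder = (start, d_end) if d_end > start else None
        async_ending: dict[int, tuple[int, int]] = {}
        for g in sorted(genes):
            cov = _gene_coverage_end(g, start, end, biclusters)
            if cov < end:
                async_ending[g] = (cov + 1, end)
        blocks.append(
            TemporalBlock(
                genes=genes,
                start=start,
                end=end,
                disorder_span=disorder,
                async_ending=async_ending,
            )
        )
    blocks.sort(key=TemporalBlock.key)
    return blocks


def validate_block(
    block: TemporalBlock, profile: BoundaryProfile, n_times: int
) -> list[str]:
    """Literal check of the four membership conditions; [] iff all hold.

    Returns the subset of ["a", "b", "c", "d"] that is violated; used as
    the independent oracle for :func:`assemble_blocks`.
    """
    s, e = block.start, block.end
    violated = []
    if any(g not in profile.BG[s] for g in block.genes):
        violated.append("a")
    if s != 0 and any(g in profile.BG[s - 1] for g in block.genes):
        violated.append("b")
    if e != n_times - 1 and any(g in profile.BG[e] for g in block.genes):
        violated.append("c")
    if e != n_times - 1 and any(g not in profile.BG[e + 1] for g in block.genes):
        violated.append("d")
    return violated


def expand_block(
    block: TemporalBlock,
    matrix,
    p: float = 0.8,
    linkage: str = "any",
) -> ExpandedTemporalBlock:
    """Add outside genes correlated with the block over its own window.

    An outside gene joins when its Pearson correlation with the block's
    member profiles over ``[start, end]`` passes ``p`` under the chosen
    linkage: ``any`` (default; some member with C >= p), ``all`` (every
    member) or ``mean`` (average over members).  The window never changes.
    """
    if not 0 < p <= 1:
        raise ValueError("correlation threshold p must be in (0, 1]")
    if linkage not in ("any", "all", "mean"):
        raise ValueError(f"unknown linkage: {linkage!r}")
    V = matrix.values if isinstance(matrix, ExpressionMatrix) else np.asarray(matrix, float)
    s, e = block.start, block.end
    if e - s + 1 < 3:
        raise ValueError("block window too short for correlation (needs >= 3 points)")
    W = V[:, s : e + 1]
    members = sorted(block.genes)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(W)  # constant rows yield NaN, which never passes
    Cm = corr[:, members]
    Cm = np.where(np.isnan(Cm), -np.inf, Cm)
    if linkage == "any":
        score = Cm.max(axis=1)
    elif linkage == "all":
        score = Cm.min(axis=1)
    else:
        score = Cm.mean(axis=1)
    joiners = {g for g in np.flatnonzero(score >= p).tolist() if g not in block.genes}
    return ExpandedTemporalBlock(
        base=block,
        genes_expanded=block.genes | joiners,
        p=p,
        linkage=linkage,
    )


# -- boundary-count summaries (phase-transition tracing) ---------------------


def boundary_gene_counts(profile: BoundaryProfile) -> np.ndarray:
    """Original boundary-gene count per time point, |BG(t)|."""
    return np.array([len(bg) for bg in profile.BG])


def refined_boundary_counts(blocks: Iterable[TemporalBlock], n_times: int) -> np.ndarray:
    """Refined boundary-gene count: genes starting a final block at t."""
    counts = np.zeros(n_times, dtype=int)
    for b in blocks:
        counts[b.start] += len(b.genes)
    return counts


def local_peak_times(counts: Sequence[float]) -> list[int]:
    """Times with a strictly positive count no smaller than both neighbours."""
    c = np.asarray(counts, dtype=float)
    peaks = []
    for t in range(len(c)):
        left = c[t - 1] if t > 0 else -np.inf
        right = c[t + 1] if t + 1 < len(c) else -np.inf
        if c[t] > 0 and c[t] >= left and c[t] >= right:
            peaks.append(t)
    return peaks
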