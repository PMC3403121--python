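"""Seeded generators for validation fixtures.

Three kinds of fixtures are produced:

* planted-block matrices — a uniform random background with block-shaped
  shifting patterns (template plus per-gene offset) embedded at known
  positions; the default design is a 10 x 15 matrix with five 5-gene x
  4-column blocks, placement drawn from the seed;
* phase-structured series — genes organised into co-expression groups
  that partially reshuffle at every phase change, with known change
  points (a stylised two-cell-cycle course);
* the worked boundary example — a hand-built bicluster list over six
  genes whose boundary scores reproduce the canonical two-block division
  with a disorder period and an asynchronous ending.

The phase-series generator plants *paired* groups: each pair shares a
base template except on the last column of every phase, where the second
group of the pair is displaced by a large constant (a brief per-phase
desynchronization).  Every phase start therefore opens two nested
maximal patterns — the tight within-group bicluster spanning the phase
and beyond, and the looser cross-pair bicluster spanning the phase minus
its final column — which is exactly what the boundary score R needs to
exceed the strict default threshold theta = 1 at a change point.
Without such two-scale structure a clean group switch creates a single
maximal bicluster start and R never rises above 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .matrix_io import ExpressionMatrix
from .ebb import Bicluster
from .blocks import TemporalBlock

__all__ = [
    "PlantedBlock",
    "PlantedDesign",
    "default_design",
    "random_design",
    "generate_block_matrix",
    "PhaseSeries",
    "generate_phase_series",
    "chain_fixture",
    "worked_example_fixture",
]


@dataclass(frozen=True)
class PlantedBlock:
    """Ground-truth planted pattern: a gene set over a contiguous window."""

    genes: frozenset[int]
    start: int
    end: int

    def __post_init__(self):
        if self.end < self.start:
            raise ValueError("planted window must satisfy start <= end")
        if not self.genes:
            raise ValueError("planted gene set must be non-empty")

    @property
    def window(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class PlantedDesign:
    """A planted-matrix specification: background size, blocks, noise, seed."""

    n_genes: int = 10
    n_times: int = 15
    blocks: list[PlantedBlock] = field(default_factory=list)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for b in self.blocks:
            if b.end >= self.n_times or b.start < 0:
                raise ValueError(
                    f"planted window {b.window} exceeds matrix bounds "
                    f"(n_times={self.n_times})"
                )
            if max(b.genes) >= self.n_genes or min(b.genes) < 0:
                raise ValueError("planted gene set exceeds matrix bounds")


def _disjoint_starts(rng, n_windows: int, width: int, n_times: int) -> list[int]:
    """Seeded draw of sorted starts of non-overlapping equal-width windows."""
    free = n_times - n_windows * width
    if free < 0:
        raise ValueError("windows do not fit")
    slots = sorted(rng.choice(free + n_windows, size=n_windows, replace=False).tolist())
    return [a + (width - 1) * i for i, a in enumerate(slots)]


def default_design(seed: int = 0, noise_sd: float = 0.0) -> PlantedDesign:
    """The canonical validation design: 10 x 15, five 5 x 4 planted blocks.

    Five blocks with five genes each in ten rows force gene reuse, so the
    two row halves alternate: three windows on rows 0-4 and two on rows
    5-9, staggered in time with placement drawn from the seed (recorded
    in the returned ground truth).  Same-half windows never overlap, so
    every planted cell carries exactly one pattern.
    """
    rng = np.random.default_rng(seed)
    half_a = frozenset(range(0, 5))
    half_b = frozenset(range(5, 10))
    starts_a = _disjoint_starts(rng, 3, 4, 15)
    starts_b = _disjoint_starts(rng, 2, 4, 15)
    blocks = [PlantedBlock(half_a, s, s + 3) for s in starts_a]
    blocks += [PlantedBlock(half_b, s, s + 3) for s in starts_b]
    blocks.sort(key=lambda b: (b.start, min(b.genes)))
    return PlantedDesign(n_genes=10, n_times=15, blocks=blocks, noise_sd=noise_sd, seed=seed)


def random_design(
    n_genes: int = 10,
    n_times: int = 15,
    n_blocks: int = 5,
    block_genes: int = 5,
    block_cols: int = 4,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> PlantedDesign:
    """Fully randomized placement (blocks may collide; later plants win)."""
    rng = np.random.default_rng(seed)
    blocks = []
    for _ in range(n_blocks):
        genes = frozenset(rng.choice(n_genes, size=block_genes, replace=False).tolist())
        s = int(rng.integers(0, n_times - block_cols + 1))
        blocks.append(PlantedBlock(genes, s, s + block_cols - 1))
    return PlantedDesign(n_genes=n_genes, n_times=n_times, blocks=blocks,
                         noise_sd=noise_sd, seed=seed)


def generate_block_matrix(design: PlantedDesign) -> tuple[ExpressionMatrix, list[PlantedBlock]]:
    """Materialise a planted design.

    Background cells are i.i.d. uniform on [0, 1); inside each planted
    block, gene g at time t equals template(t) + offset_g (an exact
    shifting pattern with zero residual when noise_sd = 0), with the
    template drawn uniform on [0, 1) and offsets uniform on [0, 1).
    Blocks are planted in order; on a cell collision the later plant
    overwrites the earlier one.  Returns the matrix and the ground truth.
    """
    rng = np.random.default_rng(design.seed)
    values = rng.uniform(0.0, 1.0, size=(design.n_genes, design.n_times))
    for block in design.blocks:
        width = block.end - block.start + 1
        template = rng.uniform(0.0, 1.0, size=width)
        for g in sorted(block.genes):
            offset = rng.uniform(0.0, 1.0)
            row = template + offset
            if design.noise_sd > 0:
                row = row + rng.normal(0.0, design.noise_sd, size=width)
            values[g, block.start : block.end + 1] = row
    matrix = ExpressionMatrix(
        gene_ids=[f"g{i + 1}" for i in range(design.n_genes)],
        time_points=[f"t{j + 1}" for j in range(design.n_times)],
        values=values,
    )
    return matrix, list(design.blocks)


class PhaseSeries(NamedTuple):
    """Phase-structured fixture: matrix, true change points, ground truth."""

    matrix: ExpressionMatrix
    change_points: list[int]
    switches: dict[int, set[int]]  # change point -> genes reassigned there
    groups: np.ndarray  # (n_phases, n_genes) group id per phase


def generate_phase_series(
    n_genes: int = 40,
    n_phases: int = 6,
    points_per_phase: int = 3,
    turnover_fraction: float = 0.5,
    noise_sd: float = 0.01,
    seed: int = 0,
    n_groups: int = 4,
    divergence: float = 1.0,
) -> PhaseSeries:
    """Phase-structured periodic series with known change points.

    Genes belong to one of ``n_groups`` co-expression groups; at every
    phase change each gene is independently reassigned to a different
    group with probability ``turnover_fraction`` (the reorganization the
    boundary score is meant to detect).  Groups come in pairs sharing a
    base random-walk template; the second group of each pair is displaced
    by ``divergence`` on the last column of every phase, which gives each
    reorganization a second, loosely-bounded pattern start (see the
    module docstring).  Gene profiles are the group template plus a
    per-gene offset plus Gaussian noise.
    """
    if n_phases < 2:
        raise ValueError("n_phases must be >= 2")
    if points_per_phase < 3:
        raise ValueError("points_per_phase must be >= 3")
    if not 0.0 <= turnover_fraction <= 1.0:
        raise ValueError("turnover_fraction must be in [0, 1]")
    if n_groups < 2 or n_groups % 2:
        raise ValueError("n_groups must be an even number >= 2")
    rng = np.random.default_rng(seed)
    n_times = n_phases * points_per_phase
    t = np.arange(n_times)

    n_pairs = n_groups // 2
    base = np.empty((n_pairs, n_times))
    for i in range(n_pairs):
        base[i] = rng.uniform(0.0, 1.0) + np.concatenate(
            [[0.0], np.cumsum(rng.normal(0.0, 0.5, size=n_times - 1))]
        )
    desync = divergence * (t % points_per_phase == points_per_phase - 1)
    templates = np.empty((n_groups, n_times))
    templates[0::2] = base
    templates[1::2] = base + desync

    change_points = [points_per_phase * i for i in range(1, n_phases)]
    groups = np.empty((n_phases, n_genes), dtype=int)
    groups[0] = rng.integers(0, n_groups, size=n_genes)
    switches: dict[int, set[int]] = {}
    for phase, cp in enumerate(change_points, start=1):
        current = groups[phase - 1].copy()
        flip = rng.random(n_genes) < turnover_fraction
        for g in np.flatnonzero(flip):
            others = [k for k in range(n_groups) if k != current[g]]
            current[g] = rng.choice(others)
        groups[phase] = current
        switches[cp] = set(np.flatnonzero(flip).tolist())

    offsets = rng.uniform(0.0, 2.0, size=n_genes)
    values = np.empty((n_genes, n_times))
    for j in range(n_times):
        phase = j // points_per_phase
        values[:, j] = templates[groups[phase], j] + offsets
    values += rng.normal(0.0, noise_sd, size=values.shape)
    matrix = ExpressionMatrix(
        gene_ids=[f"g{i + 1}" for i in range(n_genes)],
        time_points=[f"t{j + 1}" for j in range(n_times)],
        values=values,
    )
    return PhaseSeries(matrix, change_points, switches, groups)


def chain_fixture(
    n_per_block: int = 4,
    noise_sd: float = 0.005,
    seed: int = 0,
) -> tuple[ExpressionMatrix, list[TemporalBlock]]:
    """Three temporal blocks planted as a causal chain B1 -> B2 -> B3.

    Block windows are [0,5], [4,9], [8,13] over 14 time points; each gene
    of block k+1 is a near-copy of a distinct block-k gene, and the
    underlying processes are independent random walks, so within a target
    block only the matched partner correlates with a given source gene
    and the minimum conditioned partial correlation stays near 1.
    Adjacent blocks overlap temporally (admissible edges) while B1 and B3
    do not (no edge regardless of correlation).
    """
    rng = np.random.default_rng(seed)
    n_times = 14
    procs = np.cumsum(rng.normal(0.0, 1.0, size=(n_per_block, n_times)), axis=1)
    rows = []
    for k in range(3):
        rows.append(procs + rng.normal(0.0, noise_sd, size=procs.shape) + k * 5.0)
    values = np.vstack(rows)
    matrix = ExpressionMatrix(
        gene_ids=[f"g{i + 1}" for i in range(3 * n_per_block)],
        time_points=[f"t{j + 1}" for j in range(n_times)],
        values=values,
    )
    windows = [(0, 5), (4, 9), (8, 13)]
    blocks = [
        TemporalBlock(
            genes=frozenset(range(k * n_per_block, (k + 1) * n_per_block)),
            start=s,
            end=e,
        )
        for k, (s, e) in enumerate(windows)
    ]
    return matrix, blocks


def worked_example_fixture() -> tuple[list[Bicluster], list[TemporalBlock]]:
    """The canonical worked example: six genes, seven time points.

    The bicluster list is built so that the boundary sets are
    BG(t2) = {g1..g4}, BG(t3) = {g1, g2, g3, g5, g6} and BG(t7) = all
    (0-based columns 1, 2 and 6), which assembles into exactly two
    temporal blocks: {(g1..g4), [t2, t6]} with a disorder period over
    (t2, t3) and an asynchronous ending for (g3, g4) over (t5, t6), and
    {(g5, g6), [t3, t6]} with neither.  The single-column biclusters at
    the last time point model the reorganization that terminates both
    blocks at t6.
    """
    def bc(genes, start, end):
        return Bicluster(
            genes=frozenset(genes), start=start, end=end,
            reference_gene=min(genes), pattern_type="shifting", epsilon=0.0,
        )

    biclusters = [
        bc({0, 1, 2, 3}, 1, 3),
        bc({0, 1, 2, 3}, 1, 2),
        bc({0, 1, 2}, 2, 3),
        bc({0, 1}, 2, 5),
        bc({1, 2}, 2, 3),
        bc({0, 2}, 2, 3),
        bc({4, 5}, 2, 5),
        bc({4, 5}, 2, 4),
        bc({0, 1, 2, 3, 4, 5}, 6, 6),
        bc({0, 1, 2}, 6, 6),
        bc({3, 4, 5}, 6, 6),
    ]
    expected = [
        TemporalBlock(
            genes=frozenset({0, 1, 2, 3}),
            start=1,
            end=5,
            disorder_span=(1, 2),
            async_ending={2: (4, 5), 3: (4, 5)},
        ),
        TemporalBlock(
            genes=frozenset({4, 5}),
            start=2,
            end=5,
            disorder_span=None,
            async_ending={},
        ),
    ]
    return biclusters, expected
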