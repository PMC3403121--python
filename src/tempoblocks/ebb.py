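"""Error-bounded biclustering (EBB) over contiguous time windows.

A bicluster is a gene set ``G`` over a contiguous window ``[start, end]``
such that some reference gene ``r`` in ``G`` certifies an error-bounded
linear pattern for every member: the per-cell residual of the member's
profile against the reference never exceeds ``epsilon``.

Three pattern families are supported:

``shifting``
    ``x = r + c``: residual is the worst deviation of the profile
    difference from its value at the window's first column,
    ``max_t |(x_t - x_s) - (r_t - r_s)|``.  Exactly error-bounded and
    symmetric in (x, r).
``scaling``
    ``x = c * r`` for positive data: shifting residual after an
    elementwise log.
``linear``
    ``x ~ a*r + b``: maximum absolute residual of the least-squares
    affine fit.

Enumeration returns the maximal patterns only: no output bicluster's gene
set or window can be grown while keeping the criterion, and candidates
whose (gene set, window) are jointly contained in another's are dropped.
The run-length discretization below (0/1 prefix-closed rows per reference
and window start) is the accelerator; the semantics are fixed by the
maximal-pattern definition, and :func:`bruteforce_biclusters` restates it
as a direct exhaustive search for verification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .matrix_io import ExpressionMatrix

__all__ = [
    "Bicluster",
    "pattern_residual",
    "discretize",
    "enumerate_biclusters",
    "bruteforce_biclusters",
]

PATTERN_TYPES = ("shifting", "scaling", "linear")


@dataclass(frozen=True)
class Bicluster:
    """A gene set over a contiguous time window with an error-bounded pattern.

    ``start``/``end`` are 0-based inclusive column indices.  ``reference_gene``
    is one certifying member; the same (genes, window) reached through a
    different reference is reported once.
    """

    genes: frozenset[int]
    start: int
    end: int
    reference_gene: int
    pattern_type: str = "shifting"
    epsilon: float = 0.0

    def __post_init__(self):
        if self.end < self.start:
            raise ValueError("bicluster window must satisfy start <= end")
        if not self.genes:
            raise ValueError("bicluster gene set must be non-empty")
        if self.pattern_type not in PATTERN_TYPES:
            raise ValueError(f"unknown pattern type: {self.pattern_type!r}")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cols(self) -> int:
        return self.end - self.start + 1

    @property
    def window(self) -> tuple[int, int]:
        return (self.start, self.end)

    def key(self) -> tuple:
        """Canonical identity: (start, end, sorted genes)."""
        return (self.start, self.end, tuple(sorted(self.genes)))


def _values(matrix) -> np.ndarray:
    if isinstance(matrix, ExpressionMatrix):
        return matrix.values
    return np.asarray(matrix, dtype=float)


def pattern_residual(gene_profile, ref_profile, pattern_type: str = "shifting") -> float:
    """Worst per-cell residual of a profile against a reference pattern."""
    x = np.asarray(gene_profile, dtype=float)
    r = np.asarray(ref_profile, dtype=float)
    if x.shape != r.shape or x.ndim != 1:
        raise ValueError("profiles must be 1-D vectors of equal length")
    if x.size < 2:
        raise ValueError("profiles must have length >= 2")
    if pattern_type == "shifting":
        d = x - r
        return float(np.max(np.abs(d - d[0])))
    if pattern_type == "scaling":
        if np.any(x <= 0) or np.any(r <= 0):
            raise ValueError("scaling pattern requires strictly positive values")
        return pattern_residual(np.log(x), np.log(r), "shifting")
    if pattern_type == "linear":
        A = np.column_stack([r, np.ones_like(r)])
        coef, *_ = np.linalg.lstsq(A, x, rcond=None)
        return float(np.max(np.abs(x - A @ coef)))
    raise ValueError(f"unknown pattern type: {pattern_type!r}")


def discretize(
    matrix,
    reference_gene: int,
    window_start: int,
    epsilon: float,
    pattern_type: str = "shifting",
) -> np.ndarray:
    """0/1 matrix over genes x columns for one reference and window start.

    Cell ``(g, t)`` for ``t >= window_start`` is 1 iff gene ``g`` still
    satisfies the pattern criterion against the reference over every
    prefix ``[window_start, tau]``, ``tau <= t``; once a row turns 0 it
    stays 0 (prefix closure, which makes rows encodable as left-anchored
    1-runs).  Columns before ``window_start`` are 0; the single-column
    prefix is trivially 1.
    """
    V = _values(matrix)
    n_genes, n_times = V.shape
    if not 0 <= reference_gene < n_genes:
        raise IndexError(f"reference gene {reference_gene} out of range")
    if not 0 <= window_start < n_times:
        raise IndexError(f"window start {window_start} out of range")
    out = np.zeros((n_genes, n_times), dtype=np.int8)
    s = window_start
    if pattern_type in ("shifting", "scaling"):
        W = V
        if pattern_type == "scaling":
            if np.any(V <= 0):
                raise ValueError("scaling pattern requires strictly positive values")
            W = np.log(V)
        D = W - W[reference_gene]
        dev = np.abs(D[:, s:] - D[:, s : s + 1])
        ok = np.maximum.accumulate(dev, axis=1) <= epsilon
        out[:, s:] = np.cumprod(ok, axis=1)
        return out
    if pattern_type == "linear":
        out[:, s] = 1
        alive = np.ones(n_genes, dtype=bool)
        for t in range(s + 1, n_times):
            for g in np.flatnonzero(alive):
                res = pattern_residual(V[g, s : t + 1], V[reference_gene, s : t + 1], "linear")
                if res <= epsilon:
                    out[g, t] = 1
                else:
                    alive[g] = False
            if not alive.any():
                break
        return out
    raise ValueError(f"unknown pattern type: {pattern_type!r}")


def _drop_dominated(candidates: dict[tuple, int]) -> list[tuple]:
    """Remove (genes, start, end) jointly contained in another candidate.

    ``candidates`` maps key (start, end, genes frozenset) -> reference.
    """
    items = list(candidates.items())
    keep = []
    for (s1, e1, g1), ref1 in items:
        dominated = False
        for (s2, e2, g2), _ in items:
            if (s1, e1, g1) == (s2, e2, g2):
                continue
            if s2 <= s1 and e1 <= e2 and g1 <= g2:
                dominated = True
                break
        if not dominated:
            keep.append(((s1, e1, g1), ref1))
    return keep


def enumerate_biclusters(
    matrix,
    epsilon: float,
    min_genes: int = 2,
    min_cols: int = 2,
    pattern_type: str = "shifting",
) -> list[Bicluster]:
    """Enumerate all maximal error-bounded biclusters.

    Every window start is scanned with every gene as reference; per
    reference, prefix-closed 1-runs (see :func:`discretize`) give each
    gene a maximal reach, and each distinct reach defines a row-maximal
    candidate.  Candidates dominated across references/starts are dropped
    and the rest are returned in canonical (start, end, genes) order.
    """
    if min_genes < 2:
        raise ValueError("min_genes must be >= 2")
    if min_cols < 2:
        raise ValueError("min_cols must be >= 2")
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    V = _values(matrix)
    n_genes, n_times = V.shape
    candidates: dict[tuple, int] = {}

    if pattern_type in ("shifting", "scaling"):
        W = V
        if pattern_type == "scaling":
            if np.any(V <= 0):
                raise ValueError("scaling pattern requires strictly positive values")
            W = np.log(V)
        for r in range(n_genes):
            D = W - W[r]
            for s in range(0, n_times - min_cols + 1):
                dev = np.abs(D[:, s:] - D[:, s : s + 1])
                ok = np.maximum.accumulate(dev, axis=1) <= epsilon
                reach = s + np.cumprod(ok, axis=1).sum(axis=1) - 1  # per-gene max end
                min_end = s + min_cols - 1
                for e in np.unique(reach[reach >= min_end]):
                    genes = frozenset(np.flatnonzero(reach >= e).tolist())
                    if len(genes) >= min_genes:
                        candidates.setdefault((s, int(e), genes), r)
    elif pattern_type == "linear":
        for r in range(n_genes):
            for s in range(0, n_times - min_cols + 1):
                B = discretize(V, r, s, epsilon, "linear")
                reach = s + B[:, s:].cumprod(axis=1).sum(axis=1) - 1
                min_end = s + min_cols - 1
                for e in np.unique(reach[reach >= min_end]):
                    genes = frozenset(np.flatnonzero(reach >= e).tolist())
                    if len(genes) >= min_genes:
                        candidates.setdefault((s, int(e), genes), r)
    else:
        raise ValueError(f"unknown pattern type: {pattern_type!r}")

    kept = _drop_dominated(candidates)
    out = [
        Bicluster(
            genes=g,
            start=s,
            end=e,
            reference_gene=ref,
            pattern_type=pattern_type,
            epsilon=epsilon,
        )
        for (s, e, g), ref in kept
    ]
    out.sort(key=Bicluster.key)
    return out


def bruteforce_biclusters(
    matrix,
    epsilon: float,
    min_genes: int = 2,
    min_cols: int = 2,
    pattern_type: str = "shifting",
) -> list[Bicluster]:
    """Exhaustive reference enumerator used as the independent oracle.

    Triple loop over (reference, start, end); the gene set is the greedy
    closure of all genes whose prefix residuals against the reference stay
    within ``epsilon``.  Quadratic containment filtering removes dominated
    candidates.  Intentionally naive: no run-length sharing, no
    incremental residuals.
    """
    if min_genes < 2 or min_cols < 2:
        raise ValueError("minimum bicluster size is 2*2")
    V = _values(matrix)
    n_genes, n_times = V.shape
    candidates: dict[tuple, int] = {}
    for r in range(n_genes):
        for s in range(n_times):
            for e in range(s + min_cols - 1, n_times):
                genes = []
                for g in range(n_genes):
                    ok = all(
                        pattern_residual(V[g, s : t + 1], V[r, s : t + 1], pattern_type)
                        <= epsilon
                        for t in range(s + 1, e + 1)
                    )
                    if ok:
                        genes.append(g)
                if len(genes) >= min_genes:
                    candidates.setdefault((s, e, frozenset(genes)), r)
    kept = _drop_dominated(candidates)
    out = [
        Bicluster(genes=g, start=s, end=e, reference_gene=ref,
                  pattern_type=pattern_type, epsilon=epsilon)
        for (s, e, g), ref in kept
    ]
    out.sort(key=Bicluster.key)
    return out
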