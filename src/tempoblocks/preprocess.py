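"""Gene prefiltering by one-way ANOVA across time-point groups.

Time points are assigned to phase groups (e.g. six consecutive triples for
an 18-column two-cell-cycle course) and each gene is tested for unequal
group means with the one-way ANOVA F statistic; genes with p below the
significance threshold are retained.  Raw p-values are compared to alpha
(no multiple-testing correction at this stage).  Constant-profile genes
have an undefined F (zero between- and within-group variance) and are
dropped with a warning rather than raising, since real matrices routinely
contain flat probes.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .matrix_io import ExpressionMatrix

__all__ = ["anova_filter"]


def anova_filter(
    matrix: ExpressionMatrix,
    groups: Sequence,
    alpha: float = 0.05,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Retain genes whose expression differs across time-point groups.

    Parameters
    ----------
    matrix:
        Expression matrix, genes x time points.
    groups:
        One group label per time point (any hashable); every group needs
        at least two members and there must be at least two groups.
    alpha:
        Raw-p significance threshold (default 0.05).

    Returns
    -------
    (filtered, table):
        ``filtered`` is the sub-matrix of genes with ``p < alpha`` in the
        original gene order; ``table`` has one row per input gene with
        columns ``F``, ``p``, ``constant`` and ``retained``.
    """
    groups = list(groups)
    if len(groups) != matrix.n_times:
        raise ValueError(
            f"{len(groups)} group labels for {matrix.n_times} time points"
        )
    labels = sorted(set(groups), key=str)
    if len(labels) < 2:
        raise ValueError("at least two time-point groups are required")
    members = {lab: [i for i, g in enumerate(groups) if g == lab] for lab in labels}
    for lab, idx in members.items():
        if len(idx) < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 time points")
    samples = [matrix.values[:, members[lab]] for lab in labels]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant rows produce NaN F below
        F, p = stats.f_oneway(*samples, axis=1)
    constant = np.array([np.ptp(matrix.values[i]) == 0 for i in range(matrix.n_genes)])
    undefined = ~np.isfinite(F)
    if (constant & undefined).any():
        n_flat = int((constant & undefined).sum())
        warnings.warn(
            f"dropping {n_flat} constant-profile gene(s) with undefined F",
            UserWarning,
            stacklevel=2,
        )
    retained = np.isfinite(p) & (p < alpha)
    table = pd.DataFrame(
        {
            "gene": matrix.gene_ids,
            "F": F,
            "p": p,
            "constant": constant,
            "retained": retained,
        }
    )
    filtered = matrix.subset_genes(np.flatnonzero(retained))
    return filtered, table
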