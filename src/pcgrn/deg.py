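"""Differential-expression filtering and set operations.

The pipeline's DEG gate is FDR < 0.05 (strict) with absolute fold change
>= 2 (inclusive, i.e. |log2FC| >= 1). Real DE tables (DESeq2/edgeR output)
can be supplied directly; :func:`test_differential` is a simple per-gene
Welch test on log-scale values provided so synthetic data can flow through
the whole pipeline, and makes no claim of equivalence to count-based models.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import reduce

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = ["DEResultRow", "DEGSummary", "test_differential", "filter_degs",
           "intersect_deg_sets"]


@dataclass(frozen=True)
class DEResultRow:
    gene: str
    log2_fold_change: float
    p_value: float
    fdr: float

    def __post_init__(self) -> None:
        if not (0 <= self.p_value <= 1 and 0 <= self.fdr <= 1):
            raise ValueError(f"p/fdr out of [0,1] for {self.gene}")


@dataclass(frozen=True)
class DEGSummary:
    genes: dict[str, str]    # gene -> 'up' | 'down'
    n_total: int
    n_up: int
    n_down: int

    @property
    def gene_set(self) -> set[str]:
        return set(self.genes)


def test_differential(expr, group_a, group_b) -> list[DEResultRow]:
    """Per-gene Welch two-sample t-test between two sample groups.

    Values are taken as already log2-scale, so the effect size
    ``mean(a) - mean(b)`` is reported directly as log2 fold change.
    Benjamini-Hochberg correction is applied across all genes. Zero-variance
    conventions: identical groups give p = 1; zero variance with a nonzero
    mean difference gives p = 0 (with a warning).
    """
    group_a, group_b = list(group_a), list(group_b)
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    ids = [s.sample_id for s in expr.samples]
    ia = [ids.index(s) for s in group_a]
    ib = [ids.index(s) for s in group_b]
    a = expr.values[:, ia]
    b = expr.values[:, ib]
    lfc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    zero_var = (a.std(axis=1) == 0) & (b.std(axis=1) == 0)
    if zero_var.any():
        p = p.copy()
        p[zero_var & (lfc == 0)] = 1.0
        nz = zero_var & (lfc != 0)
        p[nz] = 0.0
        if nz.any():
            logger.warning("%d zero-variance genes with nonzero difference "
                           "assigned p = 0", int(nz.sum()))
    p = np.nan_to_num(p, nan=1.0)
    fdr = multipletests(p, method="fdr_bh")[1]
    return [DEResultRow(g, float(lfc[i]), float(p[i]), float(fdr[i]))
            for i, g in enumerate(expr.genes)]


def filter_degs(rows, fdr_max: float = 0.05, min_fold: float = 2.0) -> DEGSummary:
    """Retain genes with ``fdr < fdr_max`` (strict) and ``|log2FC| >=
    log2(min_fold)`` (inclusive); label up/down by the sign of log2FC."""
    if min_fold < 1:
        raise ValueError("min_fold must be >= 1")
    min_lfc = math.log2(min_fold)
    genes: dict[str, str] = {}
    for row in rows:
        if row.fdr < fdr_max and abs(row.log2_fold_change) >= min_lfc:
            genes[row.gene] = "up" if row.log2_fold_change > 0 else "down"
    n_up = sum(1 for d in genes.values() if d == "up")
    return DEGSummary(genes=genes, n_total=len(genes), n_up=n_up,
                      n_down=len(genes) - n_up)


def intersect_deg_sets(sets) -> set[str]:
    """Exact intersection of two or more gene sets."""
    sets = [set(s) for s in sets]
    if len(sets) < 2:
        raise ValueError("need at least 2 sets to intersect")
    return reduce(set.intersection, sets)
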