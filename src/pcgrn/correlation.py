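"""Pearson coexpression and first-order partial correlation.

The mediation logic of the pipeline rests on two quantities computed across
samples of an expression matrix:

* the Pearson correlation coefficient (CC) between two genes, gated at
  ``|r| >= cc_min`` and ``p < p_max`` to call a *coexpressed pair*, and
* the first-order partial correlation (PCC) of a coexpressed pair (x, y)
  conditioned on a transcription factor z,

      r_xy|z = (r_xy - r_xz * r_yz) / (sqrt(1 - r_xz^2) * sqrt(1 - r_yz^2)).

A small ``|r_xy|z|`` means z statistically explains the pair's coexpression
and is the evidence from which directed TF->gene edges are drawn.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "CorrelationResult",
    "CorrelationTriple",
    "CoexpressionPair",
    "pearson",
    "correlation_matrix",
    "coexpressed_pairs",
    "partial_correlation",
    "pcc_for_pair",
]


class DegenerateConditioningError(ValueError):
    """Conditioning variable is perfectly correlated with a pair member."""


class ConstantVectorError(ValueError):
    """Correlation of a constant vector is undefined."""


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n: int

    def __post_init__(self) -> None:
        if abs(self.r) > 1 + 1e-12:
            raise ValueError(f"correlation out of range: {self.r}")


@dataclass(frozen=True)
class CorrelationTriple:
    """Correlations among a coexpressed pair (x, y) and a TF z."""

    r_xy: float
    r_xz: float
    r_yz: float


@dataclass(frozen=True)
class CoexpressionPair:
    """Unordered coexpressed gene pair, stored with gene_x < gene_y."""

    gene_x: str
    gene_y: str
    result: CorrelationResult

    def __post_init__(self) -> None:
        if self.gene_x == self.gene_y:
            raise ValueError("a coexpression pair needs two distinct genes")
        if self.gene_x > self.gene_y:
            raise ValueError("pair must be stored with gene_x < gene_y")

    @property
    def genes(self) -> frozenset[str]:
        return frozenset((self.gene_x, self.gene_y))


def pearson(x, y) -> CorrelationResult:
    """Sample Pearson correlation with a two-sided t-test p-value.

    The p-value comes from ``t = r * sqrt((n - 2) / (1 - r^2))`` on n - 2
    degrees of freedom; ``r = +/-1`` yields ``p = 0``. Constant input raises
    :class:`ConstantVectorError` rather than returning NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations for a p-value")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantVectorError("correlation of a constant vector is undefined")
    r, p = stats.pearsonr(x, y)
    r = float(np.clip(r, -1.0, 1.0))
    # exact collinearity can come back a few ulp shy of +/-1
    if abs(r) >= 1.0 - 1e-12:
        r = math.copysign(1.0, r)
        p = 0.0
    return CorrelationResult(r=r, p_value=float(p), n=n)


def correlation_matrix(values: np.ndarray) -> np.ndarray:
    """All-pairs Pearson matrix for a genes x samples array."""
    values = np.asarray(values, dtype=float)
    sd = values.std(axis=1)
    if np.any(sd == 0):
        raise ConstantVectorError("constant gene rows have undefined correlations")
    r = np.corrcoef(values)
    return np.clip(r, -1.0, 1.0)


def _pearson_p(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p from the t statistic of r on n - 2 df (vectorized)."""
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1 - r**2, 1e-300))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    return np.where(np.abs(r) == 1.0, 0.0, p)


def coexpressed_pairs(expr, candidates, cc_min: float = 0.8,
                      p_max: float = 0.001) -> list[CoexpressionPair]:
    """All unordered candidate pairs with ``|r| >= cc_min`` and ``p < p_max``.

    ``expr`` is an :class:`~pcgrn.synthetic.ExpressionMatrix` (or anything
    with ``.values`` genes x samples and ``.genes``). Output is ordered
    lexicographically by (gene_x, gene_y).
    """
    candidates = sorted(set(candidates))
    missing = [g for g in candidates if g not in expr.gene_index]
    if missing:
        raise KeyError(f"candidate genes absent from matrix: {missing[:5]}")
    n = expr.n_samples
    if n < 3:
        raise ValueError("need at least 3 samples to call coexpression")
    idx = [expr.gene_index[g] for g in candidates]
    sub = expr.values[idx, :]
    r = correlation_matrix(sub)
    p = _pearson_p(r, n)
    out: list[CoexpressionPair] = []
    for i, j in itertools.combinations(range(len(candidates)), 2):
        if abs(r[i, j]) >= cc_min and p[i, j] < p_max:
            out.append(CoexpressionPair(
                gene_x=candidates[i], gene_y=candidates[j],
                result=CorrelationResult(r=float(r[i, j]), p_value=float(p[i, j]), n=n),
            ))
    return out


def partial_correlation(t: CorrelationTriple, formula: str = "standard") -> float:
    """First-order partial correlation r_xy|z of a triple of correlations.

    ``formula="standard"`` uses the numerator ``r_xy - r_xz * r_yz``.
    ``formula="printed"`` reproduces a literal variant with numerator
    ``r_xy - r_xy * r_yz`` (an asymmetric form kept only for comparison; it
    is not a valid partial correlation).
    """
    if formula not in ("standard", "printed"):
        raise ValueError(f"unknown formula: {formula!r}")
    if abs(t.r_xz) >= 1.0 or abs(t.r_yz) >= 1.0:
        raise DegenerateConditioningError(
            "cannot condition on a variable perfectly correlated with the pair")
    if formula == "standard":
        num = t.r_xy - t.r_xz * t.r_yz
    else:
        num = t.r_xy - t.r_xy * t.r_yz
    den = math.sqrt(1.0 - t.r_xz**2) * math.sqrt(1.0 - t.r_yz**2)
    val = num / den
    # clamp only floating-point overshoot; genuine out-of-range inputs
    # (non-PSD free-standing triples) are the caller's responsibility
    if 1.0 < abs(val) <= 1.0 + 1e-12:
        val = math.copysign(1.0, val)
    return val


def pcc_for_pair(expr, pair: CoexpressionPair, tf: str,
                 formula: str = "standard") -> float:
    """Empirical r_xy|z for a coexpressed pair given a TF, from the matrix."""
    if tf in pair.genes:
        raise ValueError(f"TF {tf!r} is a member of the pair")
    if tf not in expr.gene_index:
        raise KeyError(f"TF {tf!r} absent from matrix")
    x = expr.values[expr.gene_index[pair.gene_x]]
    y = expr.values[expr.gene_index[pair.gene_y]]
    z = expr.values[expr.gene_index[tf]]
    triple = CorrelationTriple(
        r_xy=pearson(x, y).r, r_xz=pearson(x, z).r, r_yz=pearson(y, z).r)
    return partial_correlation(triple, formula=formula)
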