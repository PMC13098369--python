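"""Wet-lab verification arithmetic for predicted regulatory edges.

A predicted TF->gene edge is tested two ways: ChIP-PCR against the four
equal tiles of the target's upstream region (binding to any tile = *direct*
regulation), and perturbation qPCR (significant expression change, fold
change >= 2 in either direction with p < 0.05, without binding = *indirect*).
Edges failing both are *unconfirmed*. Layer-pair summaries report rounded
percentages (nearest integer, half away from zero), the convention that
reproduces e.g. 4/30 -> 13% and 28/30 -> 93%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "PromoterFragment",
    "VerificationRecord",
    "EnrichmentMeasurement",
    "fragment_promoter",
    "call_regulation",
    "classify_interaction",
    "summarize_verification",
    "chip_fold_enrichment",
    "relative_expression",
]

LAYER_PAIRS = ("1-2", "2-3", "3-4")


@dataclass(frozen=True)
class PromoterFragment:
    """One tile of an upstream region, on the -L..-1 coordinate axis."""

    gene: str
    index: int           # 1..k
    start: int           # negative, 1-based inclusive, start < end
    end: int
    sequence: str


@dataclass(frozen=True)
class VerificationRecord:
    regulator: str
    target: str
    layer_pair: str
    chip_positive_fragments: frozenset[int]
    qpcr_fold: float
    qpcr_p: float

    def __post_init__(self) -> None:
        if self.layer_pair not in LAYER_PAIRS:
            raise ValueError(f"layer_pair must be one of {LAYER_PAIRS}")

    @property
    def classification(self) -> str:
        return classify_interaction(self.chip_positive_fragments,
                                    self.qpcr_fold, self.qpcr_p)


@dataclass(frozen=True)
class EnrichmentMeasurement:
    element_id: str
    fragment_id: str
    chip_plus_quantity: float
    chip_minus_quantity: float


def fragment_promoter(sequence: str, region_length: int, k: int,
                      gene: str = "") -> list[PromoterFragment]:
    """Divide an upstream region into k contiguous equal-length tiles.

    Coordinates are on the upstream axis -region_length..-1 (1-based
    inclusive, position -1 abutting the transcription start). When
    region_length is not divisible by k the leftmost (most upstream)
    fragments absorb the remainder one base each.
    """
    if len(sequence) != region_length:
        raise ValueError(
            f"sequence length {len(sequence)} != region_length {region_length}")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > region_length:
        raise ValueError(f"cannot cut {region_length} bp into {k} fragments")
    base, rem = divmod(region_length, k)
    fragments = []
    pos = 0  # 0-based offset from the -region_length end
    for i in range(k):
        length = base + (1 if i < rem else 0)
        start = -region_length + pos
        fragments.append(PromoterFragment(
            gene=gene, index=i + 1, start=start, end=start + length - 1,
            sequence=sequence[pos:pos + length]))
        pos += length
    return fragments


def call_regulation(fold: float, p: float, min_fold: float = 2.0,
                    p_max: float = 0.05, up_only: bool = False):
    """qPCR regulation call: (regulated, direction).

    Regulated iff the fold change is at least ``min_fold`` in either
    direction (``fold >= min_fold`` or ``fold <= 1/min_fold``; with
    ``up_only`` only the former) and ``p < p_max`` (strict). Direction is
    'up' for fold > 1 else 'down'.
    """
    if fold <= 0:
        raise ValueError("fold change must be positive")
    if min_fold < 1:
        raise ValueError("min_fold must be >= 1")
    passes_fold = fold >= min_fold or (not up_only and fold <= 1.0 / min_fold)
    regulated = bool(passes_fold and p < p_max)
    direction = "up" if fold > 1 else "down"
    return regulated, direction


def classify_interaction(chip_positive_fragments, qpcr_fold: float,
                         qpcr_p: float, min_fold: float = 2.0,
                         p_max: float = 0.05, up_only: bool = False) -> str:
    """direct > indirect > unconfirmed, in that precedence."""
    if chip_positive_fragments:
        return "direct"
    regulated, _ = call_regulation(qpcr_fold, qpcr_p, min_fold=min_fold,
                                   p_max=p_max, up_only=up_only)
    return "indirect" if regulated else "unconfirmed"


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def summarize_verification(records, layer_pair: str | None = None) -> dict:
    """Counts and rounded percentages for one layer pair (or all records)."""
    if layer_pair is not None:
        records = [r for r in records if r.layer_pair == layer_pair]
    records = list(records)
    if not records:
        raise ValueError("no verification records to summarize")
    n = len(records)
    n_direct = sum(1 for r in records if r.classification == "direct")
    n_indirect = sum(1 for r in records if r.classification == "indirect")
    n_unconfirmed = n - n_direct - n_indirect
    return {
        "layer_pair": layer_pair,
        "n": n,
        "n_direct": n_direct,
        "n_indirect": n_indirect,
        "n_unconfirmed": n_unconfirmed,
        "pct_direct": _round_half_away(100.0 * n_direct / n),
        "pct_indirect": _round_half_away(100.0 * n_indirect / n),
        "pct_overall": _round_half_away(100.0 * (n_direct + n_indirect) / n),
    }


def chip_fold_enrichment(m: EnrichmentMeasurement) -> float:
    """ChIP+ abundance relative to the ChIP- (no antibody) baseline of 1."""
    if m.chip_plus_quantity < 0 or m.chip_minus_quantity < 0:
        raise ValueError("abundances must be non-negative")
    if m.chip_minus_quantity == 0:
        raise ZeroDivisionError("ChIP- baseline quantity is zero")
    return m.chip_plus_quantity / m.chip_minus_quantity


def relative_expression(ct_target_treated: float, ct_ref_treated: float,
                        ct_target_control: float, ct_ref_control: float) -> float:
    """Fold change by 2^-ddCt under perfect amplification efficiency."""
    for ct in (ct_target_treated, ct_ref_treated, ct_target_control, ct_ref_control):
        if not math.isfinite(ct):
            raise ValueError("Ct values must be finite")
    ddct = (ct_target_treated - ct_ref_treated) - (ct_target_control - ct_ref_control)
    return 2.0 ** (-ddct)
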