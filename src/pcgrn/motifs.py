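"""Cis-element definitions and promoter scanning.

Three promoter elements bound by the root bZIP regulator are modelled: the
GATA-box (full site ATGATAAGG, matched in full because no deletion series
narrowed it), and two novel elements isolated as GTGGTGG and GGGGATG whose
binding-essential cores are the degenerate 4-mers [C/T]GGT (TGGT-box) and
the invariant GGAT (GGAT-box). Matching is at the core level by default;
``full_site=True`` matches the originally isolated 7/9-mers instead.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

__all__ = [
    "ElementDefinition",
    "MotifHit",
    "registry",
    "scan_sequence",
    "elements_in_fragments",
]

_VALID_BASES = set("ACGTN")


class SequenceFormatError(ValueError):
    """Sequence contains characters outside A/C/G/T/N."""


@dataclass(frozen=True)
class ElementDefinition:
    """A promoter element: full isolated site plus its conserved core."""

    element_id: str
    full_sequence: str
    core: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        if len(self.core) > len(self.full_sequence):
            raise ValueError("core longer than full sequence")
        if any(not pos for pos in self.core):
            raise ValueError("every core position needs a non-empty allowed set")

    def core_length(self) -> int:
        return len(self.core)

    def matches_core(self, window: str) -> bool:
        return len(window) == len(self.core) and all(
            b in allowed for b, allowed in zip(window, self.core))


@dataclass(frozen=True)
class MotifHit:
    """One core occurrence; offset is the 1-based start on the + strand."""

    element_id: str
    seq_id: str
    strand: str
    offset: int
    matched: str


def _exact(seq: str) -> tuple[frozenset[str], ...]:
    return tuple(frozenset(b) for b in seq)


def registry() -> list[ElementDefinition]:
    """The three elements bound by the root TF.

    * GATA-box: exact ATGATAAGG (core = full site).
    * TGGT-box: isolated as GTGGTGG; core [C/T]GGT (only the first base
      tolerates substitution, T -> C).
    * GGAT-box: isolated as GGGGATG; core GGAT with no substitutions.
    """
    return [
        ElementDefinition("GATA-box", "ATGATAAGG", _exact("ATGATAAGG")),
        ElementDefinition("TGGT-box", "GTGGTGG",
                          (frozenset("CT"),) + _exact("GGT")),
        ElementDefinition("GGAT-box", "GGGGATG", _exact("GGAT")),
    ]


def registry_by_id() -> dict[str, ElementDefinition]:
    return {e.element_id: e for e in registry()}


def _check_sequence(seq: str) -> str:
    seq = seq.upper()
    bad = set(seq) - _VALID_BASES
    if bad:
        raise SequenceFormatError(f"illegal characters in sequence: {sorted(bad)}")
    return seq


def _forward_hits(seq: str, element: ElementDefinition, seq_id: str,
                  strand: str, full_site: bool):
    pattern = (_exact(element.full_sequence) if full_site else element.core)
    k = len(pattern)
    n = len(seq)
    for i in range(n - k + 1):
        window = seq[i:i + k]
        if "N" in window:
            continue
        if all(b in allowed for b, allowed in zip(window, pattern)):
            yield i, window


def scan_sequence(seq: str, element: ElementDefinition, strands: str = "both",
                  seq_id: str = "", full_site: bool = False) -> list[MotifHit]:
    """All occurrences of an element's core (all overlaps reported).

    Minus-strand hits are found on the reverse complement and mapped back to
    plus-strand coordinates; ``matched`` always reports the bases as read
    5'->3' on the hit strand. N never matches. Hits are sorted by offset,
    then strand (+ before -).
    """
    if strands not in ("forward", "both"):
        raise ValueError(f"strands must be 'forward' or 'both', got {strands!r}")
    seq = _check_sequence(seq)
    k = len(element.full_sequence) if full_site else element.core_length()
    hits = [MotifHit(element.element_id, seq_id, "+", i + 1, window)
            for i, window in _forward_hits(seq, element, seq_id, "+", full_site)]
    if strands == "both":
        rc = str(Seq(seq).reverse_complement())
        n = len(seq)
        for i, window in _forward_hits(rc, element, seq_id, "-", full_site):
            # rc position i covers plus-strand bases (n - i - k) .. (n - i - 1)
            hits.append(MotifHit(element.element_id, seq_id, "-",
                                 n - i - k + 1, window))
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def elements_in_fragments(fragments, elements=None, strands: str = "both",
                          full_site: bool = False) -> list[dict]:
    """Per-(fragment, element) presence table with p+/p- labels.

    Each row carries the fragment's gene and index, the element, a boolean
    ``present``, the label ``p+``/``p-`` and the hit list (offsets local to
    the fragment sequence). A hit spanning two fragments is by construction
    not reported here; whole-promoter scanning finds those.
    """
    if elements is None:
        elements = registry()
    rows = []
    for frag in fragments:
        for element in elements:
            hits = scan_sequence(frag.sequence, element, strands=strands,
                                 seq_id=f"{frag.gene}:frag{frag.index}",
                                 full_site=full_site)
            rows.append({
                "gene": frag.gene,
                "fragment_index": frag.index,
                "element": element.element_id,
                "present": bool(hits),
                "label": "p+" if hits else "p-",
                "hits": hits,
            })
    return rows
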