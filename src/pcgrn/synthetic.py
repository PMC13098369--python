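"""Planted four-layer networks and the linear-Gaussian cascade simulator.

The generator emulates the study design the pipeline is meant for: a root
TF perturbed across three genotypes (overexpression OE, knockdown RE, wild
type WT) under two conditions (control, drought) with replication. A known
layered topology (root -> layer-2 TFs -> layer-3 TFs -> layer-4 structural
genes) drives a linear-Gaussian cascade on a log expression scale, so every
inference stage downstream has an exactly recoverable ground truth.

Default parameters are calibrated (see docs/methods.md) so that planted
parent-child correlations sit at ~0.9: just above the coexpression gate for
directly linked and sibling genes, while longer-path correlations fall
below it. This is the regime in which partial-correlation mediation is
informative.
"""

from __future__ import annotations

import graphlib
import itertools
from dataclasses import dataclass
from functools import cached_property

import numpy as np
import pandas as pd

from .motifs import registry_by_id, scan_sequence
from .verification import VerificationRecord

__all__ = [
    "PlantedNetwork",
    "SimulationDesign",
    "SampleInfo",
    "ExpressionMatrix",
    "PlantedElement",
    "PromoterSet",
    "generate_grn_topology",
    "simulate_expression",
    "generate_promoters",
    "simulate_verification_table",
]


# --------------------------------------------------------------------------
# domain types

@dataclass(frozen=True)
class PlantedNetwork:
    """Ground-truth four-layer topology with consecutive-layer edges only."""

    root_tf: str
    layer2: tuple[str, ...]
    layer3: tuple[str, ...]
    layer4: tuple[str, ...]
    edges: frozenset[tuple[str, str]]
    seed: int

    def __post_init__(self) -> None:
        genes = [self.root_tf, *self.layer2, *self.layer3, *self.layer4]
        if len(set(genes)) != len(genes):
            raise ValueError("gene ids must be unique across layers")
        layer = self.layer_map()
        for reg, tgt in self.edges:
            if layer[tgt] != layer[reg] + 1:
                raise ValueError(f"edge {reg}->{tgt} skips a layer")
        for gene in itertools.chain(self.layer2, self.layer3, self.layer4):
            if not any(t == gene for _, t in self.edges):
                raise ValueError(f"gene {gene} has no parent")

    def layer_map(self) -> dict[str, int]:
        out = {self.root_tf: 1}
        out.update({g: 2 for g in self.layer2})
        out.update({g: 3 for g in self.layer3})
        out.update({g: 4 for g in self.layer4})
        return out

    @property
    def genes(self) -> list[str]:
        return [self.root_tf, *self.layer2, *self.layer3, *self.layer4]

    @property
    def tfs(self) -> set[str]:
        return {self.root_tf, *self.layer2, *self.layer3}

    def annotation(self) -> dict[str, str]:
        return {g: ("TF" if g in self.tfs else "structural") for g in self.genes}

    def parents(self, gene: str) -> list[str]:
        return sorted(r for r, t in self.edges if t == gene)


@dataclass(frozen=True)
class SimulationDesign:
    """Experimental design and cascade parameters for the simulator.

    ``root_effect`` multiplies the baseline root expression per genotype;
    ``drought_effect`` shifts the root additively under drought. Noise is
    i.i.d. Gaussian per gene and sample on the log scale.
    """

    genotypes: tuple[str, ...] = ("OE", "RE", "WT")
    conditions: tuple[str, ...] = ("control", "drought")
    replicates: int = 10
    root_effect: tuple[tuple[str, float], ...] = (("OE", 4.0), ("WT", 1.0), ("RE", 0.3))
    drought_effect: float = 0.055
    baseline_expression: float = 0.055
    edge_weight_range: tuple[float, float] = (0.9, 1.0)
    weight_signs: str = "positive"   # or "random"
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ValueError("need replicates >= 2")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        eff = dict(self.root_effect)
        if set(self.genotypes) - set(eff):
            raise ValueError("every genotype needs a root_effect multiplier")
        if {"OE", "RE", "WT"} <= set(eff):
            if not (eff["OE"] > eff["WT"] > eff["RE"] > 0):
                raise ValueError("root_effect must order OE > WT > RE > 0")
        if self.weight_signs not in ("positive", "random"):
            raise ValueError("weight_signs must be 'positive' or 'random'")
        lo, hi = self.edge_weight_range
        if not (0 < lo <= hi):
            raise ValueError("edge_weight_range must be 0 < lo <= hi")

    @property
    def effect_map(self) -> dict[str, float]:
        return dict(self.root_effect)

    @property
    def n_samples(self) -> int:
        return len(self.genotypes) * len(self.conditions) * self.replicates


@dataclass(frozen=True)
class SampleInfo:
    sample_id: str
    genotype: str
    condition: str
    replicate: int


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with design labels attached."""

    values: np.ndarray
    genes: list[str]
    samples: list[SampleInfo]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError("values shape does not match genes x samples")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene ids")
        if np.isnan(self.values).any():
            raise ValueError("missing values are not allowed")

    @cached_property
    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def gene_values(self, gene: str) -> np.ndarray:
        return self.values[self.gene_index[gene]]

    def subset_samples(self, genotype=None, condition=None) -> "ExpressionMatrix":
        keep = [i for i, s in enumerate(self.samples)
                if (genotype is None or s.genotype == genotype)
                and (condition is None or s.condition == condition)]
        return ExpressionMatrix(self.values[:, keep], list(self.genes),
                                [self.samples[i] for i in keep])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes,
                            columns=[s.sample_id for s in self.samples])


# --------------------------------------------------------------------------
# topology

def _gene_names(prefix: str, n: int, start: int = 1) -> list[str]:
    width = max(3, len(str(start + n - 1)))
    return [f"{prefix}{i:0{width}d}" for i in range(start, start + n)]


def generate_grn_topology(n2: int, n3: int, n4: int, fan_in_max: int = 1,
                          seed: int = 0) -> PlantedNetwork:
    """Random planted topology: root -> n2 TFs -> n3 TFs -> n4 structural.

    The root connects to every layer-2 TF; each layer-3/4 gene draws
    1..fan_in_max distinct parents uniformly from the previous layer.
    Deterministic for a fixed seed.
    """
    if min(n2, n3, n4) < 1:
        raise ValueError("layer sizes must be >= 1")
    if fan_in_max < 1:
        raise ValueError("fan_in_max must be >= 1")
    rng = np.random.default_rng(seed)
    n_tf = 1 + n2 + n3
    tf_names = _gene_names("TF", n_tf)
    root = tf_names[0]
    layer2 = tuple(tf_names[1:1 + n2])
    layer3 = tuple(tf_names[1 + n2:])
    layer4 = tuple(_gene_names("SG", n4))
    edges: set[tuple[str, str]] = {(root, t) for t in layer2}
    for child_layer, parent_layer in ((layer3, layer2), (layer4, layer3)):
        cap = min(fan_in_max, len(parent_layer))
        for gene in child_layer:
            k = int(rng.integers(1, cap + 1))
            parents = rng.choice(len(parent_layer), size=k, replace=False)
            edges.update((parent_layer[int(p)], gene) for p in np.sort(parents))
    return PlantedNetwork(root_tf=root, layer2=layer2, layer3=layer3,
                          layer4=layer4, edges=frozenset(edges), seed=seed)


# --------------------------------------------------------------------------
# expression

def simulate_expression(net: PlantedNetwork,
                        design: SimulationDesign) -> ExpressionMatrix:
    """Linear-Gaussian cascade over the planted topology.

    Root expression per sample is ``baseline * genotype_multiplier +
    drought_effect * [drought] + noise``; every child is the weighted sum of
    its parents plus fresh Gaussian noise, evaluated in topological order.
    Edge weights are drawn once per edge from ``edge_weight_range``.
    """
    rng = np.random.default_rng(design.seed)
    edges = sorted(net.edges)
    lo, hi = design.edge_weight_range
    weights = dict(zip(edges, rng.uniform(lo, hi, size=len(edges))))
    # multi-parent genes: rescale incoming weights so their sum is itself a
    # draw from edge_weight_range, keeping the transmitted signal magnitude
    # comparable to the single-parent case instead of amplifying with fan-in
    children: dict[str, list[tuple[str, str]]] = {}
    for e in edges:
        children.setdefault(e[1], []).append(e)
    for target in sorted(children):
        incoming = children[target]
        if len(incoming) > 1:
            total = float(rng.uniform(lo, hi))
            s = sum(weights[e] for e in incoming)
            for e in incoming:
                weights[e] *= total / s
    if design.weight_signs == "random":
        signs = rng.choice([-1.0, 1.0], size=len(edges))
        weights = {e: w * s for (e, w), s in zip(weights.items(), signs)}

    ts = graphlib.TopologicalSorter({g: set() for g in net.genes})
    for reg, tgt in edges:
        ts.add(tgt, reg)
    order = list(ts.static_order())  # raises CycleError on a cyclic edge set

    samples = [SampleInfo(f"{g}_{c}_{r}", g, c, r)
               for g in design.genotypes
               for c in design.conditions
               for r in range(1, design.replicates + 1)]
    n = len(samples)
    eff = design.effect_map
    root_mean = np.array([
        design.baseline_expression * eff[s.genotype]
        + (design.drought_effect if s.condition == "drought" else 0.0)
        for s in samples])

    parents_of: dict[str, list[tuple[str, float]]] = {g: [] for g in net.genes}
    for (reg, tgt), w in weights.items():
        parents_of[tgt].append((reg, w))

    values: dict[str, np.ndarray] = {}
    for gene in order:
        noise = rng.normal(0.0, design.noise_sd, size=n)
        if gene == net.root_tf:
            values[gene] = root_mean + noise
        else:
            total = noise.copy()
            for parent, w in parents_of[gene]:
                total += w * values[parent]
            values[gene] = total
    genes = net.genes
    mat = np.vstack([values[g] for g in genes])
    return ExpressionMatrix(values=mat, genes=genes, samples=samples)


# --------------------------------------------------------------------------
# promoters

@dataclass(frozen=True)
class PlantedElement:
    """Ground-truth insertion: full site placed at ``start`` (1-based, +)."""

    gene: str
    element_id: str
    strand: str
    start: int
    inserted: str        # plus-strand bases occupying the span
    core_hits: tuple = ()  # MotifHit tuple on promoter coordinates


@dataclass
class PromoterSet:
    sequences: dict[str, str]
    planted: dict[str, list[PlantedElement]]
    gc: float
    seed: int


def _random_bases(rng, length: int, gc: float) -> list[str]:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return list(rng.choice(list("ACGT"), size=length, p=p))


def _spurious_hits(seq: str, planted_spans: list[tuple[int, int]],
                   elements) -> list:
    """Core hits not fully inside a planted span (promoter coordinates)."""
    bad = []
    for element in elements:
        for hit in scan_sequence(seq, element, strands="both"):
            s0 = hit.offset - 1
            s1 = s0 + element.core_length() - 1
            if not any(a <= s0 and s1 <= b for a, b in planted_spans):
                bad.append((s0, s1))
    return bad


def generate_promoters(gene_ids, length: int = 2000, planted=None,
                       gc: float = 0.4, seed: int = 0) -> PromoterSet:
    """Random upstream sequences with requested elements planted verbatim.

    Each requested element's full isolated site is inserted at a random
    non-overlapping position on a random strand. Background is i.i.d. with
    the given GC fraction; any background window that spuriously spells a
    registry core is re-rolled, so the recorded insertion log is the exact
    ground truth for the scanner.
    """
    planted = dict(planted or {})
    reg = registry_by_id()
    elements = list(reg.values())
    rng = np.random.default_rng(seed)
    sequences: dict[str, str] = {}
    log: dict[str, list[PlantedElement]] = {}
    for gene in gene_ids:
        wanted = [reg[e] for e in planted.get(gene, [])]
        total = sum(len(e.full_sequence) for e in wanted)
        if total > length:
            raise ValueError(
                f"cannot fit {len(wanted)} elements into {length} bp for {gene}")
        # choose non-overlapping spans by rejection
        spans: list[tuple[int, int]] = []
        inserts: list[tuple[int, str, "object"]] = []
        for element in wanted:
            size = len(element.full_sequence)
            for _ in range(10_000):
                start = int(rng.integers(0, length - size + 1))
                if all(start + size <= a or start >= b + 1 for a, b in spans):
                    break
            else:
                raise ValueError(f"could not place elements for {gene}")
            spans.append((start, start + size - 1))
            strand = "+" if rng.random() < 0.5 or size == length else "-"
            inserts.append((start, strand, element))
        seq = _random_bases(rng, length, gc)
        from Bio.Seq import Seq
        records = []
        for start, strand, element in inserts:
            segment = (element.full_sequence if strand == "+"
                       else str(Seq(element.full_sequence).reverse_complement()))
            seq[start:start + len(segment)] = list(segment)
        # purge spurious core occurrences created by the background
        for _ in range(1000):
            s = "".join(seq)
            bad = _spurious_hits(s, spans, elements)
            if not bad:
                break
            protected = {i for a, b in spans for i in range(a, b + 1)}
            for s0, s1 in bad:
                for i in range(s0, s1 + 1):
                    if i not in protected:
                        seq[i] = str(rng.choice(list("ACGT")))
        else:
            raise RuntimeError("failed to purge spurious element occurrences")
        s = "".join(seq)
        for start, strand, element in inserts:
            span = s[start:start + len(element.full_sequence)]
            hits = tuple(
                hit.__class__(hit.element_id, gene, hit.strand,
                              hit.offset + start, hit.matched)
                for hit in scan_sequence(span, element, strands="both"))
            records.append(PlantedElement(gene=gene, element_id=element.element_id,
                                          strand=strand, start=start + 1,
                                          inserted=span, core_hits=hits))
        sequences[gene] = s
        log[gene] = records
    return PromoterSet(sequences=sequences, planted=log, gc=gc, seed=seed)


# --------------------------------------------------------------------------
# verification tables

def simulate_verification_table(net: PlantedNetwork, n_sampled: int,
                                p_direct: float = 0.8,
                                p_indirect: float = 0.1333,
                                seed: int = 0) -> list[VerificationRecord]:
    """Sample edges and assign direct/indirect/unconfirmed outcomes.

    Direct records get a positive ChIP fragment (index 1..4); indirect
    records get a significant qPCR change (fold >= 2 either direction,
    p < 0.05) with negative ChIP; unconfirmed records get neither.
    """
    if not (0 <= p_direct <= 1 and 0 <= p_indirect <= 1):
        raise ValueError("probabilities must lie in [0, 1]")
    if p_direct + p_indirect > 1 + 1e-12:
        raise ValueError("p_direct + p_indirect must be <= 1")
    edges = sorted(net.edges)
    if n_sampled > len(edges):
        raise ValueError("cannot sample more edges than the network has")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(edges), size=n_sampled, replace=False)
    layer = net.layer_map()
    records = []
    for i in np.sort(chosen):
        reg_gene, tgt = edges[int(i)]
        pair = f"{layer[reg_gene]}-{layer[tgt]}"
        u = rng.random()
        if u < p_direct:
            chip = frozenset({int(rng.integers(1, 5))})
            fold = float(rng.uniform(2.0, 8.0))
            p = float(rng.uniform(0.0005, 0.04))
        elif u < p_direct + p_indirect:
            chip = frozenset()
            up = rng.random() < 0.5
            fold = float(rng.uniform(2.0, 6.0)) if up else float(rng.uniform(0.17, 0.5))
            p = float(rng.uniform(0.001, 0.049))
        else:
            chip = frozenset()
            fold = float(rng.uniform(0.6, 1.8))
            p = float(rng.uniform(0.1, 0.9))
        records.append(VerificationRecord(
            regulator=reg_gene, target=tgt, layer_pair=pair,
            chip_positive_fragments=chip, qpcr_fold=fold, qpcr_p=p))
    return records
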