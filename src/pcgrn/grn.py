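"""Mediation scan and hierarchical layer assembly.

Directed TF->gene edges are drawn wherever a TF's conditioning collapses a
coexpressed pair's correlation (|PCC| < pcc_max, strict): the TF is then
credited with both pair members as targets. Edges are assembled into the
four-layer template by breadth-first search from the root TF; edges that do
not fit the template (layer skips, equal-depth TF->TF, backward edges) are
kept aside as orphans, never silently dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .correlation import (CoexpressionPair, CorrelationTriple,
                          correlation_matrix, partial_correlation)

logger = logging.getLogger(__name__)

__all__ = ["MediationEdge", "LayeredNetwork", "mediation_scan",
           "assign_layers", "summarize_network", "recover_metrics"]


@dataclass
class MediationEdge:
    """Directed TF->target edge with the mediated pairs that support it."""

    regulator: str
    target: str
    support: list[tuple[CoexpressionPair, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.regulator == self.target:
            raise ValueError("self-regulation edges are not modelled")

    @property
    def min_pcc(self) -> float:
        if not self.support:
            raise ValueError("edge without support")
        return min(abs(p) for _, p in self.support)

    @property
    def key(self) -> tuple[str, str]:
        return (self.regulator, self.target)


@dataclass
class LayeredNetwork:
    """Genes assigned to layers 1-4 plus retained and orphan edges."""

    root: str
    layers: dict[str, int]
    edges: list[MediationEdge]
    orphan_edges: list[MediationEdge]

    def layer_sizes(self) -> list[int]:
        return [sum(1 for l in self.layers.values() if l == k) for k in (1, 2, 3, 4)]

    def edge_keys(self) -> set[tuple[str, str]]:
        return {e.key for e in self.edges}


def mediation_scan(expr, pairs, tf_candidates, pcc_max: float = 0.3,
                   formula: str = "standard") -> list[MediationEdge]:
    """Emit TF->gene edges for every (pair, TF) with ``|PCC| < pcc_max``.

    Every TF outside the pair is tested against every coexpressed pair;
    passing combinations add both pair members as targets of the TF, with
    support accumulated and deduplicated per (TF, target). Output is sorted
    by (regulator, target).
    """
    pairs = list(pairs)
    tf_candidates = sorted(set(tf_candidates))
    genes = sorted({g for p in pairs for g in p.genes} | set(tf_candidates))
    idx = {g: i for i, g in enumerate(genes)}
    rows = [expr.gene_index[g] for g in genes]
    r = correlation_matrix(expr.values[rows, :])
    edges: dict[tuple[str, str], MediationEdge] = {}
    for pair in pairs:
        ix, iy = idx[pair.gene_x], idx[pair.gene_y]
        for tf in tf_candidates:
            if tf in pair.genes:
                continue
            iz = idx[tf]
            triple = CorrelationTriple(r_xy=float(r[ix, iy]),
                                       r_xz=float(r[ix, iz]),
                                       r_yz=float(r[iy, iz]))
            pcc = partial_correlation(triple, formula=formula)
            if abs(pcc) < pcc_max:
                for target in (pair.gene_x, pair.gene_y):
                    edge = edges.setdefault((tf, target),
                                            MediationEdge(tf, target))
                    edge.support.append((pair, pcc))
    return [edges[k] for k in sorted(edges)]


def assign_layers(edges, root: str, annotation) -> LayeredNetwork:
    """Four-layer template assembly by shallowest-first BFS from the root.

    Layer 2 is the TFs with a retained edge from the root; layer 3 the TFs
    first reached from layer 2; layer 4 the structural genes first reached
    from layer 3. Ties are broken lexicographically. Edges violating the
    consecutive-layer template become orphans. A root absent from the edge
    set yields an empty network with a warning.
    """
    if annotation.get(root) != "TF":
        raise ValueError(f"root {root!r} must be annotated as a TF")
    edges = list(edges)
    out_by_reg: dict[str, list[MediationEdge]] = {}
    for e in edges:
        out_by_reg.setdefault(e.regulator, []).append(e)
    layers = {root: 1}
    if root not in out_by_reg:
        logger.warning("root %s has no outgoing edges; empty network", root)
        return LayeredNetwork(root=root, layers=layers, edges=[],
                              orphan_edges=edges)

    def eligible(gene: str, layer: int) -> bool:
        cls = annotation.get(gene)
        if layer in (2, 3):
            return cls == "TF"
        return cls == "structural"

    frontier = [root]
    for depth in (2, 3, 4):
        reached = sorted({e.target
                          for g in frontier for e in out_by_reg.get(g, [])
                          if e.target not in layers})
        frontier = []
        for gene in reached:
            if eligible(gene, depth):
                layers[gene] = depth
                frontier.append(gene)
    retained, orphans = [], []
    for e in edges:
        lr, lt = layers.get(e.regulator), layers.get(e.target)
        if lr is not None and lt is not None and lt == lr + 1:
            retained.append(e)
        else:
            orphans.append(e)
    if orphans:
        logger.info("%d edges did not fit the layer template and were "
                    "kept as orphans", len(orphans))
    return LayeredNetwork(root=root, layers=layers, edges=retained,
                          orphan_edges=orphans)


def summarize_network(net: LayeredNetwork) -> dict:
    """Per-layer gene counts, per-interlayer edge counts and their total."""
    sizes = net.layer_sizes()
    counts = [0, 0, 0]
    for e in net.edges:
        counts[net.layers[e.regulator] - 1] += 1
    return {"layer_sizes": sizes, "edge_counts": counts, "total": sum(counts)}


def recover_metrics(inferred: LayeredNetwork, truth) -> dict:
    """Edge precision/recall and layer accuracy against a planted truth.

    An empty inferred edge set reports precision 1 by convention (with a
    warning) and recall 0. Layer accuracy is the fraction of truth genes
    assigned their true layer (unassigned genes count as wrong).
    """
    true_edges = set(truth.edges)
    true_layers = truth.layer_map()
    if not set(true_layers) & (set(inferred.layers) | {inferred.root}):
        raise ValueError("inferred and truth gene universes are disjoint")
    found = inferred.edge_keys()
    tp = len(found & true_edges)
    if found:
        precision = tp / len(found)
    else:
        logger.warning("empty inferred edge set; precision reported as 1")
        precision = 1.0
    recall = tp / len(true_edges) if true_edges else 1.0
    correct = sum(1 for g, l in true_layers.items()
                  if inferred.layers.get(g) == l)
    return {"precision": precision, "recall": recall,
            "layer_accuracy": correct / len(true_layers),
            "n_inferred": len(found), "n_true": len(true_edges),
            "n_correct_edges": tp}
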