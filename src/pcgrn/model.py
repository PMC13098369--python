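"""Model/Results interface over the inference pipeline.

:class:`GRNModel` holds the data (expression matrix, TF annotation, root
TF) and thresholds; :meth:`GRNModel.fit` runs coexpression detection, the
partial-correlation mediation scan and layer assembly, returning a
:class:`GRNResults` with the network, per-edge support, a text summary and
(when the model was built from a simulation) recovery diagnostics against
the planted truth.

>>> net = generate_grn_topology(5, 8, 20, seed=42)
>>> model = GRNModel.from_simulation(net, SimulationDesign(seed=42))
>>> res = model.fit()
>>> res.recovery()["precision"]  # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass

from .correlation import coexpressed_pairs
from .grn import (LayeredNetwork, assign_layers, mediation_scan,
                  recover_metrics, summarize_network)
from .io import RunConfig
from .synthetic import (ExpressionMatrix, PlantedNetwork, SimulationDesign,
                        simulate_expression)

__all__ = ["GRNModel", "GRNResults"]


class GRNModel:
    """TF-centered hierarchical GRN inference model.

    Parameters
    ----------
    expr : ExpressionMatrix
        Genes x samples log-scale expression with design labels.
    annotation : dict
        Gene id -> 'TF' or 'structural'.
    root_tf : str
        The top-layer regulator the hierarchy is rooted at.
    config : RunConfig, optional
        Thresholds; defaults follow the standard gates (CC >= 0.8,
        p < 0.001, PCC < 0.3).
    """

    def __init__(self, expr: ExpressionMatrix, annotation: dict[str, str],
                 root_tf: str, config: RunConfig | None = None,
                 truth: PlantedNetwork | None = None):
        if root_tf not in expr.gene_index:
            raise KeyError(f"root TF {root_tf!r} absent from matrix")
        if annotation.get(root_tf) != "TF":
            raise ValueError(f"root TF {root_tf!r} must be annotated as a TF")
        self.expr = expr
        self.annotation = dict(annotation)
        self.root_tf = root_tf
        self.config = config or RunConfig(root_tf=root_tf)
        self.truth = truth

    @classmethod
    def from_simulation(cls, net: PlantedNetwork,
                        design: SimulationDesign | None = None,
                        config: RunConfig | None = None) -> "GRNModel":
        design = design or SimulationDesign()
        expr = simulate_expression(net, design)
        return cls(expr, net.annotation(), net.root_tf, config=config,
                   truth=net)

    @classmethod
    def from_tsv(cls, expression_path, annotation_path, root_tf: str,
                 config: RunConfig | None = None) -> "GRNModel":
        from .io import read_annotation, read_expression
        return cls(read_expression(expression_path),
                   read_annotation(annotation_path), root_tf, config=config)

    @property
    def tf_candidates(self) -> set[str]:
        return {g for g, c in self.annotation.items()
                if c == "TF" and g in self.expr.gene_index}

    def fit(self, candidates=None) -> "GRNResults":
        """Run the full inference: pairs -> mediation -> layers."""
        cfg = self.config
        if candidates is None:
            candidates = [g for g in self.expr.genes if g in self.annotation]
        pairs = coexpressed_pairs(self.expr, candidates, cc_min=cfg.cc_min,
                                  p_max=cfg.cc_p_max)
        if cfg.signed_cc:
            pairs = [p for p in pairs if p.result.r > 0]
        edges = mediation_scan(self.expr, pairs, self.tf_candidates,
                               pcc_max=cfg.pcc_max, formula=cfg.pcc_formula)
        network = assign_layers(edges, self.root_tf, self.annotation)
        return GRNResults(model=self, pairs=pairs, all_edges=edges,
                          network=network)


@dataclass
class GRNResults:
    """Fit result: coexpressed pairs, mediation edges, layered network."""

    model: GRNModel
    pairs: list
    all_edges: list
    network: LayeredNetwork

    @property
    def summary_dict(self) -> dict:
        return summarize_network(self.network)

    def recovery(self, truth: PlantedNetwork | None = None) -> dict:
        truth = truth or self.model.truth
        if truth is None:
            raise ValueError("no planted truth available for recovery metrics")
        return recover_metrics(self.network, truth)

    def summary(self) -> str:
        cfg = self.model.config
        s = self.summary_dict
        lines = [
            "Hierarchical GRN inference results",
            "=" * 50,
            f"Root TF:              {self.model.root_tf}",
            f"Samples:              {self.model.expr.n_samples}",
            f"Genes in matrix:      {len(self.model.expr.genes)}",
            f"Thresholds:           |CC| >= {cfg.cc_min}, p < {cfg.cc_p_max}, "
            f"|PCC| < {cfg.pcc_max}",
            f"Coexpressed pairs:    {len(self.pairs)}",
            f"Mediation edges:      {len(self.all_edges)}",
            "-" * 50,
            f"Layer sizes (1..4):   {s['layer_sizes']}",
            f"Interlayer edges:     {s['edge_counts']}",
            f"Total relationships:  {s['total']}",
            f"Orphan edges:         {len(self.network.orphan_edges)}",
        ]
        if self.model.truth is not None:
            m = self.recovery()
            lines += ["-" * 50,
                      f"Edge precision:       {m['precision']:.3f}",
                      f"Edge recall:          {m['recall']:.3f}",
                      f"Layer accuracy:       {m['layer_accuracy']:.3f}"]
        return "\n".join(lines)

    def to_graph(self):
        """Retained network as a networkx DiGraph (layer as node attribute)."""
        import networkx as nx
        g = nx.DiGraph()
        for gene, layer in self.network.layers.items():
            g.add_node(gene, layer=layer)
        for e in self.network.edges:
            g.add_edge(e.regulator, e.target, min_pcc=e.min_pcc)
        return g

    def plot(self, ax=None):
        """Four-row layered drawing of the retained network."""
        import matplotlib.pyplot as plt
        import networkx as nx
        g = self.to_graph()
        if ax is None:
            _, ax = plt.subplots(figsize=(8, 6))
        pos = nx.multipartite_layout(g, subset_key="layer",
                                     align="horizontal")
        # flip so the root is on top
        pos = {n: (x, -y) for n, (x, y) in pos.items()}
        colors = {1: "#c23b22", 2: "#e8a33d", 3: "#4a7fb5", 4: "#7fae7f"}
        node_colors = [colors[g.nodes[n]["layer"]] for n in g.nodes]
        nx.draw_networkx(g, pos=pos, ax=ax, node_color=node_colors,
                         node_size=220, font_size=6, arrowsize=7)
        ax.set_axis_off()
        return ax
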