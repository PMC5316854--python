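"""Cohort-summary network with visual-encoding rules, exported for Cytoscape.

Encoding (all configurable):

* node fill — blue for predominantly lost genes, red for predominantly
  gained, green when the gene's mutation frequency exceeds the mutation
  cut (green wins over SCNA fills);
* node shade — prevalence of the gene's most frequent SCNA event, in [0,1];
* node outline — bright cyan for mouse dose-sensitivity evidence, light
  cyan for yeast, none otherwise;
* PPI edges — drawn when an endpoint's SCNA prevalence exceeds the edge
  cut (strictly greater than 1/3 by default): blue/red when the altered
  endpoints agree in direction, purple ("antagonistic") when they
  disagree, green when either endpoint passes the mutation cut;
* grey membership edges connect each seed-pathway gene to a pathway hub
  node.

Exports are GraphML or Cytoscape JSON with style categories as plain
node/edge attribute columns; actual visual mapping is left to Cytoscape.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from .defaults import MUTATION_CUT, SCNA_EDGE_CUT
from .io import ConfigurationError, CopyNumberMatrix, MutationFrequencyMap, ValidationError
from .network import PathwayNetwork

__all__ = [
    "NodeStyle",
    "EdgeStyle",
    "CohortSummaryGraph",
    "cohort_summary_graph",
    "export_graph",
    "read_graph",
]

NODE_FILLS = ("loss_blue", "gain_red", "mutated_green")
EDGE_CATEGORIES = ("loss_blue", "gain_red", "antagonistic_purple",
                   "mutation_green", "pathway_membership_grey")
OUTLINES = ("none", "yeast_lightcyan", "mouse_cyan")


@dataclass(frozen=True)
class NodeStyle:
    gene: str
    fill: str
    shade: float          # prevalence of the most frequent SCNA event
    size: float           # emitted as prevalence; pixel mapping is Cytoscape's
    outline: str

    def __post_init__(self) -> None:
        if self.fill not in NODE_FILLS:
            raise ValidationError(f"unknown fill {self.fill!r}")
        if not (0.0 <= self.shade <= 1.0):
            raise ValidationError(f"shade {self.shade} outside [0, 1]")
        if self.outline not in OUTLINES:
            raise ValidationError(f"unknown outline {self.outline!r}")


@dataclass(frozen=True)
class EdgeStyle:
    source: str
    target: str
    category: str

    def __post_init__(self) -> None:
        if self.category not in EDGE_CATEGORIES:
            raise ValidationError(f"unknown edge category {self.category!r}")


@dataclass
class CohortSummaryGraph:
    pathway: str
    nodes: dict[str, NodeStyle]
    edges: list[EdgeStyle] = field(default_factory=list)
    hub: str | None = None    # pathway hub node for grey membership edges

    def __post_init__(self) -> None:
        known = set(self.nodes) | ({self.hub} if self.hub else set())
        for e in self.edges:
            if e.source not in known or e.target not in known:
                raise ValidationError(
                    f"edge ({e.source!r}, {e.target!r}) references an unknown node")


def _canonical_edges(edges: list[EdgeStyle], hub: str | None) -> list[EdgeStyle]:
    """Stable endpoint order (hub first on membership edges) and global sort."""
    out = []
    for e in edges:
        s, t = e.source, e.target
        if hub and t == hub:
            s, t = t, s
        elif (not hub or s != hub) and s > t:
            s, t = t, s
        out.append(EdgeStyle(source=s, target=t, category=e.category))
    out.sort(key=lambda e: (e.category, e.source, e.target))
    return out


def _prevalences(matrix: CopyNumberMatrix, gene: str) -> tuple[float, float]:
    col = matrix.values.loc[gene]
    n = matrix.n_samples
    loss = float((col < 0).sum()) / n
    gain = float((col > 0).sum()) / n
    return loss, gain


def cohort_summary_graph(
    network: PathwayNetwork,
    matrix: CopyNumberMatrix,
    mut: MutationFrequencyMap | None = None,
    scna_edge_cut: float = SCNA_EDGE_CUT,
    mut_cut: float = MUTATION_CUT,
    edge_rule: str = "either",
) -> CohortSummaryGraph:
    """Apply the cohort-level encoding rules to one pathway network.

    ``edge_rule`` decides whether one (``"either"``, default) or both
    (``"both"``) endpoints must exceed ``scna_edge_cut`` for a styled PPI
    edge to be drawn.
    """
    if edge_rule not in ("either", "both"):
        raise ConfigurationError(f"edge_rule must be 'either' or 'both', got {edge_rule!r}")
    mut = mut or MutationFrequencyMap()
    present = set(matrix.genes)
    loss_prev: dict[str, float] = {}
    gain_prev: dict[str, float] = {}
    nodes: dict[str, NodeStyle] = {}
    for gene in network.nodes:
        loss, gain = _prevalences(matrix, gene) if gene in present else (0.0, 0.0)
        loss_prev[gene], gain_prev[gene] = loss, gain
        if mut.get(gene) > mut_cut:
            fill = "mutated_green"
        elif gain > loss:
            fill = "gain_red"
        else:
            fill = "loss_blue"  # ties and unaltered genes default to the loss palette
        shade = max(loss, gain)
        prov = "mouse" if network.gds.get(gene) == 3 else ("yeast" if network.gds.get(gene) == 2 else "none")
        outline = {"mouse": "mouse_cyan", "yeast": "yeast_lightcyan", "none": "none"}[prov]
        nodes[gene] = NodeStyle(gene=gene, fill=fill, shade=shade, size=shade, outline=outline)

    edges: list[EdgeStyle] = []
    for a, b in network.edges:
        alt_a = loss_prev[a] + gain_prev[a]
        alt_b = loss_prev[b] + gain_prev[b]
        over = (alt_a > scna_edge_cut, alt_b > scna_edge_cut)
        keep = any(over) if edge_rule == "either" else all(over)
        mutated = mut.get(a) > mut_cut or mut.get(b) > mut_cut
        if not keep and not mutated:
            continue
        if mutated:
            category = "mutation_green"
        else:
            dirs = []
            for g, passed in zip((a, b), over):
                if passed:
                    dirs.append("loss" if loss_prev[g] >= gain_prev[g] else "gain")
            if len(set(dirs)) > 1:
                category = "antagonistic_purple"
            elif dirs and dirs[0] == "gain":
                category = "gain_red"
            else:
                category = "loss_blue"
        edges.append(EdgeStyle(source=a, target=b, category=category))

    hub = f"pathway:{network.name}"
    for gene in sorted(network.members & set(network.nodes)):
        edges.append(EdgeStyle(source=hub, target=gene, category="pathway_membership_grey"))
    return CohortSummaryGraph(pathway=network.name, nodes=nodes,
                              edges=_canonical_edges(edges, hub), hub=hub)


# ---------------------------------------------------------------------------
# Export / import
# ---------------------------------------------------------------------------


def _to_networkx(graph: CohortSummaryGraph) -> nx.Graph:
    g = nx.Graph(pathway=graph.pathway, hub=graph.hub or "")
    for gene, style in graph.nodes.items():
        g.add_node(gene, node_type="gene", fill=style.fill, shade=float(style.shade),
                   size=float(style.size), outline=style.outline)
    if graph.hub:
        g.add_node(graph.hub, node_type="pathway", fill="", shade=0.0, size=0.0, outline="none")
    for e in graph.edges:
        g.add_edge(e.source, e.target, category=e.category)
    return g


def _from_networkx(g: nx.Graph) -> CohortSummaryGraph:
    nodes: dict[str, NodeStyle] = {}
    hub = g.graph.get("hub") or None
    for n, attrs in g.nodes(data=True):
        if attrs.get("node_type") == "pathway":
            continue
        nodes[n] = NodeStyle(gene=n, fill=attrs["fill"], shade=float(attrs["shade"]),
                             size=float(attrs["size"]), outline=attrs["outline"])
    edges = [EdgeStyle(source=u, target=v, category=d["category"])
             for u, v, d in g.edges(data=True)]
    return CohortSummaryGraph(pathway=g.graph.get("pathway", ""), nodes=nodes,
                              edges=_canonical_edges(edges, hub), hub=hub)


FORMATS = ("graphml", "cytoscape_json")


def export_graph(graph: CohortSummaryGraph, path, format: str = "graphml") -> None:
    """Write the styled graph as GraphML or Cytoscape JSON."""
    if format not in FORMATS:
        raise ConfigurationError(f"unknown format {format!r}; expected one of {FORMATS}")
    g = _to_networkx(graph)
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(g, path)
    else:
        with open(path, "w") as fh:
            json.dump(nx.cytoscape_data(g), fh, indent=1)


def read_graph(path, format: str = "graphml") -> CohortSummaryGraph:
    """Read back a graph written by :func:`export_graph`."""
    if format not in FORMATS:
        raise ConfigurationError(f"unknown format {format!r}; expected one of {FORMATS}")
    path = Path(path)
    if format == "graphml":
        g = nx.read_graphml(path)
        # GraphML may stringify numerics depending on writer defaults
        for _, attrs in g.nodes(data=True):
            attrs["shade"] = float(attrs.get("shade", 0.0))
            attrs["size"] = float(attrs.get("size", 0.0))
    else:
        with open(path) as fh:
            g = nx.cytoscape_graph(json.load(fh))
    return _from_networkx(g)
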