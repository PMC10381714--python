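"""Alignment-graph construction for local network alignment.

A composite node pairs one protein from each input network; candidate
pairs come from a seed map of cross-species similarities (typically
orthologs). Edges between composite nodes are classified by how the two
underlying protein pairs sit topologically in their own networks:

* **match** — direct interaction on both sides (d1 = d2 = 1);
* **mismatch** — direct interaction on one side, a short indirect path
  (length 2..delta) on the other;
* **gap** — direct interaction on one side, the other side farther than
  delta or disconnected.

Each class is further split by node color: **homogeneous** when all four
proteins share one color, **heterogeneous** otherwise. The seven weights
(one per class, plus the cutoff delta) are the scheme's only tunables; the
defaults are delta 2 and weights 1 / 0.9 (match), 0.5 / 0.4 (mismatch),
0.2 / 0.1 (gap), homogeneous first.

Composite nodes sharing a protein in either coordinate never receive an
edge: within-species identity has distance zero, outside every class, and
linking them would manufacture clusters out of one protein's multiple
candidate partners.
"""

from __future__ import annotations

import logging
import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from typing import NamedTuple

import networkx as nx

from .network_io import PPINetwork, SeedPairMap

logger = logging.getLogger(__name__)

TOPO_CLASSES = ("match", "mismatch", "gap")
COLOR_CLASSES = ("homogeneous", "heterogeneous")


class CompositeNode(NamedTuple):
    """A candidate aligned pair: protein *a* of network 1, *b* of network 2."""

    a: str
    b: str

    def __str__(self) -> str:  # export format: a|b
        return f"{self.a}|{self.b}"


@dataclass(frozen=True)
class WeightParams:
    """Cutoff delta plus the seven category weights.

    The conventional ordering hom_match >= het_match >= hom_mismatch >=
    het_mismatch >= hom_gap >= het_gap >= 0 is warned about, not enforced.
    """

    delta: int = 2
    hom_match: float = 1.0
    het_match: float = 0.9
    hom_mismatch: float = 0.5
    het_mismatch: float = 0.4
    hom_gap: float = 0.2
    het_gap: float = 0.1

    def __post_init__(self):
        if self.delta < 1:
            raise ValueError("delta must be >= 1")
        vals = [self.hom_match, self.het_match, self.hom_mismatch,
                self.het_mismatch, self.hom_gap, self.het_gap]
        if any(not math.isfinite(v) for v in vals):
            raise ValueError("all weights must be finite")
        ordered = all(x >= y for x, y in zip(vals, vals[1:])) and vals[-1] >= 0
        if not ordered:
            warnings.warn(
                "weights violate the conventional ordering "
                "hom_match >= het_match >= ... >= het_gap >= 0", stacklevel=2)

    def weight(self, topo: str, color: str) -> float:
        prefix = "hom" if color == "homogeneous" else "het"
        return getattr(self, f"{prefix}_{topo}")

    def as_dict(self) -> dict:
        return {
            "delta": self.delta,
            "hom_match": self.hom_match, "het_match": self.het_match,
            "hom_mismatch": self.hom_mismatch, "het_mismatch": self.het_mismatch,
            "hom_gap": self.hom_gap, "het_gap": self.het_gap,
        }


@dataclass
class AlignmentGraph:
    """Weighted graph over composite nodes; edges carry weight + category."""

    graph: nx.Graph = field(default_factory=nx.Graph)
    params: WeightParams = field(default_factory=WeightParams)

    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def edges(self):
        return self.graph.edges

    def category_counts(self) -> Counter:
        return Counter(d["category"] for _, _, d in self.graph.edges(data=True))

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("node1\tnode2\tweight\tcategory\n")
            for u, v, d in sorted(self.graph.edges(data=True)):
                fh.write(f"{u}\t{v}\t{d['weight']:g}\t{d['category']}\n")


def select_composite_nodes(
    net1: PPINetwork,
    net2: PPINetwork,
    seeds: SeedPairMap,
    strategy: str = "best_match",
) -> list[CompositeNode]:
    """Choose the alignment graph's node set from the seed pairs.

    ``best_match`` keeps, for each protein of either network, the partner(s)
    of maximal similarity (ties keep all tied pairs) and returns the union —
    a many-to-many mapping. ``all_pairs`` keeps every valid seed pair.
    Pairs referencing proteins absent from their network are dropped with a
    warning. Output order is lexicographic by (a, b).
    """
    if strategy not in ("best_match", "all_pairs"):
        raise ValueError(f"unknown strategy {strategy!r}")
    if len(seeds) == 0:
        raise ValueError("empty alignment-graph node set: no seed pairs given")
    valid: list[tuple[str, str, float]] = []
    for a, b, sim in seeds:
        if a not in net1.graph or b not in net2.graph:
            warnings.warn(
                f"seed pair ({a}, {b}) references proteins absent from the networks; dropped",
                stacklevel=2)
            continue
        valid.append((a, b, sim))
    if not valid:
        raise ValueError("empty alignment-graph node set: no seed pair survives validation")

    if strategy == "all_pairs":
        chosen = {(a, b) for a, b, _ in valid}
    else:
        best_a: dict[str, float] = {}
        best_b: dict[str, float] = {}
        for a, b, sim in valid:
            best_a[a] = max(best_a.get(a, -math.inf), sim)
            best_b[b] = max(best_b.get(b, -math.inf), sim)
        chosen = {
            (a, b)
            for a, b, sim in valid
            if sim == best_a[a] or sim == best_b[b]
        }
    return [CompositeNode(a, b) for a, b in sorted(chosen)]


def pair_distance(net: PPINetwork, p: str, q: str) -> float:
    """Unweighted shortest-path length between two distinct proteins.

    Returns ``math.inf`` when the proteins lie in different components.
    """
    if p == q:
        raise ValueError("pair_distance undefined for identical proteins")
    try:
        return float(nx.shortest_path_length(net.graph, p, q))
    except nx.NetworkXNoPath:
        return math.inf


def classify_from_distances(d1: float, d2: float, delta: int) -> str | None:
    """Topological class from the two within-network distances, or None."""
    direct1, direct2 = d1 == 1, d2 == 1
    if direct1 and direct2:
        return "match"
    if direct1 or direct2:
        other = d2 if direct1 else d1
        return "mismatch" if other <= delta else "gap"
    return None


def classify_edge(
    u: CompositeNode,
    v: CompositeNode,
    net1: PPINetwork,
    net2: PPINetwork,
    delta: int,
) -> tuple[str, str] | None:
    """Classify the potential edge between two composite nodes.

    Returns a (topological, color) pair, or None when no edge exists —
    either because neither side has a direct interaction, or because the
    composite nodes share a protein in one coordinate.
    """
    if u == v:
        raise ValueError("cannot classify a self-loop")
    if u.a == v.a or u.b == v.b:
        return None
    topo = classify_from_distances(
        pair_distance(net1, u.a, v.a), pair_distance(net2, u.b, v.b), delta
    )
    if topo is None:
        return None
    colors = {net1.color(u.a), net1.color(v.a), net2.color(u.b), net2.color(v.b)}
    color = "homogeneous" if len(colors) == 1 else "heterogeneous"
    return topo, color


def build_alignment_graph(
    net1: PPINetwork,
    net2: PPINetwork,
    seeds: SeedPairMap,
    params: WeightParams | None = None,
    strategy: str = "best_match",
) -> AlignmentGraph:
    """Construct the full alignment graph.

    Every unordered pair of composite nodes is classified; classified pairs
    get an edge whose weight is the configured value for their category.
    Distances are taken from per-source BFS tables, so construction is
    O(k * (V + E)) for k distinct seed proteins plus O(k^2) classification.
    """
    if net1.number_of_nodes() == 0 or net2.number_of_nodes() == 0:
        raise ValueError("input networks must be non-empty")
    params = params or WeightParams()
    nodes = select_composite_nodes(net1, net2, seeds, strategy)

    # cache single-source BFS from every protein that appears in a composite node
    dist1 = {p: nx.single_source_shortest_path_length(net1.graph, p)
             for p in {n.a for n in nodes}}
    dist2 = {p: nx.single_source_shortest_path_length(net2.graph, p)
             for p in {n.b for n in nodes}}

    ag = AlignmentGraph(params=params)
    for n in nodes:
        ag.graph.add_node(n)
    for u, v in combinations(nodes, 2):
        if u.a == v.a or u.b == v.b:
            continue
        d1 = float(dist1[u.a].get(v.a, math.inf))
        d2 = float(dist2[u.b].get(v.b, math.inf))
        topo = classify_from_distances(d1, d2, params.delta)
        if topo is None:
            continue
        colors = {net1.color(u.a), net1.color(v.a), net2.color(u.b), net2.color(v.b)}
        color = "homogeneous" if len(colors) == 1 else "heterogeneous"
        ag.graph.add_edge(u, v, weight=params.weight(topo, color),
                          category=f"{color}_{topo}")
    logger.info("alignment graph: %d nodes, %d edges, categories %s",
                ag.graph.number_of_nodes(), ag.graph.number_of_edges(),
                dict(ag.category_counts()))
    return ag
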