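"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the library's own code paths: BFS is a
hand-rolled deque walk (the library uses networkx shortest paths), the
MICA oracle enumerates ancestor sets recursively, and the MCL oracle is a
minimal dense implementation written from the algorithm's definition.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np
import pytest

from lnalign.network_io import PPINetwork, SeedPairMap
from lnalign.semantic_similarity import AnnotationCorpus, OntologyStore


# ---------------------------------------------------------------- oracles

def bfs_distance(adj: dict, src, dst) -> float:
    """Plain deque BFS; returns math.inf when unreachable."""
    if src == dst:
        return 0.0
    seen = {src}
    queue = deque([(src, 0)])
    while queue:
        node, d = queue.popleft()
        for nb in adj[node]:
            if nb == dst:
                return float(d + 1)
            if nb not in seen:
                seen.add(nb)
                queue.append((nb, d + 1))
    return math.inf


def adjacency(net: PPINetwork) -> dict:
    adj = {n: set() for n in net.graph.nodes}
    for u, v in net.graph.edges:
        adj[u].add(v)
        adj[v].add(u)
    return adj


def ancestor_set(store: OntologyStore, term: str) -> set:
    """Recursive ancestor enumeration (term included), no networkx."""
    out = {term}
    stack = [term]
    while stack:
        for parent, _ in store.parents(stack.pop()):
            if parent not in out:
                out.add(parent)
                stack.append(parent)
    return out


def brute_force_mica(store: OntologyStore, ic, t1: str, t2: str) -> str:
    common = ancestor_set(store, t1) & ancestor_set(store, t2)
    scored = [(t, ic[t]) for t in common if t in ic]
    best = max(v for _, v in scored)
    return min(t for t, v in scored if v == best)


def reference_mcl(matrix: np.ndarray, inflation: float = 2.0,
                  iterations: int = 200) -> list[set[int]]:
    """Minimal dense MCL written from the definition; no pruning tricks."""
    m = matrix.astype(float)
    m = m / m.sum(axis=0)
    for _ in range(iterations):
        m = m @ m
        m = np.power(m, inflation)
        m = m / m.sum(axis=0)
    clusters = []
    for i in range(m.shape[0]):
        if m[i, i] > 1e-6:
            members = set(np.nonzero(m[i] > 1e-6)[0]) | {i}
            for c in clusters:
                if c & members:
                    c |= members
                    break
            else:
                clusters.append(members)
    return clusters


# ----------------------------------------------------------- net fixtures

def make_network(name: str, edges, colors=None) -> PPINetwork:
    net = PPINetwork(name=name)
    for u, v in edges:
        net.add_edge(u, v)
    for node, color in (colors or {}).items():
        net.add_node(node, color)
    return net


@pytest.fixture
def triangle_pair():
    """Two isomorphic triangles with identity-style seeds."""
    net1 = make_network("t1", [("x", "y"), ("y", "z"), ("z", "x")])
    net2 = make_network("t2", [("u", "v"), ("v", "w"), ("w", "u")])
    seeds = SeedPairMap([("x", "u", 1.0), ("y", "v", 1.0), ("z", "w", 1.0)])
    return net1, net2, seeds


def random_paired_networks(rng, n_max=30, colored=False):
    """A random pair of networks with random cross seeds (oracle tests)."""
    import networkx as nx
    n1 = int(rng.integers(8, n_max + 1))
    n2 = int(rng.integers(8, n_max + 1))
    g1 = nx.gnp_random_graph(n1, float(rng.uniform(0.08, 0.35)),
                             seed=int(rng.integers(2**31)))
    g2 = nx.gnp_random_graph(n2, float(rng.uniform(0.08, 0.35)),
                             seed=int(rng.integers(2**31)))
    net1 = make_network("r1", [(f"a{u}", f"a{v}") for u, v in g1.edges])
    net2 = make_network("r2", [(f"b{u}", f"b{v}") for u, v in g2.edges])
    for g, net, pre in ((g1, net1, "a"), (g2, net2, "b")):
        for n in g.nodes:
            color = f"c{int(rng.integers(0, 2))}" if colored else "c0"
            net.add_node(f"{pre}{n}", color)
    k = int(rng.integers(4, 12))
    pairs = set()
    while len(pairs) < k:
        pairs.add((f"a{int(rng.integers(0, n1))}", f"b{int(rng.integers(0, n2))}"))
    seeds = SeedPairMap([(a, b, float(rng.uniform(0.5, 1.0))) for a, b in sorted(pairs)])
    return net1, net2, seeds


# ------------------------------------------------------ ontology fixtures

LN2, LN4, LN8 = math.log(2), math.log(4), math.log(8)


@pytest.fixture(scope="session")
def eight_gene_ontology():
    """Balanced binary tree of 15 terms; 8 genes, one per leaf.

    IC values are exact: leaves ln 8, their parents ln 4, the two
    branch roots ln 2, the root 0.
    """
    edges = []
    terms = {"T:root": None}
    for name in ("L", "R"):
        edges.append((f"T:{name}", "T:root", "is_a"))
        for i in (0, 1):
            edges.append((f"T:{name}{i}", f"T:{name}", "is_a"))
            for j in (0, 1):
                edges.append((f"T:{name}{i}{j}", f"T:{name}{i}", "is_a"))
    store = OntologyStore(edges, terms=["T:root"])
    leaves = [f"T:{b}{i}{j}" for b in "LR" for i in (0, 1) for j in (0, 1)]
    corpus = AnnotationCorpus({f"g{k}": {leaf} for k, leaf in enumerate(leaves)})
    return store, corpus


@pytest.fixture(scope="session")
def wang_fixture():
    """Five-plus-one-term DAG with one part_of edge for Wang hand-checks.

    r <- x (is_a); x <- y, z (is_a); r <- q (is_a); q <- z (part_of).
    """
    edges = [
        ("x", "r", "is_a"),
        ("y", "x", "is_a"),
        ("z", "x", "is_a"),
        ("q", "r", "is_a"),
        ("z", "q", "part_of"),
    ]
    return OntologyStore(edges)


def random_dag(rng, n_terms=30):
    """Random multi-parent DAG rooted at term 0 plus a random corpus."""
    terms = [f"D:{i:02d}" for i in range(n_terms)]
    edges = []
    for i in range(1, n_terms):
        n_par = 1 + int(rng.random() < 0.3)
        parents = rng.choice(i, size=min(n_par, i), replace=False)
        for p in parents:
            edges.append((terms[i], terms[int(p)], "is_a"))
    store = OntologyStore(edges)
    genes = {}
    for g in range(25):
        k = int(rng.integers(1, 4))
        genes[f"gene{g:02d}"] = {terms[int(t)] for t in rng.choice(n_terms, size=k, replace=False)}
    return store, AnnotationCorpus(genes)
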