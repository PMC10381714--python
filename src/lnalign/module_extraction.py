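"""Markov clustering of the alignment graph and module projection.

MCL simulates random-walk flow on the weighted graph: the column-stochastic
transition matrix is alternately *expanded* (matrix power, letting flow
spread) and *inflated* (entrywise power followed by column renormalization,
sharpening strong currents and starving weak ones) until the flow settles
on attractor rows. Nodes drawn to the same attractor set form one cluster.

The implementation is dense numpy — alignment graphs here have tens to a
few hundred composite nodes, far below the point where a sparse matrix
pays for itself. Self-loops are added before normalization (each node's
maximum incident weight), the standard regularization that removes the
period-2 oscillation of bipartite-ish flow.

Determinism: the iteration is a fixed-point computation on a matrix, so
the resulting partition depends only on the graph, not on the order its
nodes are presented in; cluster read-off resolves overlapping attractor
membership by largest attractor value, then lowest cluster index, and
clusters are canonically ordered (by size descending, then smallest
member) before being returned.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .alignment_graph import AlignmentGraph, CompositeNode

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MCLParams:
    """Markov-clustering controls.

    inflation > 1 sharpens flow (higher => more, smaller clusters);
    expansion is the matrix-power exponent; entries below prune_threshold
    are zeroed each iteration; self_loop_weight None means "each node's
    maximum incident edge weight".
    """

    inflation: float = 2.0
    expansion: int = 2
    prune_threshold: float = 1e-5
    max_iterations: int = 100
    convergence_tol: float = 1e-8
    self_loop_weight: float | None = None

    def __post_init__(self):
        if self.inflation <= 1:
            raise ValueError("inflation must be > 1")
        if self.expansion < 2:
            raise ValueError("expansion must be >= 2")
        if self.prune_threshold < 0 or self.convergence_tol <= 0:
            raise ValueError("prune_threshold >= 0 and convergence_tol > 0 required")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be positive")


@dataclass
class AlignmentModule:
    """One conserved module: a cluster of composite nodes plus projections."""

    index: int
    members: frozenset[CompositeNode]

    def __post_init__(self):
        if not self.members:
            raise ValueError("module members must be non-empty")

    def project(self, species: int) -> list[str]:
        """Distinct protein ids of one species, sorted."""
        if species == 1:
            return sorted({m.a for m in self.members})
        if species == 2:
            return sorted({m.b for m in self.members})
        raise ValueError("species must be 1 or 2")

    @property
    def size(self) -> int:
        """Distinct protein count pooled over both species (namespaced)."""
        return len({(1, m.a) for m in self.members} | {(2, m.b) for m in self.members})

    def pooled_proteins(self) -> list[str]:
        """Distinct protein ids across both species, sorted."""
        return sorted({m.a for m in self.members} | {m.b for m in self.members})


def _normalize_columns(m: np.ndarray) -> np.ndarray:
    sums = m.sum(axis=0)
    sums[sums == 0] = 1.0
    return m / sums


def mcl_iterate(matrix: np.ndarray, params: MCLParams, on_iteration=None) -> np.ndarray:
    """Run the MCL fixed-point loop on a column-stochastic matrix.

    *on_iteration*, if given, is called with the matrix after every
    normalize step (used by stochasticity checks).
    """
    m = _normalize_columns(matrix.astype(float).copy())
    if on_iteration:
        on_iteration(m)
    for iteration in range(params.max_iterations):
        prev = m
        m = np.linalg.matrix_power(m, params.expansion)
        m = np.power(m, params.inflation)
        m[m < params.prune_threshold] = 0.0
        m = _normalize_columns(m)
        if on_iteration:
            on_iteration(m)
        if np.max(np.abs(m - prev)) < params.convergence_tol:
            break
    else:
        warnings.warn(
            f"MCL did not converge within {params.max_iterations} iterations; "
            "clusters read from the final matrix", stacklevel=2)
    return m


def clusters_from_matrix(m: np.ndarray) -> list[set[int]]:
    """Read clusters off a converged MCL matrix (indices into the node order).

    Attractor rows are rows with non-negligible diagonal mass; each
    attractor row's support is one raw cluster. Attractor rows whose
    supports overlap are merged (they form one attractor system). A node
    appearing in several clusters is assigned to the one where its
    attractor value is largest, ties going to the cluster with the
    smallest minimal attractor index.
    """
    n = m.shape[0]
    eps = 1e-7
    attractors = [i for i in range(n) if m[i, i] > eps]
    if not attractors:  # pathological; every node its own cluster
        return [{i} for i in range(n)]

    # merge attractors whose rows overlap: union-find over attractor indices
    parent = {i: i for i in attractors}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    support = {i: set(np.nonzero(m[i] > eps)[0]) for i in attractors}
    for i in attractors:
        for j in attractors:
            if i < j and (support[i] & support[j] or j in support[i] or i in support[j]):
                union(i, j)

    systems: dict[int, set[int]] = {}
    for i in attractors:
        systems.setdefault(find(i), set()).add(i)

    roots = sorted(systems)
    raw: list[set[int]] = []
    for root in roots:
        members: set[int] = set()
        for i in systems[root]:
            members |= support[i] | {i}
        raw.append(members)

    # resolve overlaps: largest attractor mass wins, ties -> lowest cluster index
    assignment: dict[int, int] = {}
    for node in range(n):
        best_ci, best_val = None, -1.0
        for ci, members in enumerate(raw):
            if node in members:
                val = max(m[i, node] for i in systems[roots[ci]])
                if val > best_val + 1e-15:
                    best_ci, best_val = ci, val
        if best_ci is not None:
            assignment[node] = best_ci

    clusters: dict[int, set[int]] = {}
    for node, ci in assignment.items():
        clusters.setdefault(ci, set()).add(node)
    unassigned = set(range(n)) - set(assignment)
    out = [c for _, c in sorted(clusters.items())]
    out.extend({i} for i in sorted(unassigned))
    return out


def mcl_cluster(
    graph: AlignmentGraph, params: MCLParams | None = None, on_iteration=None
) -> list[set[CompositeNode]]:
    """Partition the alignment graph's nodes by Markov clustering.

    Returns disjoint, covering clusters in canonical order (descending
    size, then smallest member).
    """
    params = params or MCLParams()
    nodes = sorted(graph.graph.nodes)
    if not nodes:
        raise ValueError("alignment graph has no nodes")
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    a = np.zeros((n, n))
    for u, v, d in graph.graph.edges(data=True):
        a[idx[u], idx[v]] = a[idx[v], idx[u]] = d["weight"]
    if params.self_loop_weight is None:
        loops = a.max(axis=0)
        loops[loops == 0] = 1.0  # isolated nodes still need a self-loop
    else:
        loops = np.full(n, params.self_loop_weight)
        loops[loops == 0] = 1.0
    np.fill_diagonal(a, loops)

    m = mcl_iterate(a, params, on_iteration=on_iteration)
    raw = clusters_from_matrix(m)
    clusters = [{nodes[i] for i in c} for c in raw]
    clusters.sort(key=lambda c: (-len(c), min(c)))
    logger.info("MCL: %d nodes -> %d clusters", n, len(clusters))
    return clusters


def extract_modules(
    graph: AlignmentGraph,
    params: MCLParams | None = None,
    min_size: int = 2,
) -> list[AlignmentModule]:
    """Cluster the alignment graph and keep clusters of >= min_size nodes.

    Modules are sorted by descending size and indexed from 1.
    """
    clusters = mcl_cluster(graph, params)
    kept = [c for c in clusters if len(c) >= min_size]
    if not kept:
        warnings.warn(f"no cluster reaches min_size={min_size}", stacklevel=2)
        return []
    modules = [AlignmentModule(index=0, members=frozenset(c)) for c in kept]
    modules.sort(key=lambda m: (-m.size, min(m.members)))
    for i, mod in enumerate(modules, start=1):
        mod.index = i
    return modules


def project_module(m: AlignmentModule, species: int) -> list[str]:
    """Distinct, sorted protein ids of one species in the module."""
    return m.project(species)
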