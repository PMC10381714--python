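"""Synthetic paired networks with planted conserved modules, plus a toy
ontology/annotation corpus with controlled functional coherence.

The generator emulates the study design the pipeline targets: two
species-specific interaction networks of modest size (tens of nodes, tens
to hundreds of edges) that share a handful of conserved modules. Each
planted module is a connected, dense subgraph (connected Erdős–Rényi with
edge probability 0.8) built once and mirrored into both networks through
the true ortholog map, so the aligner has a genuine conserved-subnetwork
signal to find. Background edges are uniform random — no attempt is made
at scale-free degree structure — and noise knobs remove/rewire planted
edges or withhold seed pairs.

The toy ontology is a root plus ``n_clades`` disjoint complete binary
subtrees of a given depth. A gene "belongs" to one clade; with
probability ``coherence`` each of its annotations lands on a leaf of its
own clade, otherwise on a uniformly random leaf of another clade. At
coherence 1 same-clade genes are functionally tight and cross-clade genes
unrelated; at coherence 0 the clade label carries no signal.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np

from .network_io import PPINetwork, SeedPairMap
from .semantic_similarity import AnnotationCorpus, OntologyStore

logger = logging.getLogger(__name__)

#: network scales mirroring small disease-neighborhood interactomes
PRESETS = {
    "ad_scale": dict(n1=33, e1=82, n2=41, e2=157, planted_sizes=[11, 7]),
    "pd_scale": dict(n1=51, e1=438, n2=51, e2=651, planted_sizes=[26, 18]),
}


@dataclass
class SyntheticSpec:
    """Parameters of one paired-network draw."""

    n1: int = 33
    e1: int = 82
    n2: int = 41
    e2: int = 157
    planted_sizes: list[int] = field(default_factory=lambda: [11, 7])
    seed_coverage: float = 1.0
    edge_noise: float = 0.0
    decoy_fraction: float = 0.1
    rng_seed: int = 0

    def validate(self) -> None:
        for frac in (self.seed_coverage, self.edge_noise, self.decoy_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if sum(self.planted_sizes) > min(self.n1, self.n2):
            raise ValueError("planted modules do not fit into the smaller network")
        min_planted = sum(s - 1 for s in self.planted_sizes)  # spanning trees
        for n, e in ((self.n1, self.e1), (self.n2, self.e2)):
            if e > n * (n - 1) // 2:
                raise ValueError(f"{e} edges infeasible for {n} nodes")
            if e < min_planted:
                raise ValueError(
                    f"edge budget {e} cannot keep planted modules connected "
                    f"(needs >= {min_planted} edges)")

    @classmethod
    def preset(cls, name: str, **overrides) -> "SyntheticSpec":
        if name not in PRESETS:
            raise KeyError(f"unknown preset {name!r}; have {sorted(PRESETS)}")
        return cls(**{**PRESETS[name], **overrides})


@dataclass
class GroundTruth:
    """What was planted, for recovery checks."""

    modules_species1: list[list[str]] = field(default_factory=list)
    modules_species2: list[list[str]] = field(default_factory=list)
    true_pairs: list[tuple[str, str]] = field(default_factory=list)
    template_edges: list[tuple[str, str]] = field(default_factory=list)  # species-1 naming
    gene_clade: dict[str, int] = field(default_factory=dict)
    clade_leaves: dict[int, list[str]] = field(default_factory=dict)

    def module_protein_set(self, i: int) -> set[tuple[int, str]]:
        """Namespaced protein set of planted module *i* (0-based)."""
        return ({(1, p) for p in self.modules_species1[i]} |
                {(2, p) for p in self.modules_species2[i]})

    def to_json(self, path) -> None:
        payload = {
            "modules_species1": self.modules_species1,
            "modules_species2": self.modules_species2,
            "true_pairs": [list(p) for p in self.true_pairs],
            "template_edges": [list(p) for p in self.template_edges],
            "gene_clade": self.gene_clade,
            "clade_leaves": {str(k): v for k, v in self.clade_leaves.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            modules_species1=d["modules_species1"],
            modules_species2=d["modules_species2"],
            true_pairs=[tuple(p) for p in d["true_pairs"]],
            template_edges=[tuple(p) for p in d.get("template_edges", [])],
            gene_clade=d.get("gene_clade", {}),
            clade_leaves={int(k): v for k, v in d.get("clade_leaves", {}).items()},
        )


def _connected_er_edges(nodes: list[str], p: float, rng) -> list[tuple[str, str]]:
    """Connected Erdős–Rényi edge set: G(n, p) plus a random spanning tree."""
    edges = {tuple(sorted(e)) for e in combinations(nodes, 2) if rng.random() < p}
    order = list(nodes)
    rng.shuffle(order)
    for i in range(1, len(order)):  # random tree guarantees connectivity
        j = int(rng.integers(0, i))
        edges.add(tuple(sorted((order[j], order[i]))))
    return sorted(edges)


def generate_paired_networks(
    spec: SyntheticSpec,
) -> tuple[PPINetwork, PPINetwork, SeedPairMap, GroundTruth]:
    """Draw a paired-network instance with planted conserved modules.

    Planted modules are near-isomorphic across the two networks (identical
    topology before noise, linked by the true pair map); background edges
    are uniform among the remaining vertex pairs up to the exact requested
    edge counts; ``edge_noise`` rewires that fraction of planted edges
    independently per network; seed pairs cover ``seed_coverage`` of
    planted node pairs plus uniformly drawn decoy (false-ortholog) pairs
    among background nodes.
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)

    names1 = [f"s1g{i:03d}" for i in range(spec.n1)]
    names2 = [f"s2g{i:03d}" for i in range(spec.n2)]
    truth = GroundTruth()

    net1, net2 = PPINetwork(name="species1"), PPINetwork(name="species2")
    for p in names1:
        net1.add_node(p)
    for p in names2:
        net2.add_node(p)

    cursor = 0
    planted_edges1: list[tuple[str, str]] = []
    planted_edges2: list[tuple[str, str]] = []
    for size in spec.planted_sizes:
        mod1 = names1[cursor:cursor + size]
        mod2 = names2[cursor:cursor + size]
        cursor += size
        pair_of = dict(zip(mod1, mod2))
        template = _connected_er_edges(mod1, 0.8, rng)
        for u, v in template:
            net1.add_edge(u, v)
            net2.add_edge(pair_of[u], pair_of[v])
            planted_edges1.append((u, v))
            planted_edges2.append((pair_of[u], pair_of[v]))
            truth.template_edges.append((u, v))
        truth.modules_species1.append(list(mod1))
        truth.modules_species2.append(list(mod2))
        truth.true_pairs.extend((a, pair_of[a]) for a in mod1)

    def _fill_background(net: PPINetwork, names: list[str], target_e: int) -> None:
        missing = [e for e in combinations(names, 2) if not net.graph.has_edge(*e)]
        need = target_e - net.number_of_edges()
        if need < 0:
            # dense planted draw overshot the budget; trim random planted edges
            drop_idx = rng.choice(net.number_of_edges(), size=-need, replace=False)
            edges = sorted(net.graph.edges())
            for k in sorted(drop_idx):
                net.graph.remove_edge(*edges[k])
            return
        picks = rng.choice(len(missing), size=need, replace=False)
        for k in sorted(picks):
            net.add_edge(*missing[k])

    _fill_background(net1, names1, spec.e1)
    _fill_background(net2, names2, spec.e2)

    def _rewire(net: PPINetwork, planted: list[tuple[str, str]], names: list[str]) -> None:
        present = [e for e in planted if net.graph.has_edge(*e)]
        n_noise = int(round(spec.edge_noise * len(present)))
        if n_noise == 0:
            return
        victims = rng.choice(len(present), size=n_noise, replace=False)
        for k in sorted(victims):
            net.graph.remove_edge(*present[k])
        missing = [e for e in combinations(names, 2) if not net.graph.has_edge(*e)]
        picks = rng.choice(len(missing), size=n_noise, replace=False)
        for k in sorted(picks):
            net.add_edge(*missing[k])

    _rewire(net1, planted_edges1, names1)
    _rewire(net2, planted_edges2, names2)

    # seeds: covered fraction of true pairs, plus decoys among background nodes
    n_true = len(truth.true_pairs)
    n_cover = int(round(spec.seed_coverage * n_true))
    cover_idx = sorted(rng.choice(n_true, size=n_cover, replace=False))
    pairs = [(truth.true_pairs[i][0], truth.true_pairs[i][1], 1.0) for i in cover_idx]

    bg1 = names1[sum(spec.planted_sizes):]
    bg2 = names2[sum(spec.planted_sizes):]
    n_decoy = int(round(spec.decoy_fraction * n_cover))
    if bg1 and bg2:
        used = set()
        while len(used) < min(n_decoy, len(bg1) * len(bg2)):
            a = bg1[int(rng.integers(0, len(bg1)))]
            b = bg2[int(rng.integers(0, len(bg2)))]
            if (a, b) not in used:
                used.add((a, b))
                pairs.append((a, b, float(rng.uniform(0.3, 0.9))))

    seeds = SeedPairMap(pairs=pairs)
    logger.info("synthetic pair: net1 %d/%d, net2 %d/%d, %d seeds (%d true, %d decoy)",
                net1.number_of_nodes(), net1.number_of_edges(),
                net2.number_of_nodes(), net2.number_of_edges(),
                len(seeds), n_cover, len(pairs) - n_cover)
    return net1, net2, seeds, truth


def generate_toy_ontology(
    n_clades: int,
    depth: int,
    genes_per_clade: int,
    coherence: float,
    rng_seed: int | np.random.Generator = 0,
) -> tuple[OntologyStore, AnnotationCorpus, GroundTruth]:
    """Build the clade ontology and an annotation corpus over toy genes.

    The ontology is a root plus ``n_clades`` complete binary subtrees of
    ``depth`` levels (2^depth - 1 terms each), all ``is_a`` edges. Each of
    the ``genes_per_clade`` genes per clade receives two annotations drawn
    from leaves — its own clade's with probability ``coherence``, another
    clade's otherwise.
    """
    if n_clades < 2 or depth < 2:
        raise ValueError("need n_clades >= 2 and depth >= 2")
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))

    root = "T:R"
    edges: list[tuple[str, str, str]] = []
    clade_leaves: dict[int, list[str]] = {}
    namespace = {root: "biological_process"}
    for c in range(n_clades):
        # complete binary tree: term k has children 2k+1, 2k+2
        n_terms = 2 ** depth - 1
        ids = [f"T:{c}_{k:03d}" for k in range(n_terms)]
        edges.append((ids[0], root, "is_a"))
        for k in range(1, n_terms):
            edges.append((ids[k], ids[(k - 1) // 2], "is_a"))
        first_leaf = 2 ** (depth - 1) - 1
        clade_leaves[c] = ids[first_leaf:]
        namespace.update({t: "biological_process" for t in ids})

    store = OntologyStore(edges, terms=[root], namespace=namespace)
    genes = {f"gene_c{c}_{i}": c for c in range(n_clades) for i in range(genes_per_clade)}
    corpus = annotate_by_clade(store, clade_leaves, genes, coherence, rng)
    truth = GroundTruth(gene_clade=genes, clade_leaves=clade_leaves)
    return store, corpus, truth


def annotate_by_clade(
    store: OntologyStore,
    clade_leaves: dict[int, list[str]],
    gene_clade: dict[str, int],
    coherence: float,
    rng: np.random.Generator,
    annotations_per_gene: int = 2,
) -> AnnotationCorpus:
    """Annotate genes to clade leaves with the given coherence.

    Each annotation lands on a leaf of the gene's own clade with
    probability *coherence*, and on a uniform leaf of the whole ontology
    otherwise — so coherence 0 carries no clade signal at all. A gene
    whose clade is None (background) always draws uniformly.
    """
    all_leaves = sorted(t for leaves in clade_leaves.values() for t in leaves)
    ann: dict[str, set[str]] = {}
    for gene in sorted(gene_clade):
        clade = gene_clade[gene]
        terms: set[str] = set()
        while len(terms) < annotations_per_gene:
            if clade is not None and rng.random() < coherence:
                pool = clade_leaves[clade]
            else:
                pool = all_leaves
            terms.add(pool[int(rng.integers(0, len(pool)))])
        ann[gene] = terms
    return AnnotationCorpus(ann)


def generate_coherence_fixture(
    spec: SyntheticSpec | None = None,
    coherence: float = 0.9,
    depth: int = 3,
    rng_seed: int = 0,
):
    """Paired networks plus an ontology in which planted-module genes are
    functionally coherent and background genes are not.

    Planted module i's genes (both species) are assigned to ontology clade
    i with the requested coherence; background genes draw annotations
    uniformly over all clades. Returns (net1, net2, seeds, store, corpus,
    truth).
    """
    spec = spec or SyntheticSpec(rng_seed=rng_seed)
    spec.rng_seed = rng_seed
    net1, net2, seeds, truth = generate_paired_networks(spec)
    rng = np.random.default_rng(rng_seed + 104729)

    n_clades = max(2, len(spec.planted_sizes))
    root = "T:R"
    edges: list[tuple[str, str, str]] = []
    clade_leaves: dict[int, list[str]] = {}
    namespace = {root: "biological_process"}
    for c in range(n_clades):
        n_terms = 2 ** depth - 1
        ids = [f"T:{c}_{k:03d}" for k in range(n_terms)]
        edges.append((ids[0], root, "is_a"))
        for k in range(1, n_terms):
            edges.append((ids[k], ids[(k - 1) // 2], "is_a"))
        clade_leaves[c] = ids[2 ** (depth - 1) - 1:]
        namespace.update({t: "biological_process" for t in ids})
    store = OntologyStore(edges, terms=[root], namespace=namespace)

    gene_clade: dict[str, int | None] = {}
    for i in range(len(spec.planted_sizes)):
        for p in truth.modules_species1[i] + truth.modules_species2[i]:
            gene_clade[p] = i
    for net in (net1, net2):
        for p in net.graph.nodes:
            gene_clade.setdefault(p, None)

    corpus = annotate_by_clade(store, clade_leaves, gene_clade, coherence, rng)
    truth.gene_clade = {g: c for g, c in gene_clade.items() if c is not None}
    truth.clade_leaves = clade_leaves
    return net1, net2, seeds, store, corpus, truth


def write_fixture(outdir, net1, net2, seeds, truth,
                  store=None, corpus=None) -> dict[str, Path]:
    """Emit a fixture directory in the formats the pipeline consumes."""
    from .network_io import write_network, write_seed_pairs
    from .semantic_similarity import write_gaf, write_obo

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "net1": outdir / "net1.tsv",
        "net2": outdir / "net2.tsv",
        "seeds": outdir / "seeds.tsv",
        "truth": outdir / "ground_truth.json",
    }
    write_network(net1, paths["net1"])
    write_network(net2, paths["net2"])
    write_seed_pairs(seeds, paths["seeds"])
    truth.to_json(paths["truth"])
    if store is not None:
        paths["obo"] = outdir / "ontology.obo"
        write_obo(store, paths["obo"])
    if corpus is not None:
        paths["gaf"] = outdir / "annotations.gaf"
        write_gaf(corpus, paths["gaf"])
    return paths
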