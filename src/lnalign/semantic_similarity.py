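"""Information-content and hybrid semantic-similarity measures over GO-style
ontologies, aggregated to gene pairs by best-match averaging.

The ontology is a DAG of terms with typed child->parent edges (``is_a``,
``part_of``). A term's information content is IC(t) = -ln p(t), where p(t)
is the fraction of annotated genes carrying t or any of t's descendants
(annotations propagate to ancestors before frequencies are taken); rarer
terms are more informative, and a root covering the whole corpus has IC 0.

Term-level measures:

* Resnik: IC of the most informative common ancestor (MICA).
* Lin: 2 IC(MICA) / (IC(t1) + IC(t2)) — identity scores 1.
  (``lin_paper_literal=True`` drops the factor 2, under which identity
  scores 1/2; provided for comparison with sources that print the formula
  that way.)
* Jiang-Conrath: 1 - (IC(t1) + IC(t2) - 2 IC(MICA)); the raw value is
  unbounded below in nats, so reported values are clamped to [0, 1] while
  the raw value remains available.
* Wang: graph-based S-value method. Within a term's ancestor DAG,
  S(t) = 1 at the term itself and S(u) = max over children c of
  w_edge * S(c), with edge weights 0.8 (is_a) and 0.6 (part_of);
  similarity is the S-value overlap of the two ancestor DAGs.

Gene-level scores are best-match averages (BMA) over the term-pair matrix,
and a module's score is the mean pairwise BMA over its pooled annotated
proteins. Scores depend only on the shared ontology, never on which
species a gene comes from, which is what makes cross-species module
scoring meaningful.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

EDGE_TYPES = ("is_a", "part_of")
DEFAULT_WANG_WEIGHTS = {"is_a": 0.8, "part_of": 0.6}


class OntologyStore:
    """Validated DAG of terms with typed child->parent edges.

    Parameters
    ----------
    edges:
        iterable of (child, parent, relation) with relation in
        {"is_a", "part_of"}.
    terms:
        optional explicit term set (covers isolated roots).
    namespace:
        optional term -> namespace label mapping.
    """

    def __init__(self, edges, terms=None, namespace=None):
        self._dag = nx.DiGraph()  # edges point child -> parent
        for t in terms or ():
            self._dag.add_node(t)
        for child, parent, rel in edges:
            if rel not in EDGE_TYPES:
                raise ValueError(f"edge type {rel!r} not in {EDGE_TYPES}")
            self._dag.add_edge(child, parent, relation=rel)
        if not nx.is_directed_acyclic_graph(self._dag):
            cycle = nx.find_cycle(self._dag)
            raise ValueError(f"ontology contains a cycle: {cycle}")
        self.namespace = dict(namespace or {})

    @property
    def terms(self) -> set[str]:
        return set(self._dag.nodes)

    def __contains__(self, term: str) -> bool:
        return term in self._dag

    def __len__(self) -> int:
        return self._dag.number_of_nodes()

    @property
    def roots(self) -> set[str]:
        return {t for t in self._dag if self._dag.out_degree(t) == 0}

    def parents(self, term: str):
        """(parent, relation) pairs of a term."""
        return [(p, self._dag.edges[term, p]["relation"]) for p in self._dag.successors(term)]

    def children(self, term: str):
        return list(self._dag.predecessors(term))

    def ancestors(self, term: str) -> set[str]:
        """All ancestors of a term, including the term itself."""
        if term not in self._dag:
            raise KeyError(term)
        return nx.descendants(self._dag, term) | {term}

    def descendants(self, term: str) -> set[str]:
        """All descendants of a term, including the term itself."""
        if term not in self._dag:
            raise KeyError(term)
        return nx.ancestors(self._dag, term) | {term}

    def edge_list(self):
        return [(c, p, d["relation"]) for c, p, d in self._dag.edges(data=True)]


@dataclass
class AnnotationCorpus:
    """Direct gene -> term annotations."""

    annotations: dict[str, set[str]] = field(default_factory=dict)

    def genes(self) -> list[str]:
        return sorted(self.annotations)

    def terms_for(self, gene: str) -> set[str]:
        return self.annotations.get(gene, set())

    def is_annotated(self, gene: str) -> bool:
        return bool(self.annotations.get(gene))

    def __len__(self) -> int:
        return len(self.annotations)


def load_ontology(path) -> OntologyStore:
    """Load an OBO 1.2/1.4 ontology into an OntologyStore.

    Obsolete terms are skipped; ``alt_id``s are recorded on the store as
    ``store.alt_ids`` mapping alternative -> canonical id. Only ``is_a``
    and ``part_of`` edges are retained.
    """
    graph = obonet.read_obo(Path(path))  # skips obsolete stanzas
    edges = []
    for child, parent, key in graph.edges(keys=True):
        if key in EDGE_TYPES:
            edges.append((child, parent, key))
    namespace = {t: d.get("namespace", "") for t, d in graph.nodes(data=True)}
    store = OntologyStore(edges, terms=graph.nodes, namespace=namespace)
    alt: dict[str, str] = {}
    for t, d in graph.nodes(data=True):
        for a in d.get("alt_id", []):
            alt[a] = t
    store.alt_ids = alt
    # a parent referenced by an is_a/relationship line but never defined by a
    # stanza shows up as a node with no 'name' attribute
    dangling = [t for t, d in graph.nodes(data=True) if "name" not in d]
    if dangling:
        raise ValueError(f"dangling parent references: {sorted(dangling)[:3]}")
    return store


def write_obo(store: OntologyStore, path, ontology_name: str = "toy") -> None:
    """Serialize a store to minimal OBO 1.2."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n")
        fh.write(f"ontology: {ontology_name}\n\n")
        for term in sorted(store.terms):
            fh.write("[Term]\n")
            fh.write(f"id: {term}\n")
            fh.write(f"name: {term}\n")
            ns = store.namespace.get(term)
            if ns:
                fh.write(f"namespace: {ns}\n")
            for parent, rel in sorted(store.parents(term)):
                if rel == "is_a":
                    fh.write(f"is_a: {parent}\n")
                else:
                    fh.write(f"relationship: part_of {parent}\n")
            fh.write("\n")


def load_annotations(path, store: OntologyStore | None = None,
                     namespace: str | None = None,
                     evidence_exclude: set[str] | None = None) -> AnnotationCorpus:
    """Read gene annotations from GAF 2.x or a two-column TSV.

    GAF rows use columns 2 (gene symbol), 5 (term), 7 (evidence code) and
    9 (aspect); by default no evidence filtering is applied. Annotations
    to terms missing from *store* are dropped with a warning; alt_ids are
    mapped to canonical ids when the store knows them.
    """
    path = Path(path)
    ann: dict[str, set[str]] = {}
    dropped = 0
    with open(path) as fh:
        for raw in fh:
            if not raw.strip() or raw.startswith("!") or raw.startswith("#"):
                continue
            fields = raw.rstrip("\n").split("\t")
            if len(fields) >= 15:  # GAF
                gene, term, evidence = fields[2], fields[4], fields[6]
                if evidence_exclude and evidence in evidence_exclude:
                    continue
            elif len(fields) >= 2:
                gene, term = fields[0], fields[1]
            else:
                raise ValueError(f"{path}: annotation line has fewer than 2 columns: {raw!r}")
            if store is not None:
                term = getattr(store, "alt_ids", {}).get(term, term)
                if term not in store:
                    dropped += 1
                    continue
                if namespace and store.namespace.get(term) not in (namespace, "", None):
                    continue
            ann.setdefault(gene, set()).add(term)
    if dropped:
        warnings.warn(f"{path}: {dropped} annotations to unknown terms dropped", stacklevel=2)
    return AnnotationCorpus(ann)


def write_gaf(corpus: AnnotationCorpus, path, taxon: str = "taxon:0000",
              aspect: str = "P") -> None:
    """Serialize a corpus as minimal GAF 2.2."""
    with open(path, "w") as fh:
        fh.write("!gaf-version: 2.2\n")
        for gene in corpus.genes():
            for term in sorted(corpus.terms_for(gene)):
                fields = ["DB", gene, gene, "", term, "REF:0", "IEA", "",
                          aspect, gene, "", "protein", taxon, "20230101", "DB", "", ""]
                fh.write("\t".join(fields) + "\n")


class ICTable:
    """Per-term information content: IC(t) = -ln(freq(t) / total genes)."""

    def __init__(self, ic: dict[str, float], log_base: float = math.e):
        self._ic = ic
        self.log_base = log_base

    def __getitem__(self, term: str) -> float:
        return self._ic[term]

    def __contains__(self, term: str) -> bool:
        return term in self._ic

    def get(self, term: str, default=None):
        return self._ic.get(term, default)

    def items(self):
        return self._ic.items()

    def max_ic(self) -> float:
        return max(self._ic.values(), default=0.0)


def compute_ic(store: OntologyStore, corpus: AnnotationCorpus,
               log_base: float = math.e) -> ICTable:
    """Annotation frequencies (propagated to ancestors) turned into IC.

    Terms annotating no gene even after propagation are absent from the
    table (undefined IC, excluded from MICA search).
    """
    if len(corpus) == 0:
        raise ValueError("annotation corpus is empty")
    counts: dict[str, int] = {}
    total = 0
    for gene in corpus.genes():
        terms = {t for t in corpus.terms_for(gene) if t in store}
        unknown = corpus.terms_for(gene) - terms
        if unknown:
            warnings.warn(f"gene {gene}: annotations to unknown terms {sorted(unknown)[:3]} dropped",
                          stacklevel=2)
        if not terms:
            continue
        total += 1
        covered: set[str] = set()
        for t in terms:
            covered |= store.ancestors(t)
        for t in covered:
            counts[t] = counts.get(t, 0) + 1
    if total == 0:
        raise ValueError("no gene carries a known annotation")
    log = math.log if log_base == math.e else (lambda x: math.log(x, log_base))
    return ICTable({t: -log(c / total) for t, c in counts.items()}, log_base=log_base)


def mica(store: OntologyStore, ic: ICTable, t1: str, t2: str) -> str:
    """Most informative common ancestor (a term is its own ancestor).

    Ties by IC are broken toward the lexicographically smallest term id.
    Raises when the terms share no ancestor with defined IC.
    """
    common = store.ancestors(t1) & store.ancestors(t2)
    scored = [(t, ic[t]) for t in common if t in ic]
    if not scored:
        raise ValueError(f"no common ancestor with defined IC for {t1!r}, {t2!r}")
    best_ic = max(v for _, v in scored)
    return min(t for t, v in scored if v == best_ic)


def sim_resnik(store: OntologyStore, ic: ICTable, t1: str, t2: str) -> float:
    """Resnik similarity: IC of the MICA."""
    return ic[mica(store, ic, t1, t2)]


def sim_lin(store: OntologyStore, ic: ICTable, t1: str, t2: str,
            lin_paper_literal: bool = False) -> float:
    """Lin similarity, 2 IC(MICA) / (IC(t1) + IC(t2)), in [0, 1].

    Two roots (both IC 0) score 0 by convention. With
    ``lin_paper_literal`` the factor 2 is dropped.
    """
    denom = ic[t1] + ic[t2]
    if denom == 0:
        return 0.0
    factor = 1.0 if lin_paper_literal else 2.0
    return factor * sim_resnik(store, ic, t1, t2) / denom


def sim_jiang(store: OntologyStore, ic: ICTable, t1: str, t2: str,
              clamp: bool = True) -> float:
    """Jiang-Conrath similarity 1 - (IC1 + IC2 - 2 IC(MICA)).

    The raw value is 1 minus an IC distance in nats and is unbounded
    below; ``clamp`` (the default, used in reports) truncates to [0, 1].
    """
    raw = 1.0 - (ic[t1] + ic[t2] - 2.0 * sim_resnik(store, ic, t1, t2))
    return min(1.0, max(0.0, raw)) if clamp else raw


def _wang_svalues(store: OntologyStore, term: str, weights: dict[str, float]) -> dict[str, float]:
    """S-value table over a term's ancestor DAG (semantic contributions)."""
    anc = store.ancestors(term)
    order = [t for t in nx.topological_sort(store._dag.subgraph(anc))]
    s = {term: 1.0}
    for t in order:  # children before parents: child->parent edges
        if t == term:
            continue
        best = 0.0
        for c in store.children(t):
            if c in s:
                rel = store._dag.edges[c, t]["relation"]
                best = max(best, weights[rel] * s[c])
        if best > 0:
            s[t] = best
    return s


def sim_wang(store: OntologyStore, t1: str, t2: str,
             w_is_a: float = 0.8, w_part_of: float = 0.6) -> float:
    """Wang's graph-based similarity from S-value overlap, in [0, 1]."""
    if not (0 < w_is_a < 1 and 0 < w_part_of < 1):
        raise ValueError("Wang edge weights must lie in (0, 1)")
    weights = {"is_a": w_is_a, "part_of": w_part_of}
    s1 = _wang_svalues(store, t1, weights)
    s2 = _wang_svalues(store, t2, weights)
    shared = set(s1) & set(s2)
    if not shared:
        return 0.0
    return sum(s1[t] + s2[t] for t in shared) / (sum(s1.values()) + sum(s2.values()))


class SimilarityScorer:
    """Caches term- and gene-level similarity computations for one corpus.

    ``measure`` is one of ``resnik_bma``, ``lin``, ``jiang``, ``wang``
    (gene-level scores always aggregate term pairs by best-match average).
    """

    MEASURES = ("resnik_bma", "lin", "jiang", "wang")

    def __init__(self, store: OntologyStore, corpus: AnnotationCorpus,
                 ic: ICTable | None = None, lin_paper_literal: bool = False,
                 w_is_a: float = 0.8, w_part_of: float = 0.6):
        self.store = store
        self.corpus = corpus
        self.ic = ic if ic is not None else compute_ic(store, corpus)
        self.lin_paper_literal = lin_paper_literal
        self.wang_weights = (w_is_a, w_part_of)
        self._term_cache: dict[tuple[str, str, str], float] = {}
        self._gene_cache: dict[tuple[str, str, str], float] = {}

    def term_sim(self, t1: str, t2: str, measure: str) -> float:
        if measure not in self.MEASURES:
            raise ValueError(f"unknown measure {measure!r}")
        key = (min(t1, t2), max(t1, t2), measure)
        if key not in self._term_cache:
            if measure == "resnik_bma":
                val = sim_resnik(self.store, self.ic, t1, t2)
            elif measure == "lin":
                val = sim_lin(self.store, self.ic, t1, t2, self.lin_paper_literal)
            elif measure == "jiang":
                val = sim_jiang(self.store, self.ic, t1, t2)
            else:
                val = sim_wang(self.store, t1, t2, *self.wang_weights)
            self._term_cache[key] = val
        return self._term_cache[key]

    def gene_similarity_bma(self, g1: str, g2: str, measure: str) -> float:
        """Best-match average of the term-pair similarity matrix.

        BMA = (mean of row maxima + mean of column maxima) / 2; symmetric
        by construction. Raises on unannotated genes.
        """
        key = (min(g1, g2), max(g1, g2), measure)
        if key in self._gene_cache:
            return self._gene_cache[key]
        terms1 = sorted(t for t in self.corpus.terms_for(g1) if t in self.store)
        terms2 = sorted(t for t in self.corpus.terms_for(g2) if t in self.store)
        if not terms1 or not terms2:
            raise ValueError(f"gene pair ({g1}, {g2}): both genes must be annotated")
        matrix = [[self.term_sim(a, b, measure) for b in terms2] for a in terms1]
        row_max = [max(row) for row in matrix]
        col_max = [max(matrix[i][j] for i in range(len(terms1))) for j in range(len(terms2))]
        val = 0.5 * (sum(row_max) / len(row_max) + sum(col_max) / len(col_max))
        self._gene_cache[key] = val
        return val

    def module_score(self, proteins, measure: str) -> float | None:
        """Mean pairwise BMA over the annotated proteins of a module.

        *proteins* is either an AlignmentModule (pooled over both species)
        or an iterable of gene ids. Returns None (with a warning) when
        fewer than 2 proteins are annotated.
        """
        if hasattr(proteins, "pooled_proteins"):
            proteins = proteins.pooled_proteins()
        annotated = [p for p in proteins if self.corpus.is_annotated(p)]
        if len(annotated) < 2:
            warnings.warn(
                f"module has {len(annotated)} annotated protein(s); score undefined",
                stacklevel=2)
            return None
        total, n = 0.0, 0
        for i in range(len(annotated)):
            for j in range(i + 1, len(annotated)):
                total += self.gene_similarity_bma(annotated[i], annotated[j], measure)
                n += 1
        return total / n


def gene_similarity_bma(g1, g2, store, corpus, measure, ic=None, **kw) -> float:
    """Functional convenience wrapper over :class:`SimilarityScorer`."""
    return SimilarityScorer(store, corpus, ic=ic, **kw).gene_similarity_bma(g1, g2, measure)


def module_score(module, store, corpus, measure, ic=None, **kw):
    """Functional convenience wrapper over :class:`SimilarityScorer`."""
    return SimilarityScorer(store, corpus, ic=ic, **kw).module_score(module, measure)
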