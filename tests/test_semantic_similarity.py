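"""IC, MICA and the four similarity measures against hand-computed values.

The eight-gene fixture is a balanced binary tree whose IC values are exact
logs: leaves ln 8, leaf-parents ln 4, branch roots ln 2, root 0 — every
asserted number below follows by hand from those.
"""

import math

import numpy as np
import pytest

from conftest import LN2, LN4, LN8, brute_force_mica, random_dag
from lnalign.semantic_similarity import (AnnotationCorpus, OntologyStore,
                                         SimilarityScorer, compute_ic,
                                         load_annotations, load_ontology, mica,
                                         sim_jiang, sim_lin, sim_resnik,
                                         sim_wang, write_gaf, write_obo)

TOL = 1e-9


class TestOntologyLoad:
    def test_toy_obo_counts(self, tmp_path):
        text = """format-version: 1.2

[Term]
id: T:1
name: root

[Term]
id: T:2
name: child a
is_a: T:1

[Term]
id: T:3
name: child b
is_a: T:1

[Term]
id: T:4
name: grandchild a
is_a: T:2

[Term]
id: T:5
name: grandchild b
is_a: T:2
alt_id: T:9

[Term]
id: T:6
name: gone
is_obsolete: true
"""
        p = tmp_path / "toy.obo"
        p.write_text(text)
        store = load_ontology(p)
        assert len(store) == 5            # obsolete term excluded
        assert len(store.edge_list()) == 4
        assert store.alt_ids == {"T:9": "T:5"}
        # stanza-count oracle: non-obsolete [Term] stanzas
        stanzas = text.count("[Term]") - text.count("is_obsolete: true")
        assert len(store) == stanzas

    def test_cycle_detected(self):
        with pytest.raises(ValueError, match="cycle"):
            OntologyStore([("a", "b", "is_a"), ("b", "a", "is_a")])

    def test_dangling_parent(self, tmp_path):
        p = tmp_path / "dangling.obo"
        p.write_text("format-version: 1.2\n\n[Term]\nid: T:1\nname: t\nis_a: T:404\n")
        with pytest.raises(ValueError, match="dangling"):
            load_ontology(p)

    def test_obo_round_trip(self, eight_gene_ontology, tmp_path):
        store, _ = eight_gene_ontology
        p = tmp_path / "rt.obo"
        write_obo(store, p)
        again = load_ontology(p)
        assert again.terms == store.terms
        assert set(again.edge_list()) == set(store.edge_list())


class TestInformationContent:
    def test_exact_values(self, eight_gene_ontology):
        store, corpus = eight_gene_ontology
        ic = compute_ic(store, corpus)
        assert ic["T:root"] == pytest.approx(0.0, abs=TOL)
        assert ic["T:L00"] == pytest.approx(LN8, abs=TOL)   # 1 of 8 genes
        assert ic["T:L0"] == pytest.approx(LN4, abs=TOL)    # 2 of 8
        assert ic["T:L"] == pytest.approx(LN2, abs=TOL)     # 4 of 8

    def test_child_ic_at_least_parent(self, eight_gene_ontology):
        store, corpus = eight_gene_ontology
        ic = compute_ic(store, corpus)
        for child, parent, _ in store.edge_list():
            assert ic[child] >= ic[parent] - TOL

    def test_unknown_term_dropped_with_warning(self, eight_gene_ontology):
        store, _ = eight_gene_ontology
        corpus = AnnotationCorpus({"g0": {"T:L00", "NOPE"}})
        with pytest.warns(UserWarning, match="unknown"):
            ic = compute_ic(store, corpus)
        assert "NOPE" not in ic

    def test_empty_corpus_errors(self, eight_gene_ontology):
        store, _ = eight_gene_ontology
        with pytest.raises(ValueError):
            compute_ic(store, AnnotationCorpus({}))


class TestMica:
    def test_self_and_siblings(self, eight_gene_ontology):
        store, corpus = eight_gene_ontology
        ic = compute_ic(store, corpus)
        assert mica(store, ic, "T:L00", "T:L00") == "T:L00"
        assert mica(store, ic, "T:L00", "T:L01") == "T:L0"

    def test_matches_brute_force_on_random_dag(self):
        rng = np.random.default_rng(13)
        store, corpus = random_dag(rng)
        ic = compute_ic(store, corpus)
        terms = sorted(t for t in store.terms if t in ic)
        pairs = [(terms[int(i)], terms[int(j)])
                 for i, j in rng.integers(0, len(terms), size=(50, 2))]
        for t1, t2 in pairs:
            assert mica(store, ic, t1, t2) == brute_force_mica(store, ic, t1, t2)


class TestMeasures:
    @pytest.fixture(autouse=True)
    def _setup(self, eight_gene_ontology):
        self.store, self.corpus = eight_gene_ontology
        self.ic = compute_ic(self.store, self.corpus)

    def test_resnik(self):
        assert sim_resnik(self.store, self.ic, "T:L00", "T:R00") == pytest.approx(0.0, abs=TOL)
        assert sim_resnik(self.store, self.ic, "T:L00", "T:L00") == pytest.approx(LN8, abs=TOL)
        assert sim_resnik(self.store, self.ic, "T:L00", "T:L01") == pytest.approx(LN4, abs=TOL)
        assert sim_resnik(self.store, self.ic, "T:L00", "T:L10") == pytest.approx(LN2, abs=TOL)

    def test_lin(self):
        assert sim_lin(self.store, self.ic, "T:L00", "T:L00") == pytest.approx(1.0, abs=TOL)
        assert sim_lin(self.store, self.ic, "T:L00", "T:R00") == pytest.approx(0.0, abs=TOL)
        # siblings: 2 ln4 / (2 ln8) = 2/3
        assert sim_lin(self.store, self.ic, "T:L00", "T:L01") == pytest.approx(2 / 3, abs=TOL)
        # printed-form variant halves the identity value
        assert sim_lin(self.store, self.ic, "T:L00", "T:L00",
                       lin_paper_literal=True) == pytest.approx(0.5, abs=TOL)

    def test_lin_two_roots_convention(self):
        store = OntologyStore([("a", "r", "is_a"), ("b", "r", "is_a")])
        corpus = AnnotationCorpus({"g1": {"a"}, "g2": {"b"}, "g3": {"r"}})
        ic = compute_ic(store, corpus)
        assert sim_lin(store, ic, "r", "r") == 0.0

    def test_jiang(self):
        assert sim_jiang(self.store, self.ic, "T:L00", "T:L00") == pytest.approx(1.0, abs=TOL)
        raw = sim_jiang(self.store, self.ic, "T:L00", "T:L01", clamp=False)
        assert raw == pytest.approx(1 - (2 * LN8 - 2 * LN4), abs=TOL)  # = 1 - 2 ln2
        assert sim_jiang(self.store, self.ic, "T:L00", "T:L01") == 0.0  # clamped

    def test_jiang_identity_iff_ic_sum_equals_twice_mica(self):
        # holds exactly at t1 = t2 and for ancestor pairs with equal IC
        assert sim_jiang(self.store, self.ic, "T:L0", "T:L0", clamp=False) == pytest.approx(1.0, abs=TOL)

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(23)
        terms = sorted(self.store.terms)
        max_ic = self.ic.max_ic()
        for _ in range(30):
            t1, t2 = (terms[int(i)] for i in rng.integers(0, len(terms), 2))
            for fn in (sim_resnik, sim_lin, sim_jiang):
                assert fn(self.store, self.ic, t1, t2) == pytest.approx(
                    fn(self.store, self.ic, t2, t1), abs=TOL)
            assert sim_wang(self.store, t1, t2) == pytest.approx(
                sim_wang(self.store, t2, t1), abs=TOL)
            assert 0.0 <= sim_lin(self.store, self.ic, t1, t2) <= 1.0
            assert 0.0 <= sim_wang(self.store, t1, t2) <= 1.0
            assert 0.0 <= sim_resnik(self.store, self.ic, t1, t2) <= max_ic + TOL

    def test_resnik_nondecreasing_toward_target(self):
        # moving t1 from the root toward t2 deepens the MICA
        path = ["T:root", "T:L", "T:L0", "T:L00"]
        vals = [sim_resnik(self.store, self.ic, t, "T:L00") for t in path]
        assert vals == sorted(vals)


class TestWang:
    def test_identity(self, wang_fixture):
        assert sim_wang(wang_fixture, "y", "y") == pytest.approx(1.0, abs=TOL)

    def test_hand_computed_svalue_overlap(self, wang_fixture):
        # S_y: y=1, x=0.8, r=0.64 (SV 2.44)
        # S_z: z=1, x=0.8, q=0.6, r=max(.8*.8, .8*.6)=0.64 (SV 3.04)
        # shared {x, r}: (0.8+0.64)+(0.8+0.64) = 2.88 over 5.48
        assert sim_wang(wang_fixture, "y", "z") == pytest.approx(2.88 / 5.48, abs=TOL)

    def test_disjoint_roots_share_nothing(self):
        store = OntologyStore([("a1", "a0", "is_a"), ("b1", "b0", "is_a")])
        assert sim_wang(store, "a1", "b1") == 0.0

    def test_weight_bounds(self, wang_fixture):
        with pytest.raises(ValueError):
            sim_wang(wang_fixture, "y", "z", w_is_a=1.5)


class TestGeneAndModuleScores:
    @pytest.fixture(autouse=True)
    def _setup(self, eight_gene_ontology):
        self.store, self.corpus = eight_gene_ontology
        self.scorer = SimilarityScorer(self.store, self.corpus)

    def test_identical_single_annotation(self):
        corpus = AnnotationCorpus({"gA": {"T:L00"}, "gB": {"T:L00"}})
        scorer = SimilarityScorer(self.store, self.corpus.__class__(
            {**self.corpus.annotations, **corpus.annotations}))
        assert scorer.gene_similarity_bma("gA", "gB", "lin") == pytest.approx(1.0, abs=TOL)
        assert scorer.gene_similarity_bma("gA", "gB", "wang") == pytest.approx(1.0, abs=TOL)

    def test_two_by_one_matrix_hand_bma(self):
        # gA {L00, L01}, gB {L00}: lin column [1, 2/3]
        # rows maxima (1, 2/3) mean 5/6; column max 1; BMA = 11/12
        corpus = AnnotationCorpus({**self.corpus.annotations,
                                   "gA": {"T:L00", "T:L01"}, "gB": {"T:L00"}})
        # pin IC to the 8-gene corpus so the matrix entries stay 1 and 2/3
        scorer = SimilarityScorer(self.store, corpus,
                                  ic=compute_ic(self.store, self.corpus))
        assert scorer.gene_similarity_bma("gA", "gB", "lin") == pytest.approx(11 / 12, abs=TOL)

    def test_bma_symmetry(self):
        assert self.scorer.gene_similarity_bma("g0", "g3", "lin") == pytest.approx(
            self.scorer.gene_similarity_bma("g3", "g0", "lin"), abs=TOL)

    def test_unannotated_gene_raises(self):
        with pytest.raises(ValueError, match="annotated"):
            self.scorer.gene_similarity_bma("g0", "ghost", "lin")

    def test_module_identical_annotations_scores_one(self):
        corpus = AnnotationCorpus({**self.corpus.annotations,
                                   "pA": {"T:L00"}, "pB": {"T:L00"}})
        scorer = SimilarityScorer(self.store, corpus)
        assert scorer.module_score(["pA", "pB"], "lin") == pytest.approx(1.0, abs=TOL)

    def test_three_protein_module_is_mean_of_pairs(self):
        genes = ["g0", "g1", "g4"]
        expected = np.mean([self.scorer.gene_similarity_bma(a, b, "lin")
                            for i, a in enumerate(genes) for b in genes[i + 1:]])
        assert self.scorer.module_score(genes, "lin") == pytest.approx(expected, abs=TOL)

    def test_coherent_module_outscores_incoherent(self):
        # same-branch leaves vs leaves scattered across branches
        coherent = ["g0", "g1"]        # T:L00, T:L01 (shared parent)
        incoherent = ["g0", "g4"]      # T:L00 vs T:R00 (only the root shared)
        for measure in ("resnik_bma", "lin", "wang"):
            assert (self.scorer.module_score(coherent, measure)
                    > self.scorer.module_score(incoherent, measure))

    def test_under_two_annotated_is_none_with_warning(self):
        with pytest.warns(UserWarning, match="annotated"):
            assert self.scorer.module_score(["g0", "ghost"], "lin") is None


class TestAnnotationIO:
    def test_gaf_round_trip(self, eight_gene_ontology, tmp_path):
        store, corpus = eight_gene_ontology
        p = tmp_path / "ann.gaf"
        write_gaf(corpus, p)
        again = load_annotations(p, store)
        assert again.annotations == corpus.annotations

    def test_two_column_tsv(self, eight_gene_ontology, tmp_path):
        store, _ = eight_gene_ontology
        p = tmp_path / "ann.tsv"
        p.write_text("gA\tT:L00\ngA\tT:L01\ngB\tT:R11\n")
        corpus = load_annotations(p, store)
        assert corpus.annotations == {"gA": {"T:L00", "T:L01"}, "gB": {"T:R11"}}

    def test_unknown_terms_dropped_with_warning(self, eight_gene_ontology, tmp_path):
        store, _ = eight_gene_ontology
        p = tmp_path / "ann.tsv"
        p.write_text("gA\tT:L00\ngA\tT:MISSING\n")
        with pytest.warns(UserWarning, match="unknown"):
            corpus = load_annotations(p, store)
        assert corpus.annotations == {"gA": {"T:L00"}}
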