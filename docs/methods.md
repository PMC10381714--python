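# Methods

## Alignment-graph model

The aligner works on the standard local-network-alignment construction: an
auxiliary graph whose nodes are cross-species protein pairs and whose
edges encode topological agreement between the two input networks.
Composite nodes come from the seed-pair table. The default selection
strategy (`best_match`) keeps, for every protein of either network, the
partner(s) of maximal similarity; ties keep all tied pairs, so the mapping
is many-to-many. `all_pairs` keeps every seed pair and is what the
brute-force test oracles use.

Edges are classified from the two within-network shortest-path distances
d₁, d₂ of the composite endpoints:

| class    | condition                                        |
|----------|--------------------------------------------------|
| match    | d₁ = 1 and d₂ = 1                                |
| mismatch | direct edge on one side, 1 < d ≤ δ on the other |
| gap      | direct edge on one side, d > δ (or ∞) on other  |
| (none)   | no direct edge on either side                    |

Each class splits into homogeneous/heterogeneous by node color (all four
proteins same color or not), for seven parameters: δ = 2 and weights
hom/het match 1 / 0.9, mismatch 0.5 / 0.4, gap 0.2 / 0.1. With a single
shared color — the default when inputs carry no color column — the
heterogeneous categories cannot occur. Two conventions close gaps left
open by the informal description of this scheme:

* composite nodes sharing a protein in either coordinate get **no** edge
  (within-species identity has distance 0, outside every class; linking
  them would manufacture clusters out of one protein's multiple candidate
  partners);
* node pairs with no direct edge on either side get no edge rather than a
  low-weight one, keeping the graph sparse (MCL treats absence as zero
  affinity anyway).

Raising δ only reclassifies gap → mismatch, never the reverse; this
monotonicity is tested.

## Markov clustering

MCL is implemented directly in dense numpy — alignment graphs here have
tens of composite nodes, so sparse machinery would cost more than it
saves. The loop is the canonical one: add self-loops (each node's maximum
incident weight, the standard regularization against period-2
oscillation), column-normalize, then repeat expansion (matrix power 2),
inflation (entrywise power 2.0, renormalize) and pruning of entries below
1e-5 until the matrix changes by less than 1e-8 or 100 iterations pass.
Inflation 2.0 and expansion 2 are the canonical defaults; nothing in the
problem constrains them further. Clusters are read off attractor rows;
attractor systems with overlapping support are merged, and a node
belonging to several systems goes to the one holding its largest attractor
value (ties to the lowest cluster index). Clusters are canonically ordered
(size descending, then smallest member), which makes the partition
invariant under relabeling/permutation of the input — verified by test.

Clusters with ≥ 2 composite nodes become modules. A module's size is the
count of distinct proteins pooled over both species (a composite node
contributes up to two); per-species counts are available from the
projections for users who prefer to count that way.

## Semantic similarity

IC(t) = −ln p(t), with p(t) the fraction of annotated genes carrying t or
any descendant (annotations propagate to ancestors before frequencies are
taken). Natural log is the default; the base is configurable. Terms with
zero propagated frequency have undefined IC and are excluded from MICA
search. Measures:

* **Resnik** = IC(MICA), in [0, max corpus IC];
* **Lin** = 2·IC(MICA)/(IC₁+IC₂) so that identity scores 1; the variant
  without the factor 2 (identity = ½) is available as
  `lin_paper_literal` for comparison with sources that print the formula
  that way; two roots (both IC 0) score 0 by convention;
* **Jiang–Conrath** = 1 − (IC₁ + IC₂ − 2·IC(MICA)); the raw value is an
  IC distance in nats and unbounded below, so reported values are clamped
  to [0, 1] while the raw value stays available;
* **Wang** = S-value overlap of the two ancestor DAGs with edge weights
  0.8 (is_a) and 0.6 (part_of), the canonical weights for this measure.

MICA ties break to the lexicographically smallest term id (determinism).
Gene pairs aggregate term pairs by best-match average; modules average
gene-pair BMA over all unordered pairs of annotated proteins pooled across
both species — pooling is what makes the score meaningful across species,
since it depends only on the shared ontology. Scoring within one GO
namespace is the default; MICA across namespaces is undefined and never
computed. GAF evidence codes are not filtered by default (configurable).
Modules with fewer than two annotated proteins have undefined scores and
are flagged, not failed.

## Null model

Random "alignments" are size-matched uniform draws: for each real module
of size s, s distinct proteins are sampled without replacement from the
pooled vertex set V₁ ∪ V₂ (species recorded). This is the minimal null
that isolates the question "is this module's coherence better than an
arbitrary same-sized protein set from the same networks?" —
degree-preserving or topology-aware nulls are deliberately out of scope.
Nine replicates per comparison is the default. The summary is the
empirical exceedance fraction (#random ≥ real)/replicates; no parametric
p-value is claimed. When the "real" module is itself a random draw the
exceedance is uniform on {0, 1/9, …, 1} — the calibration test checks
this with a chi-square goodness of fit over 500 trials.

## Synthetic data

The generator emulates small disease-neighborhood interactome pairs: two
networks of exact node/edge counts (presets 33/82 vs 41/157 and 51/438 vs
51/651) containing planted conserved modules. Each planted module is a
connected Erdős–Rényi subgraph (edge probability 0.8, plus a random
spanning tree for connectivity) built once and mirrored into both networks
via the true ortholog map; background edges are then drawn uniformly from
the remaining vertex pairs up to the exact edge budget, which can densify
either side of a module independently — modules are near-isomorphic, not
exactly isomorphic. `edge_noise` rewires that fraction of planted edges
per network; `seed_coverage` controls how many true pairs appear in the
seed table; decoy (false-ortholog) seeds default to 10% of true seeds.

Planted sizes default to [11, 7] at the smaller scale and [26, 18] at the
denser scale, so modules dominate the networks as they do in real
disease-neighborhood alignments (where reported modules cover most of the
input proteins). This matters at the denser scale: a uniform background of
651 edges on 51 nodes puts almost every node pair within distance 2, and
small planted modules would be topologically indistinguishable from
background — conserved modules must carry most of the network's edge mass
to be detectable at that density, which is also the regime the method is
actually used in.

The toy ontology is a root plus n disjoint complete binary subtrees
("clades") of configurable depth, all is_a edges. Each gene draws two leaf
annotations: from its own clade with probability `coherence`, otherwise
uniformly from all leaves — so coherence 0 carries no clade signal at all
(verified: the same-clade minus cross-clade mean Lin difference is ≈ 0
over 20 replicates), while coherence 1 makes same-clade genes tight and
cross-clade genes unrelated. The combined "coherence fixture" assigns each
planted module's genes (both species) to one clade at coherence 0.9 and
annotates background genes uniformly.

What the generator does **not** emulate: scale-free degree structure, hub
proteins, STRING evidence channels, annotation-depth heterogeneity of real
GO corpora, or any disease biology. Passing tests therefore show that the
pipeline recovers conserved dense subgraphs and detects controlled
annotation coherence — not that it would rank real disease modules the
same way a specific database snapshot would.

## Numerical and procedural choices

* Distances come from per-source BFS tables; construction is
  O(k·(V+E) + k²) for k seed proteins.
* STRING-dialect scores are auto-detected: any score > 1 puts the file on
  the 0–999 scale and all scores are divided by 1000.
* Protein ids are opaque case-sensitive strings; the seed table is the
  only bridge between the two namespaces.
* The weight-ordering convention (hom_match ≥ het_match ≥ … ≥ het_gap ≥ 0)
  is warned about, not enforced.
* Determinism: composite nodes are ordered lexicographically, MCL
  tie-breaks are explicit, random draws all flow through a
  `numpy.random.Generator` seeded from the run seed; the same config and
  seed reproduce reports byte-for-byte (tested).
* Problem sizes in tests and the acceptance script: 20 random network
  pairs for the brute-force edge oracle, 5 draws per preset for recovery,
  9 replicates for real-vs-random, 500 trials for calibration — small
  enough to run in seconds while leaving the checks statistically
  meaningful.

## Known limitations

* The mismatch-on-both-sides case (d₁, d₂ both in (1, δ]) creates no edge;
  some alignment-graph variants add one. Flagged for comparison, not
  implemented.
* Seed similarity values are used only for node selection, never to scale
  edge weights.
* Exact reproduction of published module tables from live STRING/GO
  snapshots is out of scope: those depend on database versions that are
  not archived with the publications that use them.
* At partial seed coverage the recovery metric is noisy at small sample
  sizes; the monotonicity checks (noise up → recovery down, coverage up →
  recovery up) are asserted with a small sampling slack over 15 seeds.
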