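"""Size-matched random alignments and the real-vs-random comparison.

The null model is deliberately minimal: a random "module" of size s draws
s distinct proteins uniformly without replacement from the pooled vertex
set of the two input networks, ignoring topology and seeds. Comparing a
real module's semantic-similarity score against scores of size-matched
random modules asks whether the aligner's modules are more functionally
coherent than arbitrary same-sized protein sets from the same networks —
the empirical exceedance fraction (#random >= real) / replicates is the
summary; no formal p-value is claimed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .network_io import PPINetwork
from .semantic_similarity import SimilarityScorer

logger = logging.getLogger(__name__)


@dataclass
class RandomModule:
    """A size-matched random protein set posing as an alignment module."""

    index: int
    proteins: list[tuple[int, str]]  # (species, protein id)

    @property
    def size(self) -> int:
        return len(set(self.proteins))

    def project(self, species: int) -> list[str]:
        return sorted({p for s, p in self.proteins if s == species})

    def pooled_proteins(self) -> list[str]:
        return sorted({p for _, p in self.proteins})


@dataclass
class NullComparisonReport:
    """Per-module, per-measure real score vs random-replicate scores."""

    replicates: int
    # rows: (module index, measure, real score, [replicate scores], exceedance)
    rows: list[tuple[int, str, float, list[float], float]] = field(default_factory=list)

    def exceedance(self, module_index: int, measure: str) -> float:
        for idx, meas, _, _, exc in self.rows:
            if idx == module_index and meas == measure:
                return exc
        raise KeyError((module_index, measure))

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            cols = ["module", "measure", "real_score"]
            cols += [f"random_{i + 1}" for i in range(self.replicates)]
            cols += ["exceedance"]
            fh.write("\t".join(cols) + "\n")
            for idx, meas, real, rand, exc in self.rows:
                row = [str(idx), meas, f"{real:.6g}"]
                row += [f"{r:.6g}" for r in rand]
                row += [f"{exc:.6g}"]
                fh.write("\t".join(row) + "\n")


def random_alignment(
    net1: PPINetwork,
    net2: PPINetwork,
    sizes: list[int],
    rng_seed: int | np.random.Generator,
) -> list[RandomModule]:
    """Draw one size-matched random module per requested size.

    Proteins are sampled uniformly without replacement from the pooled
    vertex set V1 u V2 (species recorded with each draw); modules in the
    list are independent. Fully reproducible from the seed.
    """
    pool = [(1, p) for p in sorted(net1.graph.nodes)] + \
           [(2, p) for p in sorted(net2.graph.nodes)]
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    modules = []
    for i, s in enumerate(sizes, start=1):
        if s < 1:
            raise ValueError(f"module size must be >= 1, got {s}")
        if s > len(pool):
            raise ValueError(f"requested size {s} exceeds pooled vertex count {len(pool)}")
        picks = rng.choice(len(pool), size=s, replace=False)
        modules.append(RandomModule(index=i, proteins=[pool[j] for j in sorted(picks)]))
    return modules


def compare_real_vs_random(
    real_modules,
    net1: PPINetwork,
    net2: PPINetwork,
    scorer: SimilarityScorer,
    measures=("resnik_bma", "lin", "wang"),
    replicates: int = 9,
    rng_seed: int = 0,
) -> NullComparisonReport:
    """Score real modules against *replicates* size-matched random draws.

    For every (module, measure) the report row holds the real score, the
    replicate scores and the exceedance fraction (#random >= real) /
    replicates. Modules with fewer than two annotated proteins are
    excluded with a warning; a random replicate that itself cannot be
    scored contributes a score of 0 (no annotated signal).
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(rng_seed)
    report = NullComparisonReport(replicates=replicates)

    scorable = []
    for mod in real_modules:
        n_annot = sum(1 for p in mod.pooled_proteins() if scorer.corpus.is_annotated(p))
        if n_annot < 2:
            warnings.warn(f"module {mod.index} has <2 annotated proteins; excluded",
                          stacklevel=2)
            continue
        scorable.append(mod)
    if not scorable:
        return report

    sizes = [m.size for m in scorable]
    replicate_sets = [random_alignment(net1, net2, sizes, rng) for _ in range(replicates)]

    for mi, mod in enumerate(scorable):
        for measure in measures:
            real = scorer.module_score(mod, measure)
            rand_scores = []
            for rep in replicate_sets:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    val = scorer.module_score(rep[mi], measure)
                rand_scores.append(0.0 if val is None else val)
            exceed = sum(1 for r in rand_scores if r >= real) / replicates
            report.rows.append((mod.index, measure, real, rand_scores, exceed))
    logger.info("null comparison: %d modules x %d measures x %d replicates",
                len(scorable), len(measures), replicates)
    return report
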