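"""Pipeline orchestration: align -> extract -> score -> null-compare.

Each stage is a plain function over the library types; the CLI and the
analysis drivers are thin wrappers. Every run writes a provenance JSON
(config echo, input content hashes, seed, package version) sufficient to
reproduce its outputs bit for bit.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import __version__
from .alignment_graph import AlignmentGraph, WeightParams, build_alignment_graph
from .module_extraction import AlignmentModule, MCLParams, extract_modules
from .network_io import (PPINetwork, SeedPairMap, file_sha256, read_network,
                         read_seed_pairs, write_module_report)
from .randomization import NullComparisonReport, compare_real_vs_random
from .semantic_similarity import (SimilarityScorer, load_annotations,
                                  load_ontology)

logger = logging.getLogger(__name__)

DEFAULT_MEASURES = ("resnik_bma", "lin", "wang")


@dataclass
class PipelineConfig:
    """Everything one run needs; file paths may be None for in-memory use."""

    net1: str | None = None
    net2: str | None = None
    seeds: str | None = None
    obo: str | None = None
    annotations: str | None = None
    net_format: str = "edgelist"
    min_confidence: float = 0.7
    weights: WeightParams = field(default_factory=WeightParams)
    mcl: MCLParams = field(default_factory=MCLParams)
    strategy: str = "best_match"
    measures: tuple[str, ...] = DEFAULT_MEASURES
    min_module_size: int = 2
    replicates: int = 9
    rng_seed: int = 0
    outdir: str = "results"

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        weights = WeightParams(**raw.pop("weights", {})) if isinstance(raw.get("weights"), dict) \
            else raw.pop("weights", WeightParams())
        mcl = MCLParams(**raw.pop("mcl", {})) if isinstance(raw.get("mcl"), dict) \
            else raw.pop("mcl", MCLParams())
        cfg = cls(weights=weights, mcl=mcl, **raw)
        return cfg

    def provenance(self) -> dict:
        prov = {
            "version": __version__,
            "rng_seed": self.rng_seed,
            "config": {k: (asdict(v) if hasattr(v, "__dataclass_fields__") else v)
                       for k, v in asdict(self).items()},
            "input_hashes": {},
        }
        for key in ("net1", "net2", "seeds", "obo", "annotations"):
            p = getattr(self, key)
            if p and Path(p).exists():
                prov["input_hashes"][key] = file_sha256(p)
        return prov


def load_inputs(config: PipelineConfig) -> tuple[PPINetwork, PPINetwork, SeedPairMap]:
    for key in ("net1", "net2", "seeds"):
        p = getattr(config, key)
        if p is None or not Path(p).exists():
            raise FileNotFoundError(f"{key} file not found: {p}")
    net1 = read_network(config.net1, config.net_format,
                        config.min_confidence if config.net_format == "string_tsv" else 0.0)
    net2 = read_network(config.net2, config.net_format,
                        config.min_confidence if config.net_format == "string_tsv" else 0.0)
    seeds = read_seed_pairs(config.seeds)
    return net1, net2, seeds


def run_align(
    config: PipelineConfig,
    net1: PPINetwork | None = None,
    net2: PPINetwork | None = None,
    seeds: SeedPairMap | None = None,
) -> tuple[AlignmentGraph, list[AlignmentModule]]:
    """Build the alignment graph, cluster it, and write the module report."""
    t0 = time.perf_counter()
    if net1 is None or net2 is None or seeds is None:
        net1, net2, seeds = load_inputs(config)
    graph = build_alignment_graph(net1, net2, seeds, config.weights, config.strategy)
    modules = extract_modules(graph, config.mcl, config.min_module_size)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    graph.write_tsv(outdir / "alignment_graph.tsv")
    prov = config.provenance()
    prov["stage"] = "align"
    prov["category_counts"] = dict(graph.category_counts())
    prov["elapsed_s"] = round(time.perf_counter() - t0, 3)
    if modules:
        write_module_report(modules, {}, outdir / "modules.tsv", provenance=prov)
    with open(outdir / "align_provenance.json", "w") as fh:
        json.dump(prov, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    logger.info("align stage: %d composite nodes, %d edges, %d modules (%.2fs)",
                graph.graph.number_of_nodes(), graph.graph.number_of_edges(),
                len(modules), prov["elapsed_s"])
    return graph, modules


def make_scorer(config: PipelineConfig, store=None, corpus=None) -> SimilarityScorer:
    if store is None:
        if config.obo is None:
            raise FileNotFoundError("no ontology configured")
        store = load_ontology(config.obo)
    if corpus is None:
        if config.annotations is None:
            raise FileNotFoundError("no annotation file configured")
        corpus = load_annotations(config.annotations, store)
    return SimilarityScorer(store, corpus)


def run_score(
    config: PipelineConfig,
    modules: list[AlignmentModule],
    scorer: SimilarityScorer | None = None,
) -> dict[tuple[int, str], float | None]:
    """Score every module under every configured measure; write the report."""
    scorer = scorer or make_scorer(config)
    scores: dict[tuple[int, str], float | None] = {}
    for mod in modules:
        for measure in config.measures:
            scores[(mod.index, measure)] = scorer.module_score(mod, measure)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prov = config.provenance()
    prov["stage"] = "score"
    if modules:
        write_module_report(modules, scores, outdir / "modules_scored.tsv", provenance=prov)
    return scores


def run_null(
    config: PipelineConfig,
    modules: list[AlignmentModule],
    net1: PPINetwork | None = None,
    net2: PPINetwork | None = None,
    scorer: SimilarityScorer | None = None,
) -> NullComparisonReport:
    """Compare real module scores against size-matched random alignments."""
    if net1 is None or net2 is None:
        net1, net2, _ = load_inputs(config)
    scorer = scorer or make_scorer(config)
    report = compare_real_vs_random(
        modules, net1, net2, scorer,
        measures=config.measures, replicates=config.replicates,
        rng_seed=config.rng_seed)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report.write_tsv(outdir / "null_comparison.tsv")
    with open(outdir / "null_provenance.json", "w") as fh:
        prov = config.provenance()
        prov["stage"] = "null"
        json.dump(prov, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return report


def run_all(config: PipelineConfig):
    """simulate-independent full pass: align, score, null-compare."""
    net1, net2, seeds = load_inputs(config)
    graph, modules = run_align(config, net1, net2, seeds)
    scorer = make_scorer(config)
    scores = run_score(config, modules, scorer)
    report = run_null(config, modules, net1, net2, scorer)
    return graph, modules, scores, report
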