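#!/usr/bin/env python
"""Score the extracted modules with GO semantic similarity.

For each scale, re-runs alignment on the fixture and scores every module
with Resnik-BMA, Lin and Wang over the pooled (both-species) protein set,
writing the scored module report next to the unscored one.
"""

import argparse
import warnings
from pathlib import Path

from lnalign.pipeline import PipelineConfig, make_scorer, run_align, run_score


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    for preset in ("ad_scale", "pd_scale"):
        fx = args.data / preset
        cfg = PipelineConfig(
            net1=str(fx / "net1.tsv"), net2=str(fx / "net2.tsv"),
            seeds=str(fx / "seeds.tsv"), obo=str(fx / "ontology.obo"),
            annotations=str(fx / "annotations.gaf"),
            outdir=str(args.out / preset), rng_seed=args.seed)
        _, modules = run_align(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scores = run_score(cfg, modules)
        print(f"{preset}:")
        for m in modules:
            row = ", ".join(f"{meas} {scores[(m.index, meas)]:.3f}"
                            for meas in cfg.measures
                            if scores[(m.index, meas)] is not None)
            print(f"  module {m.index} ({m.size} proteins): {row}")


if __name__ == "__main__":
    main()
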