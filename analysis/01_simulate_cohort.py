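#!/usr/bin/env python
"""Generate the synthetic discovery and external-validation cohorts.

Writes expression / clinical / immune tables, the PPI edge list, a
hallmark-style gene-set collection and the generating-truth record under
results/cohort/ (discovery) and results/external/ (validation). Both
cohorts share the generative structure: zero-inflated correlated PSG
genes, a 3-gene causal panel (PSG3+PSG7+PSG8) with hazard ratio 2.45 in
panel-positive females only, and a 7-type immune shift in panel-positive
samples.
"""

import argparse
import dataclasses
import json
from pathlib import Path

from psgsurv import io
from psgsurv.pipeline import stage_seed, synthetic_gene_sets
from psgsurv.simulate import luad_config, simulate_cohort


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    cfg = luad_config(seed=stage_seed(args.seed, "train"))
    cohort = simulate_cohort(cfg)
    cohort.write(args.outdir / "cohort")

    ext_cfg = dataclasses.replace(cfg, n_samples=106,
                                  female_fraction=36 / 106,
                                  seed=stage_seed(args.seed, "external"))
    external = simulate_cohort(ext_cfg)
    external.write(args.outdir / "external")

    sets = synthetic_gene_sets(cfg, seed=stage_seed(args.seed, "gene_sets"))
    io.write_gmt(sets, args.outdir / "cohort" / "gene_sets.gmt")

    n_f = (cohort.clinical["sex"] == "female").sum()
    print(f"discovery cohort: {cfg.n_samples} samples ({n_f} female), "
          f"panel-positive fraction "
          f"{cohort.truth['panel_positive_fraction']:.3f}")
    print(f"external cohort: {ext_cfg.n_samples} samples "
          f"({(external.clinical['sex'] == 'female').sum()} female)")
    print(f"tables written under {args.outdir}/cohort and "
          f"{args.outdir}/external")


if __name__ == "__main__":
    main()
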