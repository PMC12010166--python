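#!/usr/bin/env python
"""Uni/multivariate Cox models on continuous and binarized PSG features.

For the female stratum, fits univariate Cox models to each PSG gene's
continuous expression, its binarized status, and the combination-panel
indicator; features with univariate p < .05 enter the multivariate model
after the redundancy-exclusion rule (constituents rank-correlated > 0.6
with the combination are dropped). Writes results/tables/cox_female.tsv.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from psgsurv import io, stats
from psgsurv.status import call_status


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    expr = io.read_expression(args.outdir / "cohort" / "expression.tsv")
    clin = io.read_clinical(args.outdir / "cohort" / "clinical.tsv")
    best = json.loads((args.outdir / "tables" / "best_panel.json")
                      .read_text())
    panel = best["female"]["panel"].split("+")

    sub = clin[clin["sex"] == "female"]
    e = expr[sub["sample_id"].tolist()]
    psg = [g for g in e.index if g.startswith("PSG")]

    feats = {}
    for gene in psg:
        if e.loc[gene].nunique() > 1:
            feats[gene] = e.loc[gene].to_numpy(float)
            feats[f"b{gene}"] = (e.loc[gene] > 0).to_numpy(float)
    combo_name = "b" + "+".join(panel)
    feats[combo_name] = call_status(e, panel).to_numpy(float)

    res = stats.cox_fit(pd.DataFrame(feats), sub["time"], sub["event"],
                        mode="multivariate",
                        combinations={combo_name: [f"b{g}" for g in panel]})
    tables = args.outdir / "tables"
    tables.mkdir(parents=True, exist_ok=True)
    res.to_csv(tables / "cox_female.tsv", sep="\t", index=False)

    uni = res[res["model"] == "univariate"].set_index("feature")
    multi = res[res["model"] == "multivariate"].set_index("feature")
    print(f"univariate {combo_name}: HR = "
          f"{uni.loc[combo_name, 'hazard_ratio']:.2f} "
          f"(p = {uni.loc[combo_name, 'p']:.3g})")
    if combo_name in multi.index:
        print(f"multivariate {combo_name}: HR = "
              f"{multi.loc[combo_name, 'hazard_ratio']:.2f} "
              f"(p = {multi.loc[combo_name, 'p']:.3g}); "
              f"features: {list(multi.index)}")


if __name__ == "__main__":
    main()
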