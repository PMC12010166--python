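#!/usr/bin/env python
"""Cohort characteristics by sex: per-gene PSG+/- counts with chi-squared
tests, age comparison, and per-gene KM/log-rank within each sex.

Reads results/cohort/, writes results/tables/cohort_summary.tsv and
per_gene_km.tsv. The expected picture mirrors the motivating study: no
sex difference in PSG status frequencies, but sex-specific survival
separation for individual PSG genes in the female stratum only.
"""

import argparse
from pathlib import Path

import pandas as pd

from psgsurv import io, stats
from psgsurv.status import call_status, status_by_group


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    expr = io.read_expression(args.outdir / "cohort" / "expression.tsv")
    clin = io.read_clinical(args.outdir / "cohort" / "clinical.tsv")
    bundle = io.align_cohort(expr, clin)
    expr, clin = bundle.expression, bundle.clinical
    psg = [g for g in expr.index if g.startswith("PSG")]

    rows = []
    male = clin[clin["sex"] == "male"]
    female = clin[clin["sex"] == "female"]
    rows.append({"variable": "age", "male": male["age"].median(),
                 "female": female["age"].median(),
                 "p": stats.wilcoxon_ranksum(male["age"],
                                             female["age"])["p"]})
    for gene in psg:
        table = status_by_group(call_status(expr, [gene]), clin)
        rows.append({"variable": gene,
                     "male": int(table.loc["positive", "male"]),
                     "female": int(table.loc["positive", "female"]),
                     "p": stats.chisq_independence(table.to_numpy())["p"]})
    summary = pd.DataFrame(rows)

    km_rows = []
    for sex, sub in clin.groupby("sex"):
        e = expr[sub["sample_id"].tolist()]
        t = sub["time"].to_numpy()
        ev = sub["event"].to_numpy()
        for gene in psg:
            pos = call_status(e, [gene]).to_numpy()
            if pos.all() or not pos.any():
                continue
            res = stats.km_logrank(t[pos], ev[pos], t[~pos], ev[~pos],
                                   curves=False)
            km_rows.append({"gene": gene, "stratum": sex,
                            "n_pos": int(pos.sum()),
                            "logrank_p": res["p"]})
    km = pd.DataFrame(km_rows)

    tables = args.outdir / "tables"
    tables.mkdir(parents=True, exist_ok=True)
    summary.to_csv(tables / "cohort_summary.tsv", sep="\t", index=False)
    km.to_csv(tables / "per_gene_km.tsv", sep="\t", index=False)

    n_sig = {s: (g["logrank_p"] < 0.05).sum() for s, g in km.groupby("stratum")}
    print(f"status-by-sex chi-squared: min p = {summary['p'].min():.4f} "
          "(no sex difference expected)")
    print(f"per-gene log-rank significant at .05: {n_sig} "
          "(female-specific separation expected)")


if __name__ == "__main__":
    main()
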