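#!/usr/bin/env python
"""Elastic-net Cox predictive models, internal and external validation.

Per sex: a panel-only model evaluated on a stratified 2/3-1/3 internal
split and on the external cohort, plus a panel + pathway-PC model (three
training-fitted principal components of the panel-coupled gene block).
Writes results/tables/predictive.json. The expected contrast is the
sex-specific one: useful female C-indices, chance-level male ones.
"""

import argparse
import json
from pathlib import Path

from psgsurv import io, predict
from psgsurv.status import call_status


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    expr = io.read_expression(args.outdir / "cohort" / "expression.tsv")
    clin = io.read_clinical(args.outdir / "cohort" / "clinical.tsv")
    ext_expr = io.read_expression(args.outdir / "external" / "expression.tsv")
    ext_clin = io.read_clinical(args.outdir / "external" / "clinical.tsv")
    best = json.loads((args.outdir / "tables" / "best_panel.json")
                      .read_text())
    panel = best["female"]["panel"].split("+")
    sets = io.read_gmt(args.outdir / "cohort" / "gene_sets.gmt")
    pathway = [g for g in sets.get("PANEL_RESPONSE_UP", [])
               if g in expr.index]

    out = {}
    for sex in ("female", "male"):
        sub = clin[clin["sex"] == sex].reset_index(drop=True)
        ids = sub["sample_id"].tolist()
        e = expr[ids]
        feats = call_status(e, panel).astype(float).rename("panel") \
            .to_frame()
        train, valid = predict.stratified_split(sub, seed=args.seed)
        model = predict.fit_elastic_cox(feats.loc[train["sample_id"]],
                                        train["time"], train["event"],
                                        seed=args.seed)
        internal = predict.evaluate(model, feats.loc[valid["sample_id"]],
                                    valid["time"], valid["event"])

        ext_sub = ext_clin[ext_clin["sex"] == sex].reset_index(drop=True)
        ext_e = ext_expr[ext_sub["sample_id"].tolist()]
        ext_feats = call_status(ext_e, panel).astype(float) \
            .rename("panel").to_frame()
        full = predict.fit_elastic_cox(feats, sub["time"], sub["event"],
                                       seed=args.seed)
        external = predict.evaluate(full, ext_feats, ext_sub["time"],
                                    ext_sub["event"])
        out[sex] = {"internal_c_index": internal,
                    "external_c_index": external}

        if pathway:
            block = predict.fit_pca_block(e.loc[pathway].T, k=3,
                                          prefix="pathway")
            m2 = predict.fit_elastic_cox(
                feats.join(block.transform(e.loc[pathway].T)),
                sub["time"], sub["event"], seed=args.seed)
            out[sex]["external_c_index_pathway_pcs"] = predict.evaluate(
                m2, ext_feats.join(block.transform(ext_e.loc[pathway].T)),
                ext_sub["time"], ext_sub["event"])

        print(f"{sex}: internal C = {internal:.3f}, "
              f"external C = {external:.3f}, "
              f"panel+pathway-PC external C = "
              f"{out[sex].get('external_c_index_pathway_pcs', float('nan')):.3f}")

    tables = args.outdir / "tables"
    tables.mkdir(parents=True, exist_ok=True)
    (tables / "predictive.json").write_text(json.dumps(out, indent=2) + "\n")


if __name__ == "__main__":
    main()
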