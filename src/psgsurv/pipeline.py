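"""End-to-end orchestration of the PSG panel survival analysis.

``run_all`` executes every stage on a cohort bundle — panel binarization,
cohort summary table, per-gene KM/log-rank by sex, the exhaustive 2/3-gene
combination search with external validation, uni/multivariate Cox, immune
association, differential expression + over-representation + GSEA, the
graph-W1 pair analysis, and elastic-net Cox prediction — and returns a
JSON-serializable summary plus tab-separated result tables.

Every stochastic stage derives its seed from one master seed by stable
hashing of the stage name, so stages are reproducible independently of
execution order. Any stage failure is recorded in a stage-status ledger
and the remaining stages still run.
"""

from __future__ import annotations

import json
import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from psgsurv import combos, dge, immune, io, predict, stats, status, transport
from psgsurv.simulate import (SimulationConfig, simulate_cohort,
                              de_gene_names)

logger = logging.getLogger("psgsurv")


def stage_seed(master_seed: int, stage: str) -> int:
    """Per-stage seed: stable hash of the stage name mixed with the master
    seed (always below 2**31)."""
    return (zlib.crc32(stage.encode()) ^ (int(master_seed) * 0x9E3779B1)) \
        % (2**31)


def synthetic_gene_sets(config: SimulationConfig, n_sets: int = 50,
                        set_size: int = 40, seed: int = 0) -> dict:
    """A hallmark-style 50-set collection over the synthetic universe.

    One set ("PANEL_RESPONSE_UP") is the block of background genes coupled
    to panel status; the rest are random draws from the background genes.
    """
    rng = np.random.default_rng(seed)
    background = [f"BG{i + 1:04d}" for i in range(config.n_background_genes)]
    sets = {"PANEL_RESPONSE_UP": de_gene_names(config)}
    for i in range(n_sets - 1):
        members = rng.choice(background, size=min(set_size, len(background)),
                             replace=False)
        sets[f"RANDOM_SET_{i + 1:02d}"] = sorted(members)
    return sets


def _json_safe(obj):
    if isinstance(obj, dict):
        return {k: _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def run_all(config: SimulationConfig | None = None,
            bundle: io.CohortBundle | None = None,
            external_bundle: io.CohortBundle | None = None,
            gene_sets: dict | None = None,
            graph_edges: list | None = None,
            outdir: str | Path | None = None,
            master_seed: int | None = None,
            w1_max_patients: int = 50,
            gsea_n_perm: int = 1000,
            external_n: int = 106,
            external_female_fraction: float = 36 / 106) -> dict:
    """Run the full analysis.

    Either pass a :class:`SimulationConfig` (synthetic mode: a training
    cohort and an independent external cohort with the same generative
    effect are simulated) or pre-aligned ``bundle``/``external_bundle``
    inputs. Returns the summary dict; when ``outdir`` is given, tables and
    ``summary.json`` are written there.
    """
    if (config is None) == (bundle is None):
        raise ValueError("pass exactly one of config (synthetic) or bundle")
    if master_seed is None:
        master_seed = config.seed if config is not None else 0

    summary: dict = {"master_seed": int(master_seed), "stages": {}}
    tables: dict[str, pd.DataFrame] = {}

    def run_stage(name, fn):
        try:
            fn()
            summary["stages"][name] = "ok"
        except Exception as exc:
            logger.exception("stage %s failed", name)
            summary["stages"][name] = f"failed: {exc}"

    # ---- data -------------------------------------------------------
    if config is not None:
        import dataclasses

        cfg = dataclasses.replace(config, seed=stage_seed(master_seed, "train"))
        cohort = simulate_cohort(cfg)
        bundle = io.align_cohort(cohort.expression, cohort.clinical,
                                 cohort.immune)
        ext_cfg = dataclasses.replace(
            config, n_samples=external_n,
            female_fraction=external_female_fraction,
            seed=stage_seed(master_seed, "external"))
        ext = simulate_cohort(ext_cfg)
        external_bundle = io.align_cohort(ext.expression, ext.clinical,
                                          ext.immune)
        graph_edges = cohort.graph_edges
        gene_sets = gene_sets or synthetic_gene_sets(
            cfg, seed=stage_seed(master_seed, "gene_sets"))
        panel = list(cfg.panel_genes)
        psg_genes = list(cfg.psg_genes)
        summary["truth"] = _json_safe(cohort.truth)
    else:
        psg_genes = [g for g in bundle.expression.index
                     if g.startswith("PSG")]
        panel = None

    expr, clin = bundle.expression, bundle.clinical
    imm = bundle.immune

    # ---- panel status + cohort summary table ------------------------
    def cohort_summary():
        rows = []
        male = clin[clin["sex"] == "male"]
        female = clin[clin["sex"] == "female"]
        rows.append({"variable": "age", "test": "wilcoxon",
                     "male": float(male["age"].median()),
                     "female": float(female["age"].median()),
                     "p": stats.wilcoxon_ranksum(male["age"],
                                                 female["age"])["p"]})
        for gene in psg_genes:
            st = status.call_status(expr, [gene])
            table = status.status_by_group(st, clin)
            res = stats.chisq_independence(table.to_numpy())
            rows.append({"variable": gene, "test": "chisq",
                         "male": int(table.loc["positive", "male"]),
                         "female": int(table.loc["positive", "female"]),
                         "p": res["p"]})
        tables["cohort_summary"] = pd.DataFrame(rows)
        summary["cohort"] = {
            "n": len(clin), "n_female": int((clin["sex"] == "female").sum()),
            "n_male": int((clin["sex"] == "male").sum()),
            "event_fraction": float(clin["event"].mean()),
        }

    run_stage("cohort_summary", cohort_summary)

    # ---- per-gene KM ------------------------------------------------
    def per_gene_km():
        rows = []
        for sex in ("female", "male"):
            sub = clin[clin["sex"] == sex]
            e = expr[sub["sample_id"].tolist()]
            for gene in psg_genes:
                pos = status.call_status(e, [gene]).to_numpy()
                if pos.all() or not pos.any():
                    continue
                t = sub["time"].to_numpy(float)
                ev = sub["event"].to_numpy(int)
                res = stats.km_logrank(t[pos], ev[pos], t[~pos], ev[~pos])
                rows.append({"gene": gene, "stratum": sex,
                             "n_pos": int(pos.sum()),
                             "n_neg": int((~pos).sum()),
                             "logrank_p": res["p"]})
        tables["per_gene_km"] = pd.DataFrame(rows)
        summary["per_gene_km"] = {
            sex: sorted(
                r["gene"] for r in tables["per_gene_km"].to_dict("records")
                if r["stratum"] == sex and r["logrank_p"] < stats.ALPHA)
            for sex in ("female", "male")}

    run_stage("per_gene_km", per_gene_km)

    # ---- combination search + external validation -------------------
    best_panel = {"female": panel, "male": panel}

    def combo_search():
        for sex in ("female", "male"):
            res = combos.search(expr, clin, psg_genes, sizes=(2, 3),
                                stratum=sex)
            tables[f"combo_search_{sex}"] = res
            top = res.iloc[0]
            best_panel[sex] = top["panel"].split("+")
            summary[f"combo_search_{sex}"] = {
                "n_panels": int(len(res)),
                "best_panel": top["panel"],
                "best_p": float(top["logrank_p"]),
                "best_q": float(top["q_value"]),
            }
        if external_bundle is not None:
            val = combos.validate_panel(
                best_panel["female"], external_bundle.expression,
                external_bundle.clinical, stratum="female")
            summary["external_validation"] = {
                "panel": val["panel"], "p": float(val["p"]),
                "n_pos": val["n_pos"], "n_neg": val["n_neg"]}

    run_stage("combo_search", combo_search)

    # ---- Cox models (female stratum, continuous + binarized) --------
    def cox_models():
        sub = clin[clin["sex"] == "female"]
        e = expr[sub["sample_id"].tolist()]
        feats = {}
        for gene in psg_genes:
            if e.loc[gene].nunique() > 1:
                feats[gene] = e.loc[gene].to_numpy(float)
                feats[f"b{gene}"] = (e.loc[gene] > 0).to_numpy(float)
        combo_name = "b" + "+".join(best_panel["female"])
        feats[combo_name] = status.call_status(
            e, best_panel["female"]).to_numpy(float)
        fdf = pd.DataFrame(feats)
        constituents = [f"b{g}" for g in best_panel["female"]]
        res = stats.cox_fit(
            fdf, sub["time"], sub["event"], mode="multivariate",
            combinations={combo_name: constituents})
        tables["cox_female"] = res
        uni = res[res["model"] == "univariate"].set_index("feature")
        multi = res[res["model"] == "multivariate"].set_index("feature")
        summary["cox_female"] = {
            "combo_feature": combo_name,
            "combo_univariate_hr": float(uni.loc[combo_name,
                                                 "hazard_ratio"]),
            "combo_univariate_p": float(uni.loc[combo_name, "p"]),
            "combo_multivariate_hr": (
                float(multi.loc[combo_name, "hazard_ratio"])
                if combo_name in multi.index else None),
            "multivariate_features": list(multi.index),
        }

    run_stage("cox_models", cox_models)

    # ---- immune association ----------------------------------------
    def immune_assoc():
        sub = clin[clin["sex"] == "female"]
        ids = sub["sample_id"].tolist()
        st = status.call_status(expr[ids], best_panel["female"])
        corr = immune.psg_immune_correlation(
            expr.loc[psg_genes, ids], imm.loc[ids])
        diff = immune.group_difference(imm.loc[ids], st)
        tables["immune_correlation"] = corr
        tables["immune_group_difference"] = diff
        summary["immune"] = {
            "n_types_fdr05": int((diff["q"] < 0.05).sum()),
            "significant_types": sorted(
                diff.loc[diff["q"] < 0.05, "cell_type"]),
        }

    if imm is None:
        summary["stages"]["immune_assoc"] = "skipped: no immune table"
    else:
        run_stage("immune_assoc", immune_assoc)

    # ---- differential expression + enrichment -----------------------
    def enrichment():
        sub = clin[clin["sex"] == "female"]
        ids = sub["sample_id"].tolist()
        e = expr[ids]
        st = status.call_status(e, best_panel["female"])
        background = [g for g in e.index if g not in psg_genes]
        table, sig = dge.differential_expression(
            e.loc[background], st, lfc_threshold=1.0)
        tables["dge"] = table
        summary["dge"] = {"n_significant": len(sig)}
        if gene_sets:
            ora = dge.overrepresentation(sig, gene_sets, background)
            tables["overrepresentation"] = ora
            top = ora.iloc[0]
            summary["overrepresentation"] = {
                "top_set": top["set_name"], "p": float(top["p"]),
                "q": float(top["q"]), "overlap": int(top["overlap_count"])}
            scores = dge.ranking_scores(table)
            gs = dge.gsea_es(scores, gene_sets[top["set_name"]],
                             n_perm=gsea_n_perm,
                             seed=stage_seed(master_seed, "gsea"))
            summary["gsea"] = {"set": top["set_name"],
                               "es": float(gs["es"]),
                               "nes": float(gs["nes"]),
                               "p": float(gs["p"])}

    run_stage("dge_enrichment", enrichment)

    # ---- graph transport -------------------------------------------
    def graph_w1():
        graph = transport.build_graph(graph_edges)
        node_expr = expr.reindex(graph.nodes)
        if node_expr.isna().any().any():
            # interactor genes need not exist in expression: give them
            # zero (they then contribute only smoothing mass)
            node_expr = node_expr.fillna(0.0)
        out = {}
        for sex in ("female", "male"):
            res = transport.pairwise_distance_analysis(
                graph, node_expr, clin, sex,
                seed=stage_seed(master_seed, f"w1_{sex}"),
                max_patients=w1_max_patients)
            tables[f"w1_pairs_{sex}"] = res["pairs"]
            out[sex] = {"anova_p": res["anova_p"],
                        "perm_p": res["perm_p"],
                        "n_patients": res["n_patients"]}
        summary["graph_w1"] = _json_safe(out)

    if graph_edges is None:
        summary["stages"]["graph_transport"] = "skipped: no graph"
    else:
        run_stage("graph_transport", graph_w1)

    # ---- predictive modelling --------------------------------------
    def predictive():
        out = {}
        pathway = (gene_sets or {}).get("PANEL_RESPONSE_UP")

        def one_sex(sex):
            sub = clin[clin["sex"] == sex].reset_index(drop=True)
            ids = sub["sample_id"].tolist()
            e = expr[ids]
            seed = stage_seed(master_seed, f"predict_{sex}")
            feats = status.call_status(e, best_panel["female"]) \
                .astype(float).rename("panel").to_frame()
            # internal 2/3 - 1/3 split on the panel-only model
            train, valid = predict.stratified_split(sub, seed=seed)
            model = predict.fit_elastic_cox(
                feats.loc[train["sample_id"]], train["time"],
                train["event"], seed=seed)
            internal_c = predict.evaluate(
                model, feats.loc[valid["sample_id"]], valid["time"],
                valid["event"])
            out[sex] = {"internal_c_index": internal_c}
            if external_bundle is None:
                return
            ext_clin = external_bundle.clinical
            ext_sub = ext_clin[ext_clin["sex"] == sex].reset_index(drop=True)
            ext_ids = ext_sub["sample_id"].tolist()
            ext_e = external_bundle.expression[ext_ids]
            ext_feats = status.call_status(ext_e, best_panel["female"]) \
                .astype(float).rename("panel").to_frame()
            full_model = predict.fit_elastic_cox(
                feats, sub["time"], sub["event"], seed=seed)
            out[sex]["external_c_index"] = predict.evaluate(
                full_model, ext_feats, ext_sub["time"], ext_sub["event"])
            if pathway:
                genes = [g for g in pathway if g in e.index]
                if genes:
                    block = predict.fit_pca_block(
                        e.loc[genes].T, k=3, prefix="pathway")
                    tr_p = feats.join(block.transform(e.loc[genes].T))
                    ex_p = ext_feats.join(
                        block.transform(ext_e.loc[genes].T))
                    m2 = predict.fit_elastic_cox(
                        tr_p, sub["time"], sub["event"], seed=seed)
                    out[sex]["external_c_index_pathway_pcs"] = \
                        predict.evaluate(m2, ex_p, ext_sub["time"],
                                         ext_sub["event"])

        for sex in ("female", "male"):
            try:
                one_sex(sex)
            except ValueError as exc:
                # e.g. too few comparable pairs in a tiny external stratum
                logger.warning("predictive stage, %s stratum: %s", sex, exc)
                out.setdefault(sex, {})["error"] = str(exc)
        summary["predictive"] = _json_safe(out)

    run_stage("predictive", predictive)

    # ---- output -----------------------------------------------------
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, table in tables.items():
            table.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
        (outdir / "summary.json").write_text(
            json.dumps(_json_safe(summary), indent=2, sort_keys=True) + "\n")
    summary["_tables"] = tables
    return summary
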