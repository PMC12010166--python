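"""Differential expression between panel status groups, hallmark-style
over-representation, and GSEA enrichment scores.

The differential test is the per-gene Wilcoxon rank-sum (the pipeline's
test for continuous variables) with BH-FDR across all tested genes; the
effect-size rule is |log2 fold change| > threshold on pseudocounted group
means. Over-representation is the one-sided hypergeometric tail.
The GSEA enrichment score is the weighted Kolmogorov-Smirnov running-sum
statistic; its normalized version (NES) and p-value come from gene-set
permutation (random same-size sets), seeded.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from psgsurv import stats as pstats

logger = logging.getLogger("psgsurv")


def differential_expression(expression: pd.DataFrame, status: pd.Series,
                            lfc_threshold: float = 2.0,
                            fdr_threshold: float = 0.05,
                            pseudocount: float = 1.0):
    """Per-gene Wilcoxon DE between panel-positive and -negative samples.

    log2fc = log2((mean_pos + c) / (mean_neg + c)) with pseudocount c.
    Returns (table, significant_genes) where significance requires both
    q < ``fdr_threshold`` and |log2fc| > ``lfc_threshold``.
    """
    status = status.reindex(expression.columns)
    if status.isna().any():
        raise ValueError("status missing for some expression samples")
    mask = status.astype(bool).to_numpy()
    if mask.sum() < 3 or (~mask).sum() < 3:
        raise ValueError("each status group needs at least 3 samples")
    pos = expression.loc[:, mask].to_numpy(float)
    neg = expression.loc[:, ~mask].to_numpy(float)

    # vectorized two-sided rank-sum across genes
    res = sps.mannwhitneyu(pos, neg, axis=1, alternative="two-sided")
    p = np.asarray(res.pvalue, float)
    # a gene constant across both groups gives an undefined test; p := 1
    constant = (expression.nunique(axis=1) <= 1).to_numpy()
    p[constant] = 1.0
    log2fc = np.log2((pos.mean(axis=1) + pseudocount)
                     / (neg.mean(axis=1) + pseudocount))
    q = pstats.bh_fdr(p)
    table = pd.DataFrame({"gene": expression.index, "log2fc": log2fc,
                          "p": p, "q": q})
    sig = table.loc[(table["q"] < fdr_threshold)
                    & (table["log2fc"].abs() > lfc_threshold), "gene"]
    return table, list(sig)


def overrepresentation(sig_genes, collection: dict[str, list[str]],
                       universe) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of ``sig_genes`` in
    each gene set, BH-FDR over the sets.

    Set members outside ``universe`` are ignored; ``sig_genes`` must be a
    subset of the universe.
    """
    universe = list(dict.fromkeys(universe))
    uni = set(universe)
    sig = set(sig_genes)
    stray = sig - uni
    if stray:
        raise ValueError(f"significant genes outside the universe: "
                         f"{sorted(stray)[:5]}")
    N, n = len(uni), len(sig)
    rows = []
    for name, members in collection.items():
        K = len(uni.intersection(members))
        k = len(sig.intersection(members))
        if n == 0 or K == 0:
            p = 1.0
        else:
            p = float(sps.hypergeom.sf(k - 1, N, K, n))
        rows.append({"set_name": name, "set_size": K, "overlap_count": k,
                     "p": p})
    out = pd.DataFrame(rows)
    out["q"] = pstats.bh_fdr(out["p"].to_numpy())
    return out.sort_values("p", kind="stable").reset_index(drop=True)


def _running_es(order_scores: np.ndarray, hit: np.ndarray,
                weight_p: float) -> tuple[float, np.ndarray]:
    """Signed extremum of the weighted KS running sum for one ordering."""
    w = np.abs(order_scores) ** weight_p
    hit_w = np.where(hit, w, 0.0)
    total_hit = hit_w.sum()
    if total_hit == 0:
        # all hit weights zero (e.g. zero scores); fall back to unweighted
        hit_w = hit.astype(float)
        total_hit = hit_w.sum()
    n_miss = len(hit) - int(hit.sum())
    p_hit = np.cumsum(hit_w) / total_hit
    p_miss = (np.cumsum(~hit) / n_miss if n_miss
              else np.zeros(len(hit)))
    dev = p_hit - p_miss
    i = int(np.argmax(np.abs(dev)))
    return float(dev[i]), dev


def gsea_es(ranked_scores: pd.Series, gene_set, weight_p: float = 1.0,
            n_perm: int = 1000, seed: int = 0) -> dict:
    """GSEA enrichment score of ``gene_set`` in a ranked gene list.

    ``ranked_scores`` maps gene -> ranking score (higher = more associated
    with the positive class); genes are ordered by decreasing score. ES is
    the signed extremum of the running sum with hit increments weighted by
    |score|^weight_p. NES divides ES by the mean |ES| of same-signed
    gene-set permutations (random sets of the same size); p is the
    same-signed permutation tail frequency.
    """
    scores = ranked_scores.sort_values(ascending=False)
    genes = scores.index.to_numpy()
    hits = np.isin(genes, list(set(gene_set)))
    if not hits.any():
        raise ValueError("gene set does not intersect the ranked list")
    vals = scores.to_numpy(float)
    es, running = _running_es(vals, hits, weight_p)

    rng = np.random.default_rng(seed)
    k = int(hits.sum())
    null = np.empty(n_perm)
    for b in range(n_perm):
        idx = rng.choice(len(genes), size=k, replace=False)
        h = np.zeros(len(genes), bool)
        h[idx] = True
        null[b], _ = _running_es(vals, h, weight_p)
    same = null[np.sign(null) == np.sign(es)] if es != 0 else null
    if same.size == 0:
        nes = 0.0 if es == 0 else np.inf * np.sign(es)
        p = 1.0 / (n_perm + 1)
    else:
        nes = es / np.abs(same).mean()
        p = (1 + (np.abs(same) >= abs(es)).sum()) / (1 + same.size)
    return {"es": es, "nes": float(nes), "p": float(p),
            "running_sum": pd.DataFrame({"gene": genes, "score": vals,
                                         "hit": hits, "running_es": running})}


def ranking_scores(dge_table: pd.DataFrame) -> pd.Series:
    """Default GSEA ranking metric: signed -log10(p) x sign(log2fc)."""
    p = np.clip(dge_table["p"].to_numpy(float), 1e-300, None)
    s = -np.log10(p) * np.sign(dge_table["log2fc"].to_numpy(float))
    return pd.Series(s, index=dge_table["gene"].to_numpy())
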