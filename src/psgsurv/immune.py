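"""Association of PSG expression/status with immune-cell score profiles."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from psgsurv import stats as pstats

logger = logging.getLogger("psgsurv")


def psg_immune_correlation(expression: pd.DataFrame,
                           immune: pd.DataFrame) -> pd.DataFrame:
    """Spearman correlation of every gene in ``expression`` against every
    immune cell type, with BH-FDR over the full gene x type family.

    Returns a long table (gene, cell_type, rho, p, q); constant columns
    give NaN with a warning.
    """
    samples = [s for s in expression.columns if s in immune.index]
    if len(samples) < 10:
        raise ValueError("need at least 10 shared samples")
    expr = expression[samples]
    imm = immune.loc[samples]
    rows = []
    for gene in expr.index:
        x = expr.loc[gene].to_numpy(float)
        for cell in imm.columns:
            y = imm[cell].to_numpy(float)
            if np.unique(x).size == 1 or np.unique(y).size == 1:
                logger.warning("constant column in correlation: %s / %s",
                               gene, cell)
                rows.append({"gene": gene, "cell_type": cell,
                             "rho": np.nan, "p": np.nan})
                continue
            res = pstats.spearman(x, y)
            rows.append({"gene": gene, "cell_type": cell,
                         "rho": res["rho"], "p": res["p"]})
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    ok = out["p"].notna()
    if ok.any():
        out.loc[ok, "q"] = pstats.bh_fdr(out.loc[ok, "p"].to_numpy())
    return out


def group_difference(immune: pd.DataFrame, status: pd.Series) -> pd.DataFrame:
    """Per-cell-type Wilcoxon rank-sum between panel-positive and
    panel-negative samples, BH-FDR over the cell types.

    ``direction`` names the group with the higher median ("positive" /
    "negative"). The output includes a plot-ready ``minus_log10_q`` column.
    Results are invariant to cell-type column order (tests are per-column;
    BH is permutation-invariant).
    """
    status = status.reindex(immune.index)
    if status.isna().any():
        raise ValueError("status missing for some immune-table samples")
    pos = immune.loc[status.astype(bool).values]
    neg = immune.loc[~status.astype(bool).values]
    if pos.empty or neg.empty:
        raise ValueError("both status groups must be non-empty")
    rows = []
    for cell in immune.columns:
        res = pstats.wilcoxon_ranksum(pos[cell], neg[cell])
        direction = ("positive"
                     if pos[cell].median() >= neg[cell].median()
                     else "negative")
        rows.append({"cell_type": cell, "p": res["p"],
                     "direction": direction})
    out = pd.DataFrame(rows)
    out["q"] = pstats.bh_fdr(out["p"].to_numpy())
    out["minus_log10_q"] = -np.log10(np.clip(out["q"], 1e-300, None))
    return out
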