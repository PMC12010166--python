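"""Exhaustive combination-signature search over PSG gene panels.

Every 2- and 3-gene panel (45 and 120 for ten genes) is binarized with the
all-zero rule and tested by a sex-stratified log-rank test; BH-FDR is
applied within each panel-size family separately (the 120-test family
reproduces q = min_p x 120 for the top 3-gene panel). Validation of a
pre-registered panel on an external cohort is a single uncorrected
log-rank test.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd

from psgsurv import stats as pstats
from psgsurv.status import call_status

logger = logging.getLogger("psgsurv")


def enumerate_panels(genes, sizes=(2, 3)) -> list[tuple[str, ...]]:
    """All gene combinations of the requested sizes, lexicographically
    ordered and duplicate-free."""
    genes = sorted(set(genes))
    if len(genes) == 0:
        raise ValueError("no genes supplied")
    panels: list[tuple[str, ...]] = []
    for k in sorted(set(sizes)):
        if k > len(genes):
            raise ValueError(f"panel size {k} exceeds {len(genes)} genes")
        panels.extend(itertools.combinations(genes, k))
    return panels


def _stratum_clinical(clinical: pd.DataFrame, stratum: str) -> pd.DataFrame:
    if stratum not in {"male", "female", "both"}:
        raise ValueError(f"unknown stratum {stratum!r}")
    if stratum == "both":
        return clinical
    return clinical[clinical["sex"] == stratum]


def search(expression: pd.DataFrame, clinical: pd.DataFrame, genes,
           sizes=(2, 3), stratum: str = "female",
           small_group: int = 5) -> pd.DataFrame:
    """Evaluate every panel of the requested sizes within one sex stratum.

    Returns a table (panel, size, stratum, n_pos, n_neg, logrank_p,
    q_value, rank, small_group_flag) sorted by p (ties broken
    lexicographically by panel). Panels with an empty status group are
    recorded with NaN p and excluded from the FDR family.
    """
    clin = _stratum_clinical(clinical, stratum)
    if clin.empty:
        raise ValueError(f"stratum {stratum!r} is empty")
    expr = expression[clin["sample_id"].tolist()]
    time = clin["time"].to_numpy(float)
    event = clin["event"].to_numpy(int)

    rows = []
    for panel in enumerate_panels(genes, sizes):
        pos = call_status(expr, panel).to_numpy()
        n_pos, n_neg = int(pos.sum()), int((~pos).sum())
        if n_pos == 0 or n_neg == 0:
            logger.info("panel %s: empty status group, excluded from FDR",
                        "+".join(panel))
            p = np.nan
        else:
            p = pstats.km_logrank(time[pos], event[pos],
                                  time[~pos], event[~pos],
                                  curves=False)["p"]
        rows.append({
            "panel": "+".join(panel),
            "size": len(panel),
            "stratum": stratum,
            "n_pos": n_pos,
            "n_neg": n_neg,
            "logrank_p": p,
            "small_group_flag": min(n_pos, n_neg) < small_group,
        })
    out = pd.DataFrame(rows)
    out["q_value"] = np.nan
    for k in out["size"].unique():
        mask = (out["size"] == k) & out["logrank_p"].notna()
        if mask.any():
            out.loc[mask, "q_value"] = pstats.bh_fdr(
                out.loc[mask, "logrank_p"].to_numpy())
    out = out.sort_values(["logrank_p", "panel"],
                          na_position="last").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def validate_panel(panel, external_expression: pd.DataFrame,
                   external_clinical: pd.DataFrame,
                   stratum: str = "female") -> dict:
    """Pre-registered single log-rank test of one panel on an external
    cohort (no multiplicity correction)."""
    clin = _stratum_clinical(external_clinical, stratum)
    if clin.empty:
        raise ValueError(f"stratum {stratum!r} is empty in external cohort")
    expr = external_expression[clin["sample_id"].tolist()]
    pos = call_status(expr, panel).to_numpy()
    if pos.all() or not pos.any():
        raise ValueError("panel produces a single status group in the "
                         "external cohort")
    time = clin["time"].to_numpy(float)
    event = clin["event"].to_numpy(int)
    res = pstats.km_logrank(time[pos], event[pos], time[~pos], event[~pos])
    return {"panel": "+".join(panel), "stratum": stratum,
            "p": res["p"], "km_curves": res["km_curves"],
            "n_pos": int(pos.sum()), "n_neg": int((~pos).sum())}
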