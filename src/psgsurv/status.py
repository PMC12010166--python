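"""Binarized PSG+/- panel status.

A sample is panel-negative iff every gene in the panel has expression value
exactly 0 (no epsilon), and panel-positive otherwise — equivalently, the OR
of the single-gene calls. An optional threshold parameter is exposed for
sensitivity analyses but defaults to exact zero.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

logger = logging.getLogger("psgsurv")


def call_status(expression: pd.DataFrame, panel,
                threshold: float = 0.0) -> pd.Series:
    """Per-sample panel status: True = positive (any panel gene expressed).

    Parameters
    ----------
    expression : genes x samples matrix.
    panel : iterable of gene names; all must be present.
    threshold : a gene counts as expressed when its value is strictly
        greater than this (default 0, the no-expression convention).
    """
    panel = list(panel)
    if not panel:
        raise ValueError("panel must name at least one gene")
    missing = [g for g in panel if g not in expression.index]
    if missing:
        raise KeyError(f"panel genes absent from expression matrix: {missing}")
    status = (expression.loc[panel] > threshold).any(axis=0)
    status.name = "+".join(panel)
    return status


def status_frame(status: pd.Series) -> pd.DataFrame:
    """Long-form (sample_id, panel, status) table for serialization."""
    return pd.DataFrame({
        "sample_id": status.index,
        "panel": status.name,
        "status": ["positive" if s else "negative" for s in status],
    })


def write_status(status: pd.Series, path: str | Path) -> None:
    status_frame(status).to_csv(path, sep="\t", index=False)


def status_by_group(status: pd.Series, clinical: pd.DataFrame) -> pd.DataFrame:
    """2x2 counts of panel status (+/-) by sex.

    Rows ``positive``/``negative``, columns ``male``/``female``; column sums
    equal the stratum sizes. An empty stratum yields a zero column with a
    warning.
    """
    clin = clinical.set_index("sample_id").loc[status.index]
    out = pd.DataFrame(0, index=["positive", "negative"],
                       columns=["male", "female"])
    for sex in out.columns:
        mask = (clin["sex"] == sex).values
        if not mask.any():
            logger.warning("stratum %r is empty", sex)
            continue
        n_pos = int(status[mask].sum())
        out.loc["positive", sex] = n_pos
        out.loc["negative", sex] = int(mask.sum()) - n_pos
    return out
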