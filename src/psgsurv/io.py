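"""Readers/writers for the pipeline's tabular and graph formats.

All tables are tab-separated text. Expression is genes x samples with the
gene identifier in the first column; "no expression" is an exact 0 on the
stored scale and no re-normalization is ever applied. Sample identifiers
are matched case-sensitively. Every exclusion (missing follow-up,
unmatched samples) is logged with a count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("psgsurv")

CLINICAL_COLUMNS = ["sample_id", "sex", "age", "race", "stage", "time", "event"]


class ParseError(ValueError):
    """A malformed input file; the message names the offending location."""


def _check_unique(names, what: str, path) -> None:
    dup = pd.Index(names)[pd.Index(names).duplicated()].unique().tolist()
    if dup:
        raise ParseError(f"{path}: duplicate {what}: {dup[:5]}")


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples expression matrix.

    Raises :class:`ParseError` for duplicate gene/sample identifiers,
    negative or non-finite entries (naming the offending cell).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.columns.empty:
        raise ParseError(f"{path}: no sample columns in header")
    _check_unique(df.index, "gene ids", path)
    _check_unique(df.columns, "sample ids", path)
    values = df.to_numpy(dtype=float)
    bad = ~np.isfinite(values) | (values < 0)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ParseError(
            f"{path}: invalid expression value {values[i, j]!r} at "
            f"gene {df.index[i]!r}, sample {df.columns[j]!r}")
    df.index.name = "gene"
    return df.astype(float)


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene")


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read the per-sample clinical table; samples with missing follow-up
    time are excluded at load with a logged count."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing_cols = [c for c in ("sample_id", "sex", "time", "event")
                    if c not in df.columns]
    if missing_cols:
        raise ParseError(f"{path}: missing required columns {missing_cols}")
    _check_unique(df["sample_id"], "sample ids", path)
    df = drop_missing_followup(df)
    if (df["time"] < 0).any():
        bad = df.loc[df["time"] < 0, "sample_id"].iloc[0]
        raise ParseError(f"{path}: negative follow-up time for {bad!r}")
    if not df["event"].isin([0, 1]).all():
        raise ParseError(f"{path}: event indicator must be 0 or 1")
    bad_sex = set(df["sex"].dropna()) - {"male", "female"}
    if bad_sex:
        raise ParseError(f"{path}: unknown sex levels {sorted(bad_sex)}")
    return df.reset_index(drop=True)


def drop_missing_followup(clinical: pd.DataFrame) -> pd.DataFrame:
    """Drop samples whose follow-up time is missing, logging the count."""
    missing = clinical["time"].isna()
    if missing.any():
        logger.info("excluded %d samples with missing follow-up time",
                    int(missing.sum()))
    return clinical.loc[~missing].copy()


def write_clinical(clinical: pd.DataFrame, path: str | Path) -> None:
    clinical.to_csv(path, sep="\t", index=False)


def read_immune(path: str | Path) -> pd.DataFrame:
    """Samples x cell-type immune score table (first column sample_id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    _check_unique(df.index, "sample ids", path)
    _check_unique(df.columns, "cell types", path)
    values = df.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ParseError(f"{path}: non-finite immune score")
    if (values < 0).any():
        raise ParseError(f"{path}: negative immune score")
    return df.astype(float)


def write_immune(immune: pd.DataFrame, path: str | Path) -> None:
    immune.to_csv(path, sep="\t", index_label="sample_id")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT gene-set collection: name, description, members per line.

    Duplicate members within a set are deduplicated with a warning; a line
    with fewer than three fields or an empty member list is an error.
    """
    sets: dict[str, list[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected >= 3 tab-separated "
                             f"fields, got {len(fields)}")
        name, members = fields[0], [m for m in fields[2:] if m]
        if not members:
            raise ParseError(f"{path}:{lineno}: gene set {name!r} has no members")
        if name in sets:
            raise ParseError(f"{path}:{lineno}: duplicate set name {name!r}")
        unique = list(dict.fromkeys(members))
        if len(unique) != len(members):
            logger.warning("gene set %r: %d duplicate members removed",
                           name, len(members) - len(unique))
        sets[name] = unique
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, name] + list(members)) + "\n")


def read_edge_list(path: str | Path) -> list[tuple[str, str]]:
    """Two-column whitespace/tab-separated undirected edge list."""
    edges = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ParseError(f"{path}:{lineno}: expected two node names")
        edges.append((parts[0], parts[1]))
    return edges


def write_edge_list(edges, path: str | Path) -> None:
    with open(path, "w") as fh:
        for u, v in edges:
            fh.write(f"{u}\t{v}\n")


@dataclass
class CohortBundle:
    """Sample-aligned expression/clinical(/immune) views of one cohort."""

    expression: pd.DataFrame
    clinical: pd.DataFrame
    immune: pd.DataFrame | None
    n_dropped_expression: int
    n_dropped_clinical: int
    immune_skipped: bool

    @property
    def sample_ids(self) -> list[str]:
        return list(self.expression.columns)


def align_cohort(expression: pd.DataFrame, clinical: pd.DataFrame,
                 immune: pd.DataFrame | None = None) -> CohortBundle:
    """Intersect sample ids across inputs and order everything identically.

    Samples lacking follow-up time are removed; all exclusions are logged.
    An empty intersection is a hard error. Idempotent and order-stable:
    the output order follows the expression column order.
    """
    clinical = drop_missing_followup(clinical)
    keep = [s for s in expression.columns if s in set(clinical["sample_id"])]
    if immune is not None:
        immune_ids = set(immune.index)
        keep = [s for s in keep if s in immune_ids]
    if not keep:
        raise ValueError("no samples shared between expression and clinical "
                         "tables after exclusions")
    n_dropped_expr = expression.shape[1] - len(keep)
    n_dropped_clin = len(clinical) - len(keep)
    if n_dropped_expr or n_dropped_clin:
        logger.info("alignment dropped %d expression and %d clinical samples",
                    n_dropped_expr, n_dropped_clin)
    clin = (clinical.set_index("sample_id").loc[keep]
            .reset_index())
    imm = immune.loc[keep] if immune is not None else None
    return CohortBundle(
        expression=expression[keep],
        clinical=clin,
        immune=imm,
        n_dropped_expression=n_dropped_expr,
        n_dropped_clinical=n_dropped_clin,
        immune_skipped=immune is None,
    )
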