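"""Survival and association statistics.

Thin, validated wrappers with the conventions fixed once for the whole
pipeline: two-sided tests, alpha = 0.05, Pearson chi-squared without
continuity correction, Wilcoxon rank-sum with tie correction (exact null
at small n without ties), Benjamini-Hochberg FDR, Cox proportional hazards
with Efron tie handling, and Harrell's concordance counting tied risks
as 1/2.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from lifelines.utils import concordance_index
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("psgsurv")

ALPHA = 0.05


def km_curve(time, event) -> pd.DataFrame:
    """Kaplan-Meier survival step function: columns ``time``, ``survival``."""
    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(time, float), np.asarray(event, int))
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.values,
                         "survival": sf.iloc[:, 0].values})


def km_logrank(time_a, event_a, time_b, event_b, curves: bool = True) -> dict:
    """Two-group log-rank test (chi-squared, 1 df) plus KM curves.

    Both groups must be non-empty and contribute at least one event in
    total. ``curves=False`` skips the KM estimates (used in bulk screens).
    """
    time_a, event_a = np.asarray(time_a, float), np.asarray(event_a, int)
    time_b, event_b = np.asarray(time_b, float), np.asarray(event_b, int)
    if time_a.size == 0 or time_b.size == 0:
        raise ValueError("both groups must be non-empty")
    if event_a.sum() + event_b.sum() == 0:
        raise ValueError("log-rank test requires at least one event")
    res = logrank_test(time_a, time_b, event_observed_A=event_a,
                       event_observed_B=event_b)
    out = {"chi2": float(res.test_statistic), "p": float(res.p_value)}
    if curves:
        out["km_curves"] = {"a": km_curve(time_a, event_a),
                            "b": km_curve(time_b, event_b)}
    return out


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values (monotone, capped at 1)."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p
    if np.isnan(p).any():
        raise ValueError("NaN p-value passed to BH adjustment")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def chisq_independence(counts) -> dict:
    """Pearson chi-squared test of independence, no continuity correction."""
    table = np.asarray(counts, float)
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero margin")
    res = sps.chi2_contingency(table, correction=False)
    return {"chi2": float(res.statistic), "df": int(res.dof),
            "p": float(res.pvalue)}


def wilcoxon_ranksum(x, y) -> dict:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Uses the exact null distribution at small n without ties and the
    tie-corrected normal approximation otherwise. Completely tied inputs
    yield p = 1 with a warning.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:
        logger.warning("all values tied across both samples; p set to 1")
        return {"statistic": float(x.size * y.size / 2), "p": 1.0}
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return {"statistic": float(res.statistic), "p": float(res.pvalue)}


def spearman(x, y) -> dict:
    """Spearman rank correlation with average ranks for ties and the
    t-approximation p-value."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired vectors of length >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("Spearman correlation undefined for a constant vector")
    rho, p = sps.spearmanr(x, y)
    return {"rho": float(rho), "p": float(p)}


def _fit_cox(df: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    cph = CoxPHFitter()
    try:
        cph.fit(df[covariates + ["time", "event"]], duration_col="time",
                event_col="event")
    except Exception as exc:  # convergence / separation
        raise RuntimeError(
            f"Cox model failed for covariates {covariates}: {exc}") from exc
    out = cph.summary
    return pd.DataFrame({
        "feature": out.index,
        "hazard_ratio": np.exp(out["coef"]).values,
        "ci_low": np.exp(out["coef lower 95%"]).values,
        "ci_high": np.exp(out["coef upper 95%"]).values,
        "p": out["p"].values,
    })


def cox_fit(features: pd.DataFrame, time, event,
            mode: str = "univariate",
            combinations: dict[str, list[str]] | None = None,
            redundancy_rho: float = 0.6) -> pd.DataFrame:
    """Cox proportional-hazards estimates (Efron ties, Wald p, 95% CI).

    ``mode="univariate"`` fits each feature alone. ``mode="multivariate"``
    first runs the univariate screen, keeps features with p < 0.05, then
    applies the redundancy-exclusion rule: when a combination feature and
    its constituents (given by ``combinations``) both pass the screen, the
    constituents whose rank correlation with the combination exceeds
    ``redundancy_rho`` are dropped. Exactly duplicated features are reduced
    to one (logged).

    Returns a table (feature, hazard_ratio, ci_low, ci_high, p, model).
    """
    features = features.copy()
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    constant = [c for c in features.columns if features[c].nunique() <= 1]
    if constant:
        raise ValueError(f"constant features cannot enter a Cox model: "
                         f"{constant}")
    df = features.reset_index(drop=True)
    df["time"], df["event"] = time, event
    if event.sum() == 0:
        raise ValueError("Cox model requires at least one event")

    uni = pd.concat([_fit_cox(df, [c]) for c in features.columns],
                    ignore_index=True)
    uni["model"] = "univariate"
    if mode == "univariate":
        return uni

    selected = uni.loc[uni["p"] < ALPHA, "feature"].tolist()
    if not selected:
        logger.warning("no features passed the univariate p < .05 screen")
        return uni

    # drop exact duplicates, keeping the first occurrence
    kept: list[str] = []
    for c in selected:
        if any(features[c].equals(features[k]) for k in kept):
            logger.info("dropping %r from multivariate model: duplicate", c)
            continue
        kept.append(c)
    selected = kept

    if combinations:
        for combo, parts in combinations.items():
            if combo not in selected:
                continue
            for part in parts:
                if part in selected:
                    rho = spearman(features[combo], features[part])["rho"]
                    if abs(rho) > redundancy_rho:
                        logger.info(
                            "dropping %r from multivariate model: rank "
                            "correlation %.2f with %r", part, rho, combo)
                        selected.remove(part)

    if event.sum() < len(selected):
        logger.warning("fewer events (%d) than multivariate features (%d)",
                       int(event.sum()), len(selected))
    multi = _fit_cox(df, selected)
    multi["model"] = "multivariate"
    return pd.concat([uni, multi], ignore_index=True)


def concordance(predicted_risk, time, event) -> float:
    """Harrell's C-index: fraction of comparable pairs whose risk ordering
    agrees with the survival ordering (tied risks count 1/2)."""
    risk = np.asarray(predicted_risk, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    if risk.size != time.size:
        raise ValueError("one risk score per sample required")
    if event.sum() == 0:
        raise ValueError("no comparable pairs: no events observed")
    try:
        return float(concordance_index(time, -risk, event))
    except ZeroDivisionError as exc:
        raise ValueError("no comparable pairs") from exc
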