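"""Elastic-net Cox predictive models with PCA-derived feature blocks.

The model is the elastic-net-penalized Cox partial likelihood
(`sksurv.linear_model.CoxnetSurvivalAnalysis`) with the L1 ratio fixed at
0.5 and the penalty strength chosen by 10-fold cross-validated Harrell
concordance. Feature blocks: the binary panel indicator, top principal
components of the immune-score table, and top principal components of a
pathway gene block — each PCA centered on training data only and the same
centering reused when projecting external samples (no leakage).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA
from sklearn.model_selection import KFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from psgsurv.stats import concordance

logger = logging.getLogger("psgsurv")


def stratified_split(clinical: pd.DataFrame, fraction: float = 2 / 3,
                     seed: int = 0, max_tries: int = 1000,
                     max_event_diff: float = 0.05,
                     max_ks: float = 0.15) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random train/validation split balanced on outcome distribution.

    Resamples up to ``max_tries`` seeds until the event-rate difference
    between the sets is <= ``max_event_diff`` and the follow-up-time KS
    statistic is <= ``max_ks``; otherwise warns and returns the best split
    found. Deterministic given ``seed``.
    """
    n = len(clinical)
    if n < 30:
        raise ValueError("need at least 30 samples to split")
    n_train = int(round(fraction * n))
    rng = np.random.default_rng(seed)
    event = clinical["event"].to_numpy(int)
    time = clinical["time"].to_numpy(float)
    best, best_score = None, np.inf
    for _ in range(max_tries):
        perm = rng.permutation(n)
        tr, va = perm[:n_train], perm[n_train:]
        diff = abs(event[tr].mean() - event[va].mean())
        ks = sps.ks_2samp(time[tr], time[va]).statistic
        score = max(diff / max_event_diff, ks / max_ks)
        if score < best_score:
            best, best_score = (tr, va), score
        if diff <= max_event_diff and ks <= max_ks:
            break
    else:
        logger.warning("split constraints not met after %d tries "
                       "(best score %.2f); using best split",
                       max_tries, best_score)
    tr, va = best
    return (clinical.iloc[np.sort(tr)].reset_index(drop=True),
            clinical.iloc[np.sort(va)].reset_index(drop=True))


@dataclass
class PCABlock:
    """A PCA projection fitted on training data and reusable externally."""

    columns: list[str]
    pca: PCA
    prefix: str

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        z = self.pca.transform(table[self.columns].to_numpy(float))
        cols = [f"{self.prefix}_PC{i + 1}" for i in range(z.shape[1])]
        return pd.DataFrame(z, index=table.index, columns=cols)


def fit_pca_block(table: pd.DataFrame, k: int = 3,
                  prefix: str = "block") -> PCABlock:
    """Centered PCA on the columns of ``table``, keeping the top ``k``
    components. Constant columns are dropped with a warning. External
    samples are projected with the training means."""
    cols = list(table.columns)
    constant = [c for c in cols if table[c].nunique() <= 1]
    if constant:
        logger.warning("dropping %d constant columns from PCA block",
                       len(constant))
        cols = [c for c in cols if c not in constant]
    k_eff = min(k, len(cols), len(table))
    if k_eff < 1:
        raise ValueError("no usable columns for PCA")
    pca = PCA(n_components=k_eff)
    pca.fit(table[cols].to_numpy(float))
    return PCABlock(columns=cols, pca=pca, prefix=prefix)


@dataclass
class ElasticCoxModel:
    """A fitted elastic-net Cox model with its chosen penalty."""

    estimator: CoxnetSurvivalAnalysis
    feature_names: list[str]
    alpha: float
    l1_ratio: float
    cv_concordance: float
    coefficients: pd.Series = field(repr=False)

    def predict_risk(self, features: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.feature_names if c not in features.columns]
        if missing:
            raise KeyError(f"missing model features: {missing}")
        x = features[self.feature_names].to_numpy(float)
        return self.estimator.predict(x, alpha=self.alpha)


def fit_elastic_cox(features: pd.DataFrame, time, event,
                    cv_folds: int = 10, seed: int = 0,
                    l1_ratio: float = 0.5) -> ElasticCoxModel:
    """Elastic-net Cox with penalty strength selected by cross-validated
    concordance over the estimator's own alpha path.

    With a single feature the penalty path still runs, so the returned
    coefficient may be shrunk but keeps its sign. If every alpha zeroes
    all coefficients, a warning is emitted and the null model (largest
    alpha) is returned.
    """
    x = features.to_numpy(float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    y = Surv.from_arrays(event=event.astype(bool), time=time)
    if event.sum() < 2 * cv_folds:
        logger.warning("fewer than 2 events per fold on average")
    path = CoxnetSurvivalAnalysis(l1_ratio=l1_ratio, alpha_min_ratio=0.01)
    with warnings.catch_warnings():
        # the saturated end of the penalty path legitimately zeroes
        # every coefficient; that is not a user error here
        warnings.filterwarnings("ignore", message="all coefficients are zero")
        path.fit(x, y)
    alphas = np.asarray(path.alphas_)

    rng = np.random.default_rng(seed)
    kf = KFold(n_splits=cv_folds, shuffle=True,
               random_state=int(rng.integers(2**31)))
    scores = np.zeros(len(alphas))
    counts = np.zeros(len(alphas))
    for tr, te in kf.split(x):
        if event[te].sum() == 0 or event[tr].sum() == 0:
            continue
        est = CoxnetSurvivalAnalysis(l1_ratio=l1_ratio, alphas=alphas,
                                     fit_baseline_model=False)
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore",
                                    message="all coefficients are zero")
            est.fit(x[tr], y[tr])
        for i, a in enumerate(alphas):
            risk = est.predict(x[te], alpha=a)
            if np.ptp(risk) == 0:
                c = 0.5
            else:
                c = concordance(risk, time[te], event[te])
            scores[i] += c
            counts[i] += 1
    mean_cv = np.where(counts > 0, scores / np.maximum(counts, 1), 0.5)
    best = int(np.argmax(mean_cv))
    alpha = float(alphas[best])
    coefs = pd.Series(path.coef_[:, best], index=features.columns)
    if (coefs == 0).all():
        logger.warning("all coefficients zero at every penalty; "
                       "returning the null model")
    return ElasticCoxModel(
        estimator=path, feature_names=list(features.columns),
        alpha=alpha, l1_ratio=l1_ratio,
        cv_concordance=float(mean_cv[best]), coefficients=coefs)


def evaluate(model: ElasticCoxModel, features: pd.DataFrame,
             time, event) -> float:
    """Harrell's C of the model's risk scores on an external cohort."""
    risk = model.predict_risk(features)
    if np.ptp(risk) == 0:
        return 0.5
    return concordance(risk, np.asarray(time, float),
                       np.asarray(event, int))
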