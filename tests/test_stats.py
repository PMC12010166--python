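"""Survival/association statistics against closed forms and brute force."""

import numpy as np
import pandas as pd
import pytest

from psgsurv import stats as pstats
from tests import oracles


class TestChiSquared:
    @pytest.mark.parametrize("table,expected_p", [
        ([[47, 61], [188, 210]], 0.4921),   # PSG1 counts by sex
        ([[15, 14], [220, 257]], 0.5570),   # PSG2
        ([[66, 69], [169, 202]], 0.5057),   # PSG3
        ([[46, 47], [189, 224]], 0.5179),   # PSG5
        ([[28, 40], [207, 231]], 0.3493),   # PSG8
        ([[50, 59], [185, 212]], 0.8933),   # PSG9
    ])
    def test_published_contingency_pvalues(self, table, expected_p):
        # Pearson chi-squared without continuity correction reproduces the
        # published sex-by-status p-values (PSG1/2/3/8 to 4 decimals;
        # PSG5/PSG9 carry a 4th-decimal rounding wobble in the source)
        assert pstats.chisq_independence(table)["p"] == \
            pytest.approx(expected_p, abs=1e-3)

    def test_perfect_independence(self):
        res = pstats.chisq_independence([[10, 10], [25, 25]])
        assert res["chi2"] == pytest.approx(0.0)
        assert res["p"] == pytest.approx(1.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            pstats.chisq_independence([[0, 0], [5, 3]])


class TestBH:
    def test_single_p_unchanged(self):
        assert pstats.bh_fdr([0.04])[0] == pytest.approx(0.04)

    def test_min_p_times_family_size(self):
        # q of the smallest of 120 p-values is p * 120 when it is rank 1
        p = np.concatenate([[8.67e-6], np.linspace(0.2, 0.99, 119)])
        q = pstats.bh_fdr(p)
        assert q[0] == pytest.approx(8.67e-6 * 120, rel=1e-9)
        assert q[0] == pytest.approx(0.0010, abs=5e-5)

    def test_matches_hand_computation_and_permutation(self):
        rng = np.random.default_rng(2)
        p = rng.random(40) ** 2
        q = pstats.bh_fdr(p)
        assert np.allclose(q, oracles.bh_by_hand(p))
        perm = rng.permutation(40)
        assert np.allclose(pstats.bh_fdr(p[perm]), q[perm])

    def test_monotone_in_rank(self):
        p = np.sort(np.random.default_rng(3).random(25))
        assert (np.diff(pstats.bh_fdr(p)) >= -1e-12).all()

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            pstats.bh_fdr([0.1, np.nan])


class TestLogrank:
    def test_identical_groups_null(self):
        t = [1, 2, 3, 4.0]
        e = [1, 0, 1, 1]
        res = pstats.km_logrank(t, e, t, e)
        assert res["chi2"] == pytest.approx(0.0, abs=1e-12)
        assert res["p"] == pytest.approx(1.0)

    def test_against_permutation_null_small_n(self):
        rng = np.random.default_rng(4)
        time = rng.exponential(10, 20)
        event = rng.integers(0, 2, 20)
        event[0] = 1
        group = np.array([0] * 10 + [1] * 10)
        res = pstats.km_logrank(time[group == 1], event[group == 1],
                                time[group == 0], event[group == 0])
        perm_p = oracles.permutation_logrank_p(time, event, group,
                                               n_perm=10_000, seed=0)
        se = np.sqrt(perm_p * (1 - perm_p) / 10_000)
        assert abs(res["p"] - perm_p) <= 3 * se + 0.01

    def test_zero_events_rejected(self):
        with pytest.raises(ValueError):
            pstats.km_logrank([1, 2], [0, 0], [3, 4], [0, 0])

    def test_km_curve_properties(self):
        rng = np.random.default_rng(5)
        curve = pstats.km_curve(rng.exponential(5, 50),
                                rng.integers(0, 2, 50))
        s = curve["survival"].to_numpy()
        assert s[0] == pytest.approx(1.0)
        assert (np.diff(s) <= 1e-12).all()


class TestWilcoxon:
    def test_identical_multisets(self):
        x = [1, 2, 3, 4.0]
        assert pstats.wilcoxon_ranksum(x, list(x))["p"] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_enumeration_small_n(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=6)
        y = rng.normal(0.8, 1, size=7)
        p = pstats.wilcoxon_ranksum(x, y)["p"]
        assert p == pytest.approx(oracles.exact_ranksum_p(x, y), abs=1e-9)

    def test_all_tied_warns_p_one(self):
        assert pstats.wilcoxon_ranksum([2, 2], [2, 2, 2])["p"] == 1.0

    def test_power_on_shifted_normals(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            p = pstats.wilcoxon_ranksum(rng.normal(0, 1, 100),
                                        rng.normal(1, 1, 100))["p"]
            hits += p < 0.01
        assert hits >= 19


class TestSpearman:
    def test_perfect_monotone(self):
        x = [1, 3, 2, 5, 4.0]
        assert pstats.spearman(x, x)["rho"] == pytest.approx(1.0)
        assert pstats.spearman(x, [-v for v in x])["rho"] == \
            pytest.approx(-1.0)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            pstats.spearman([1, 1, 1], [1, 2, 3])


class TestCox:
    def test_null_feature_ci_covers_one(self):
        covered = 0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            n = 150
            x = rng.integers(0, 2, n).astype(float)
            res = pstats.cox_fit(
                pd.DataFrame({"x": x}), rng.exponential(10, n),
                rng.integers(0, 2, n))
            covered += res["ci_low"].iloc[0] <= 1 <= res["ci_high"].iloc[0]
        assert covered >= 24  # ~95% coverage, allow sampling slack

    def test_duplicated_feature_dropped_in_multivariate(self):
        rng = np.random.default_rng(6)
        n = 200
        x = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(10 / (1 + 2 * x))
        res = pstats.cox_fit(pd.DataFrame({"x1": x, "x2": x.copy()}),
                             t, np.ones(n, int), mode="multivariate")
        multi = res[res["model"] == "multivariate"]
        assert list(multi["feature"]) == ["x1"]

    def test_redundancy_rule_drops_correlated_constituent(self):
        rng = np.random.default_rng(7)
        n = 300
        a = (rng.random(n) < 0.25).astype(float)
        b = (rng.random(n) < 0.1).astype(float)
        combo = np.maximum(a, b)
        t = rng.exponential(10 / (1 + 2 * combo))
        res = pstats.cox_fit(
            pd.DataFrame({"combo": combo, "a": a, "b": b}),
            t, np.ones(n, int), mode="multivariate",
            combinations={"combo": ["a", "b"]})
        multi = set(res.loc[res["model"] == "multivariate", "feature"])
        assert "combo" in multi
        assert "a" not in multi  # rho(a, combo) > 0.6 given 0.25/0.35 overlap

    def test_constant_feature_rejected(self):
        with pytest.raises(ValueError):
            pstats.cox_fit(pd.DataFrame({"x": [1.0, 1.0, 1.0]}),
                           [1, 2, 3], [1, 1, 0])

    def test_score_agreement_with_logrank_on_binary_covariate(self):
        # Cox Wald chi2 on one binary covariate tracks the log-rank chi2
        rng = np.random.default_rng(8)
        n = 2000
        x = rng.integers(0, 2, n)
        t = rng.exponential(10 / (1 + x))
        e = (t < rng.exponential(30, n)).astype(int)
        t = np.minimum(t, 60)
        res = pstats.cox_fit(pd.DataFrame({"x": x.astype(float)}), t, e)
        z = np.log(res["hazard_ratio"].iloc[0]) \
            / (np.log(res["ci_high"].iloc[0] / res["hazard_ratio"].iloc[0])
               / 1.959964)
        lr = pstats.km_logrank(t[x == 1], e[x == 1],
                               t[x == 0], e[x == 0])["chi2"]
        assert z**2 == pytest.approx(lr, rel=0.05)


class TestConcordance:
    def test_perfect_ranking(self):
        t = np.array([5, 3, 8, 1, 9.0])
        assert pstats.concordance(-t, t, np.ones(5, int)) == 1.0

    def test_random_scores_near_half(self):
        cs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            cs.append(pstats.concordance(rng.random(200),
                                         rng.exponential(5, 200),
                                         rng.integers(0, 2, 200)))
        assert abs(np.mean(cs) - 0.5) < 0.05

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_pairs(self, seed):
        rng = np.random.default_rng(seed)
        n = 40
        risk = rng.choice([0.0, 0.5, 1.0], n)  # force ties
        time = np.round(rng.exponential(5, n), 1)
        event = rng.integers(0, 2, n)
        event[0] = 1
        assert pstats.concordance(risk, time, event) == pytest.approx(
            oracles.brute_concordance(risk, time, event), abs=1e-12)
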