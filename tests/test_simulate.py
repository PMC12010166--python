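"""Synthetic-cohort generator: determinism, marginal structure, calibration."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest, spearmanr

from psgsurv import stats as pstats
from psgsurv.simulate import (DEFAULT_IMMUNE_SHIFTS, SimulationConfig,
                              joint_zero_probability, luad_config,
                              make_fixture_graph, simulate_cohort,
                              simulate_expression, simulate_immune,
                              simulate_survival)
from psgsurv.status import call_status


def test_seed_determinism_bytes():
    cfg = luad_config(seed=5, n_samples=40, n_background_genes=10)
    a, b = simulate_cohort(cfg), simulate_cohort(cfg)
    assert a.expression.to_csv() == b.expression.to_csv()
    assert a.clinical.to_csv() == b.clinical.to_csv()
    assert a.immune.to_csv() == b.immune.to_csv()
    assert a.graph_edges == b.graph_edges


def test_zero_inflation_one_gives_all_zero_psg():
    cfg = SimulationConfig(seed=0, n_samples=20, zero_inflation=1.0,
                           n_background_genes=0)
    expr = simulate_expression(cfg)
    assert (expr.loc[list(cfg.psg_genes)].to_numpy() == 0).all()


def test_rejects_tiny_cohorts():
    with pytest.raises(ValueError):
        simulate_expression(SimulationConfig(n_samples=5))


def test_latent_correlation_recovered_without_zeros():
    # equicorrelation contract: mean off-diagonal Spearman within +-0.15
    # of the latent target at large n (checked across a few seeds)
    means = []
    for seed in range(1, 6):
        cfg = SimulationConfig(seed=seed, n_samples=1000, zero_inflation=0.0,
                               latent_correlation=0.6, n_background_genes=0)
        expr = simulate_expression(cfg)
        rho = spearmanr(expr.to_numpy().T).statistic
        means.append(rho[np.triu_indices(10, 1)].mean())
    assert all(0.45 <= m <= 0.75 for m in means)


def test_panel_negative_fraction_matches_cohort_target():
    # the 3-gene panel should be all-zero in ~70% of samples (70.1% +- 5)
    fractions = []
    for seed in range(3):
        cfg = luad_config(seed=seed, n_samples=1000, n_background_genes=0)
        expr = simulate_expression(cfg)
        neg = ~call_status(expr, cfg.panel_genes)
        fractions.append(neg.mean())
    assert abs(np.mean(fractions) - 0.701) < 0.05


def test_joint_zero_quadrature_matches_monte_carlo():
    # the calibration integral agrees with brute-force simulation
    rng = np.random.default_rng(0)
    lam = np.array([0.7, 0.5, 0.8])
    pis = np.array([0.8, 0.9, 0.7])
    f = rng.standard_normal(200_000)
    z = lam[:, None] * f + np.sqrt(1 - lam**2)[:, None] \
        * rng.standard_normal((3, 200_000))
    from scipy.stats import norm
    mc = (z < norm.ppf(pis)[:, None]).all(axis=0).mean()
    assert abs(joint_zero_probability(pis, lam) - mc) < 0.005


def test_survival_null_logrank_uniform():
    # with no hazard effect, log-rank p over seeds should look uniform
    ps = []
    for seed in range(60):
        cfg = SimulationConfig(seed=seed, n_samples=120,
                               female_hazard_ratio=1.0,
                               n_background_genes=0)
        expr = simulate_expression(cfg)
        clin = simulate_survival(expr, cfg)
        pos = call_status(expr, cfg.panel_genes).to_numpy()
        if pos.sum() < 2 or (~pos).sum() < 2:
            continue
        t = clin["time"].to_numpy()
        e = clin["event"].to_numpy()
        ps.append(pstats.km_logrank(t[pos], e[pos], t[~pos], e[~pos])["p"])
    assert kstest(ps, "uniform").pvalue > 0.01


def test_admin_censor_zero_censors_everything():
    cfg = SimulationConfig(seed=1, n_samples=30, admin_censor_time=0.0,
                           n_background_genes=0)
    clin = simulate_survival(simulate_expression(cfg), cfg)
    assert (clin["time"] == 0).all()
    assert (clin["event"] == 0).all()


def test_female_hazard_ratio_recovered_by_cox():
    # injected HR 2.45 recovered within [1.6, 3.7] in >= 80% of seeds
    hits = 0
    n_seeds = 25
    for seed in range(n_seeds):
        cfg = luad_config(seed=seed, n_samples=271, female_fraction=1.0,
                          n_background_genes=0)
        expr = simulate_expression(cfg)
        clin = simulate_survival(expr, cfg)
        feat = call_status(expr, cfg.panel_genes).astype(float) \
            .rename("panel").to_frame().reset_index(drop=True)
        res = pstats.cox_fit(feat, clin["time"], clin["event"])
        hits += 1.6 <= res["hazard_ratio"].iloc[0] <= 3.7
    assert hits / n_seeds >= 0.8


def test_immune_rows_on_simplex(small_cohort):
    sums = small_cohort.immune.sum(axis=1)
    assert np.allclose(sums, 1.0, atol=1e-9)
    assert (small_cohort.immune.to_numpy() >= 0).all()


def test_immune_null_shift_rarely_significant():
    # no shift -> at most a couple of the 22 types reach FDR < 0.05
    from psgsurv.immune import group_difference
    cfg = SimulationConfig(seed=3, n_samples=200, immune_shift=0.0,
                           n_background_genes=0)
    expr = simulate_expression(cfg)
    st = call_status(expr, cfg.panel_genes)
    imm = simulate_immune(cfg, st)
    diff = group_difference(imm, st)
    assert (diff["q"] < 0.05).sum() <= 2


def test_fixture_graph_shape_and_determinism():
    cfg = SimulationConfig(seed=9)
    edges = make_fixture_graph(cfg)
    assert edges == make_fixture_graph(cfg)
    import networkx as nx
    g = nx.Graph(edges)
    assert g.number_of_nodes() == 64
    assert nx.is_connected(g)
    small = nx.Graph(make_fixture_graph(cfg, n_interactors=0))
    assert small.number_of_nodes() == 10
    assert nx.is_connected(small)


def test_cohort_roundtrip_write(tmp_path, small_cohort):
    from psgsurv import io
    small_cohort.write(tmp_path)
    expr = io.read_expression(tmp_path / "expression.tsv")
    pd.testing.assert_frame_equal(expr, small_cohort.expression,
                                  check_names=False)
    clin = io.read_clinical(tmp_path / "clinical.tsv")
    assert list(clin["sample_id"]) == list(small_cohort.clinical["sample_id"])
    edges = io.read_edge_list(tmp_path / "ppi_edges.tsv")
    assert [tuple(e) for e in edges] == small_cohort.graph_edges


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        SimulationConfig(female_fraction=1.5)
    with pytest.raises(ValueError):
        SimulationConfig(zero_inflation=-0.1)
    with pytest.raises(ValueError):
        SimulationConfig(baseline_hazard=0.0)
    with pytest.raises(ValueError):
        SimulationConfig(n_psg_genes=2,
                         panel_genes=("PSG1", "PSG2", "PSG3"))
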