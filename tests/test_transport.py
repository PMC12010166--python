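"""Graph W1: Beckmann LP vs Kantorovich oracle, metric properties,
pair-class analysis."""

import numpy as np
import pandas as pd
import pytest

from psgsurv import transport
from psgsurv.simulate import SimulationConfig, make_fixture_graph
from tests import oracles


@pytest.fixture(scope="module")
def triangle():
    return transport.build_graph([("A", "B"), ("B", "C"), ("A", "C")])


class TestBuildGraph:
    def test_triangle_incidence(self, triangle):
        assert triangle.n_nodes == 3 and triangle.n_edges == 3
        D = triangle.incidence
        assert D.shape == (3, 3)
        assert np.allclose(D.sum(axis=0), 0)
        assert set(np.unique(D)) == {-1.0, 0.0, 1.0}

    def test_duplicate_edges_deduplicated(self):
        g = transport.build_graph([("A", "B"), ("B", "A"), ("B", "C")])
        assert g.n_edges == 2

    def test_disconnected_rejected(self):
        with pytest.raises(ValueError, match="disconnected"):
            transport.build_graph([("A", "B"), ("C", "D")])

    def test_self_loop_rejected(self):
        with pytest.raises(ValueError, match="self-loop"):
            transport.build_graph([("A", "A"), ("A", "B")])

    def test_fixture_graph_valid(self):
        g = transport.build_graph(make_fixture_graph(SimulationConfig()))
        assert g.n_nodes == 64


class TestMeasures:
    def test_uniform_for_equal_and_zero_profiles(self, triangle):
        expr = pd.DataFrame({"s1": [2.0, 2.0, 2.0], "s2": [0.0, 0.0, 0.0]},
                            index=["A", "B", "C"])
        for s in ("s1", "s2"):
            mu = transport.expression_to_measure(expr, s, triangle)
            assert np.allclose(mu, 1 / 3)

    def test_normalized_for_random_profiles(self, triangle):
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(rng.random((3, 5)), index=["A", "B", "C"],
                            columns=[f"s{i}" for i in range(5)])
        for s in expr.columns:
            mu = transport.expression_to_measure(expr, s, triangle)
            assert mu.sum() == pytest.approx(1.0, abs=1e-12)
            assert (mu > 0).all()


class TestW1:
    def test_identical_measures_zero(self, triangle):
        mu = np.array([0.2, 0.3, 0.5])
        assert transport.w1_distance(triangle, mu, mu).objective == \
            pytest.approx(0.0, abs=1e-9)

    def test_path_graph_point_masses(self):
        g = transport.build_graph([("A", "B"), ("B", "C")])
        mu = np.zeros(3)
        nu = np.zeros(3)
        mu[g.nodes.index("A")] = 1.0
        nu[g.nodes.index("C")] = 1.0
        sol = transport.w1_distance(g, mu, nu)
        assert sol.objective == pytest.approx(2.0, abs=1e-9)
        # divergence constraint holds
        assert np.abs(mu - nu - g.incidence @ sol.flux).max() < 1e-6

    def test_mass_mismatch_rejected(self, triangle):
        with pytest.raises(ValueError, match="mass mismatch"):
            transport.w1_distance(triangle, np.array([0.5, 0.3, 0.2]),
                                  np.array([0.5, 0.3, 0.4]))

    @pytest.mark.parametrize("seed", range(25))
    def test_beckmann_equals_kantorovich(self, seed):
        rng = np.random.default_rng(seed)
        edges, nodes = oracles.random_connected_graph(rng)
        g = transport.build_graph(edges)
        mu = oracles.random_measure(rng, g.n_nodes)
        nu = oracles.random_measure(rng, g.n_nodes)
        beckmann = transport.w1_distance(g, mu, nu).objective
        mu_s = pd.Series(mu, index=g.nodes)
        nu_s = pd.Series(nu, index=g.nodes)
        kant = oracles.kantorovich_w1(edges, mu_s[g.nodes].to_numpy(),
                                      nu_s[g.nodes].to_numpy())
        assert beckmann == pytest.approx(kant, abs=1e-6)

    @pytest.mark.parametrize("seed", range(10))
    def test_metric_properties(self, seed):
        rng = np.random.default_rng(100 + seed)
        edges, _ = oracles.random_connected_graph(rng)
        g = transport.build_graph(edges)
        mu = oracles.random_measure(rng, g.n_nodes)
        nu = oracles.random_measure(rng, g.n_nodes)
        pi = oracles.random_measure(rng, g.n_nodes)
        d = lambda a, b: transport.w1_distance(g, a, b).objective
        assert d(mu, nu) == pytest.approx(d(nu, mu), abs=1e-7)
        assert d(mu, pi) <= d(mu, nu) + d(nu, pi) + 1e-7
        assert d(mu, mu) == pytest.approx(0.0, abs=1e-9)

    def test_orientation_invariance(self):
        # flipping edge orientations in D leaves the objective unchanged
        g = transport.build_graph([("A", "B"), ("B", "C"), ("A", "C"),
                                   ("C", "D")])
        rng = np.random.default_rng(3)
        mu = oracles.random_measure(rng, g.n_nodes)
        nu = oracles.random_measure(rng, g.n_nodes)
        base = transport.w1_distance(g, mu, nu).objective
        flipped = transport.PPIGraph(nodes=g.nodes, edges=g.edges,
                                     incidence=-g.incidence)
        assert transport.w1_distance(flipped, mu, nu).objective == \
            pytest.approx(base, abs=1e-8)


class TestPairAnalysis:
    def _cohort(self, n=16, seed=0, perturb_dead=True):
        rng = np.random.default_rng(seed)
        edges = make_fixture_graph(SimulationConfig(seed=seed),
                                   n_interactors=5)
        g = transport.build_graph(edges)
        dead = np.array([False] * (n // 2) + [True] * (n - n // 2))
        base = rng.random(g.n_nodes) + 0.5
        cols = {}
        for i in range(n):
            profile = base + 0.05 * rng.standard_normal(g.n_nodes)
            if perturb_dead and dead[i]:
                profile = profile + rng.permutation(g.n_nodes) / \
                    g.n_nodes * 2.0
            cols[f"s{i}"] = np.clip(profile, 0, None)
        expr = pd.DataFrame(cols, index=g.nodes)
        clin = pd.DataFrame({
            "sample_id": list(cols), "sex": ["female"] * n,
            "time": np.concatenate([rng.uniform(10, 40, n // 2),
                                    rng.uniform(10, 40, n - n // 2)]),
            "event": dead.astype(int)})
        return g, expr, clin

    def test_pair_count_combinatorics(self):
        g, expr, clin = self._cohort(n=12, seed=1)
        res = transport.pairwise_distance_analysis(g, expr, clin, "female",
                                                   n_perm=50)
        n_kept = res["n_patients"]
        assert len(res["pairs"]) == n_kept * (n_kept - 1) // 2

    def test_perturbed_deceased_detected(self):
        hits = 0
        for seed in range(5):
            g, expr, clin = self._cohort(n=14, seed=seed)
            res = transport.pairwise_distance_analysis(
                g, expr, clin, "female", n_perm=200, seed=seed)
            hits += res["anova_p"] < 0.01
        assert hits >= 4

    def test_identical_patients_degenerate_na(self):
        g, expr, clin = self._cohort(n=10, seed=2, perturb_dead=False)
        expr[:] = 1.0
        clin = clin.copy()
        clin["time"] = 20.0  # all pass the median-follow-up filter
        res = transport.pairwise_distance_analysis(g, expr, clin, "female",
                                                   n_perm=20)
        assert np.isnan(res["anova_p"])

    def test_median_followup_filter_is_cohort_wide(self):
        g, expr, clin = self._cohort(n=12, seed=3)
        clin = clin.copy()
        clin.loc[0, "time"] = 0.1  # below the combined median
        res = transport.pairwise_distance_analysis(g, expr, clin, "female",
                                                   n_perm=20)
        pair_samples = set(res["pairs"]["a"]) | set(res["pairs"]["b"])
        assert "s0" not in pair_samples
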