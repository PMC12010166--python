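"""W1 (Earth Mover's) distances between patients on a PPI network.

The distance between two probability measures mu, nu on the nodes of a
connected undirected graph is computed in the Beckmann (minimum total
flux) form

    W1(mu, nu) = min_u { sum_i |u_i|  :  mu - nu - D u = 0 }

where D is the signed node x edge incidence matrix and u assigns a flux to
every edge (unit edge lengths). The LP is solved after splitting each flux
into non-negative forward/backward parts. On a connected graph this equals
the Kantorovich optimal-transport cost with shortest-path ground metric.

The cohort-level analysis computes all within-stratum pairwise distances,
classifies pairs by the two patients' vital status (alive/alive,
alive/dead, dead/dead) and compares the classes by one-way ANOVA, with a
patient-label permutation p-value reported alongside.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import linprog

logger = logging.getLogger("psgsurv")


@dataclass
class PPIGraph:
    """Validated undirected graph with a fixed edge orientation.

    ``edges`` are lexicographically oriented (head < tail); ``incidence``
    is the node x edge matrix with +1 at the head and -1 at the tail.
    """

    nodes: list[str]
    edges: list[tuple[str, str]]
    incidence: np.ndarray

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def node_index(self, names) -> np.ndarray:
        lookup = {n: i for i, n in enumerate(self.nodes)}
        return np.array([lookup[n] for n in names])


@dataclass
class TransportSolution:
    """Optimal flux and objective of one Beckmann problem."""

    flux: np.ndarray          # signed flux per edge (head -> tail positive)
    objective: float          # sum |flux| = W1

    @property
    def w1(self) -> float:
        return self.objective


def build_graph(edge_list) -> PPIGraph:
    """Validate an undirected edge list into a :class:`PPIGraph`.

    Self-loops are an error; duplicate edges are removed with a warning;
    a disconnected graph is an error naming the components (W1 between
    arbitrary measures is undefined across components).
    """
    seen: set[tuple[str, str]] = set()
    edges: list[tuple[str, str]] = []
    for u, v in edge_list:
        u, v = str(u), str(v)
        if u == v:
            raise ValueError(f"self-loop on node {u!r}")
        e = (min(u, v), max(u, v))
        if e in seen:
            logger.warning("duplicate edge %s-%s removed", *e)
            continue
        seen.add(e)
        edges.append(e)
    if not edges:
        raise ValueError("empty edge list")
    g = nx.Graph(edges)
    if not nx.is_connected(g):
        comps = [sorted(c) for c in nx.connected_components(g)]
        raise ValueError(f"graph is disconnected; components: "
                         f"{[c[:4] for c in comps]}")
    nodes = sorted(g.nodes)
    edges = sorted(edges)
    index = {n: i for i, n in enumerate(nodes)}
    D = np.zeros((len(nodes), len(edges)))
    for j, (head, tail) in enumerate(edges):
        D[index[head], j] = 1.0
        D[index[tail], j] = -1.0
    return PPIGraph(nodes=nodes, edges=edges, incidence=D)


def expression_to_measure(expression: pd.DataFrame, sample: str,
                          graph: PPIGraph,
                          eps_factor: float = 1e-8) -> np.ndarray:
    """Probability measure on the graph nodes from one sample's expression.

    Node-gene values are smoothed by eps = eps_factor x max(value) and
    sum-normalized; an all-zero profile yields the uniform measure.
    """
    missing = [n for n in graph.nodes if n not in expression.index]
    if missing:
        raise KeyError(f"graph nodes absent from expression: {missing[:5]}")
    v = expression.loc[graph.nodes, sample].to_numpy(float)
    if (v < 0).any():
        raise ValueError("expression values must be non-negative")
    vmax = v.max()
    if vmax == 0:
        return np.full(len(v), 1.0 / len(v))
    v = v + eps_factor * vmax
    return v / v.sum()


def w1_distance(graph: PPIGraph, mu, nu) -> TransportSolution:
    """Solve the Beckmann minimum-total-flux problem for W1(mu, nu).

    The flux is split into non-negative parts u = u+ - u- and the LP
    min 1'(u+ + u-) s.t. D(u+ - u-) = mu - nu is solved with HiGHS.
    """
    mu = np.asarray(mu, float)
    nu = np.asarray(nu, float)
    if mu.shape != (graph.n_nodes,) or nu.shape != (graph.n_nodes,):
        raise ValueError("measures must be indexed by the graph nodes")
    if (mu < 0).any() or (nu < 0).any():
        raise ValueError("measures must be non-negative")
    if abs(mu.sum() - nu.sum()) > 1e-9:
        raise ValueError(f"mass mismatch: {mu.sum()} vs {nu.sum()}")
    m = graph.n_edges
    D = graph.incidence
    # drop the last (redundant) divergence constraint to keep A_eq full rank
    A = np.hstack([D, -D])[:-1]
    b = (mu - nu)[:-1]
    res = linprog(c=np.ones(2 * m), A_eq=A, b_eq=b,
                  bounds=[(0, None)] * (2 * m), method="highs")
    if not res.success:
        raise RuntimeError(f"Beckmann LP failed: {res.message}")
    flux = res.x[:m] - res.x[m:]
    div = mu - nu - D @ flux
    if np.abs(div).max() > 1e-6:
        raise RuntimeError("divergence constraint violated beyond tolerance")
    return TransportSolution(flux=flux, objective=float(res.fun))


def pairwise_w1(graph: PPIGraph, expression: pd.DataFrame,
                samples, eps_factor: float = 1e-8) -> pd.DataFrame:
    """Symmetric matrix of pairwise W1 distances between samples."""
    samples = list(samples)
    measures = {s: expression_to_measure(expression, s, graph, eps_factor)
                for s in samples}
    out = pd.DataFrame(0.0, index=samples, columns=samples)
    for a, b in itertools.combinations(samples, 2):
        d = w1_distance(graph, measures[a], measures[b]).objective
        out.loc[a, b] = out.loc[b, a] = d
    return out


def _pair_class_frame(dist: pd.DataFrame,
                      dead: pd.Series) -> pd.DataFrame:
    samples = list(dist.index)
    rows = []
    for a, b in itertools.combinations(samples, 2):
        k = int(dead[a]) + int(dead[b])
        label = {0: "alive/alive", 1: "alive/dead", 2: "dead/dead"}[k]
        rows.append({"a": a, "b": b, "pair_class": label,
                     "w1": dist.loc[a, b]})
    return pd.DataFrame(rows)


def _anova_from_pairs(pairs: pd.DataFrame, min_pairs: int = 2):
    groups = [g["w1"].to_numpy() for _, g in pairs.groupby("pair_class")
              if len(g) >= min_pairs]
    if len(groups) < 2 or np.ptp(np.concatenate(groups)) == 0:
        return np.nan, np.nan
    f, p = sps.f_oneway(*groups)
    return float(f), float(p)


def pairwise_distance_analysis(graph: PPIGraph, expression: pd.DataFrame,
                               clinical: pd.DataFrame, stratum: str,
                               n_perm: int = 1000, seed: int = 0,
                               max_patients: int | None = None) -> dict:
    """Within-stratum pairwise-W1 analysis by survival-status pair class.

    Patients with follow-up shorter than the median follow-up of the
    *combined* cohort are excluded before stratification. All pairwise W1
    distances within the stratum are classified as alive/alive,
    alive/dead or dead/dead by last-follow-up vital status and compared by
    one-way ANOVA; classes with fewer than 2 pairs are dropped with a
    warning. Because pairs sharing a patient are dependent, a
    patient-label permutation p-value (vital-status labels permuted,
    F recomputed) is reported alongside.

    ``max_patients`` optionally subsamples the stratum (deterministic in
    ``seed``) to bound the LP count.
    """
    median_fu = clinical["time"].median()
    kept = clinical[clinical["time"] >= median_fu]
    strat = kept[kept["sex"] == stratum] if stratum != "both" else kept
    dead = strat.set_index("sample_id")["event"].astype(bool)
    if dead.sum() < 2 or (~dead).sum() < 2:
        raise ValueError("need at least 2 patients per survival status")
    rng = np.random.default_rng(seed)
    samples = list(strat["sample_id"])
    if max_patients is not None and len(samples) > max_patients:
        samples = sorted(rng.choice(samples, size=max_patients,
                                    replace=False))
        dead = dead[samples]

    dist = pairwise_w1(graph, expression, samples)
    pairs = _pair_class_frame(dist, dead)
    if np.ptp(pairs["w1"].to_numpy()) == 0:
        logger.warning("all pairwise distances identical; ANOVA undefined")
        return {"pairs": pairs, "anova_f": np.nan, "anova_p": np.nan,
                "perm_p": np.nan, "median_followup": float(median_fu),
                "n_patients": len(samples)}
    counts = pairs["pair_class"].value_counts()
    small = counts[counts < 2]
    if not small.empty:
        logger.warning("pair classes dropped (<2 pairs): %s",
                       list(small.index))
    f_obs, anova_p = _anova_from_pairs(pairs)

    # permutation of patient vital-status labels
    d = dist.to_numpy()
    labels = dead.to_numpy().astype(int)
    iu = np.triu_indices(len(samples), 1)
    f_null = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(labels)
        cls = perm[iu[0]] + perm[iu[1]]
        vals = d[iu]
        groups = [vals[cls == k] for k in (0, 1, 2)]
        groups = [g for g in groups if g.size >= 2]
        f_null[b] = (sps.f_oneway(*groups).statistic
                     if len(groups) >= 2 else np.nan)
    valid = f_null[~np.isnan(f_null)]
    perm_p = float((1 + (valid >= f_obs).sum()) / (1 + valid.size)) \
        if valid.size and not np.isnan(f_obs) else np.nan
    return {"pairs": pairs, "anova_f": f_obs, "anova_p": anova_p,
            "perm_p": perm_p, "median_followup": float(median_fu),
            "n_patients": len(samples)}
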