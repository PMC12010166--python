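"""Independent brute-force oracles used by the test suite.

These are deliberately naive re-derivations (enumeration, permutation,
direct LP formulations) kept separate from the package code paths they
check.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
from scipy.optimize import linprog


def logrank_chi2(time, event, group) -> float:
    """Two-group log-rank chi-squared from the risk-table definition."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    group = np.asarray(group, int)
    o1 = e1 = v = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 1)).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & (group == 1)).sum()
        o1 += d1
        e1 += d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (o1 - e1) ** 2 / v if v > 0 else 0.0


def permutation_logrank_p(time, event, group, n_perm=10_000, seed=0):
    """Permutation p-value of the log-rank chi-squared under label shuffles."""
    rng = np.random.default_rng(seed)
    obs = logrank_chi2(time, event, group)
    group = np.asarray(group, int)
    count = 0
    for _ in range(n_perm):
        stat = logrank_chi2(time, event, rng.permutation(group))
        if stat >= obs - 1e-12:
            count += 1
    return (count + 1) / (n_perm + 1)


def exact_ranksum_p(x, y) -> float:
    """Exact two-sided rank-sum p-value by enumerating all group splits."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n, m = len(x), len(y)
    from scipy.stats import rankdata

    ranks = rankdata(pooled)
    obs = ranks[:n].sum()
    mean = n * (len(pooled) + 1) / 2
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n):
        s = ranks[list(idx)].sum()
        total += 1
        if abs(s - mean) >= abs(obs - mean) - 1e-12:
            count += 1
    return count / total


def brute_concordance(risk, time, event) -> float:
    """Harrell's C by explicit O(n^2) pair enumeration (ties count 1/2)."""
    risk = np.asarray(risk, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    num = den = 0.0
    n = len(risk)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            # i must experience the event before j's observed time
            if event[i] == 1 and (time[i] < time[j]
                                  or (time[i] == time[j] and event[j] == 0)):
                den += 1
                if risk[i] > risk[j]:
                    num += 1
                elif risk[i] == risk[j]:
                    num += 0.5
    if den == 0:
        raise ValueError("no comparable pairs")
    return num / den


def bh_by_hand(p):
    """Benjamini-Hochberg from the textbook definition."""
    p = np.asarray(p, float)
    order = np.argsort(p, kind="stable")
    m = len(p)
    q = np.empty(m)
    prev = 1.0
    for rank_from_last, idx in enumerate(order[::-1]):
        rank = m - rank_from_last
        prev = min(prev, p[idx] * m / rank)
        q[idx] = prev
    return q


def kantorovich_w1(edges, mu, nu) -> float:
    """Optimal-transport W1 with shortest-path ground costs on an
    undirected unit-length graph, solved as the dense Kantorovich LP."""
    g = nx.Graph(edges)
    nodes = sorted(g.nodes)
    n = len(nodes)
    dist = dict(nx.all_pairs_shortest_path_length(g))
    cost = np.array([[dist[a][b] for b in nodes] for a in nodes], float)
    c = cost.ravel()
    a_eq = []
    b_eq = []
    for i in range(n):  # row sums = mu
        row = np.zeros(n * n)
        row[i * n:(i + 1) * n] = 1
        a_eq.append(row)
        b_eq.append(mu[i])
    for j in range(n - 1):  # col sums = nu (last redundant)
        col = np.zeros(n * n)
        col[j::n] = 1
        a_eq.append(col)
        b_eq.append(nu[j])
    res = linprog(c, A_eq=np.array(a_eq), b_eq=np.array(b_eq),
                  bounds=[(0, None)] * (n * n), method="highs")
    assert res.success, res.message
    return float(res.fun)


def random_connected_graph(rng, max_nodes=8):
    """Random connected graph: a random spanning tree plus random extras."""
    n = int(rng.integers(3, max_nodes + 1))
    nodes = [f"N{i}" for i in range(n)]
    edges = set()
    order = rng.permutation(n)
    for i in range(1, n):
        a = nodes[order[i]]
        b = nodes[order[int(rng.integers(0, i))]]
        edges.add((min(a, b), max(a, b)))
    for _ in range(int(rng.integers(0, n))):
        i, j = rng.choice(n, 2, replace=False)
        a, b = nodes[i], nodes[j]
        edges.add((min(a, b), max(a, b)))
    return sorted(edges), nodes


def random_measure(rng, n):
    v = rng.random(n) + 1e-3
    return v / v.sum()
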