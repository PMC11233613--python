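"""Network characterization.

Degree distribution / power-law diagnostic, hub definition (top decile of
connectivity), MCODE module detection, node-class enrichment, and a
permutation test for the mean shortest path among a node set.

The power-law diagnostic is a least-squares regression of log10 P(k) on
log10 k over observed degrees, reporting the slope magnitude as the
exponent and the regression R^2 — the classic scale-free check that yields
an R-squared (maximum-likelihood exponent estimation does not).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import fisher_exact_2x2, ranksum_test

__all__ = [
    "MCODEParams",
    "ModuleResult",
    "degree_and_power_law",
    "hub_nodes",
    "mcode",
    "node_set_enrichment",
    "shortest_path_permutation_test",
    "compare_degree_distributions",
]


# ------------------------------------------------------------ power law


def degree_and_power_law(net: nx.Graph) -> tuple[pd.DataFrame, float, float]:
    """Degree-frequency table plus log-log power-law fit.

    Returns (table with columns degree / count / freq, exponent, r_squared).
    Degrees of 0 are excluded (log undefined). Refuses to fit with fewer
    than 3 distinct positive degrees.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    degs = np.array([d for _, d in net.degree()])
    ks, counts = np.unique(degs[degs > 0], return_counts=True)
    table = pd.DataFrame({"degree": ks, "count": counts, "freq": counts / degs.size})
    if len(ks) < 3:
        raise ValueError(
            f"power-law fit needs >= 3 distinct positive degrees, got {len(ks)}"
        )
    fit = sps.linregress(np.log10(ks), np.log10(table["freq"]))
    return table, float(-fit.slope), float(fit.rvalue**2)


def hub_nodes(net: nx.Graph, fraction: float = 0.10) -> tuple[set, bool]:
    """Top-``fraction`` highest-degree nodes.

    The target size is ceil(fraction * |V|); nodes tied with the degree at
    the cutoff are all included, so the returned set may be larger.
    Returns (node set, tie_expanded flag).
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    deg = dict(net.degree())
    n_target = int(np.ceil(fraction * len(deg)))
    ordered = sorted(deg, key=lambda v: (-deg[v], str(v)))
    cutoff_degree = deg[ordered[n_target - 1]]
    hubs = {v for v in deg if deg[v] >= cutoff_degree}
    return hubs, len(hubs) > n_target


# ------------------------------------------------------------ MCODE


@dataclass
class MCODEParams:
    degree_cutoff: int = 3
    node_score_cutoff: float = 0.2
    k_core: int = 3
    max_depth: int = 100
    haircut: bool = True
    fluff: bool = False

    def __post_init__(self):
        if self.degree_cutoff < 1:
            raise ValueError("degree_cutoff must be >= 1")
        if not (0 <= self.node_score_cutoff <= 1):
            raise ValueError("node_score_cutoff must be in [0, 1]")
        if self.k_core < 2:
            raise ValueError("k_core must be >= 2")


@dataclass
class ModuleResult:
    members: set
    score: float  # density x size, the MCODE ranking score
    seed: str
    rank: int = 0


def _highest_k_core(g: nx.Graph) -> tuple[int, nx.Graph]:
    """Highest k-core of g: returns (k, core subgraph); k=0 if g empty."""
    if g.number_of_nodes() == 0:
        return 0, g
    core_nums = nx.core_number(nx.Graph(g))
    k = max(core_nums.values())
    core = g.subgraph([v for v, c in core_nums.items() if c == k])
    return k, core


def _density(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * g.number_of_edges() / (n * (n - 1))


def mcode_vertex_weights(net: nx.Graph, params: MCODEParams) -> dict:
    """MCODE stage 1: weight(v) = k x density of the highest k-core of the
    subgraph induced by v's closed neighborhood; 0 below the degree cutoff."""
    return {v: w for v, (w, _) in _vertex_weights_and_cores(net, params).items()}


def _vertex_weights_and_cores(net: nx.Graph, params: MCODEParams) -> dict:
    """(weight, core level) per vertex; both 0 below the degree cutoff."""
    out = {}
    for v in net.nodes:
        if net.degree(v) < params.degree_cutoff:
            out[v] = (0.0, 0)
            continue
        closed = list(net.neighbors(v)) + [v]
        sub = net.subgraph(closed)
        k, core = _highest_k_core(sub)
        out[v] = (float(k) * _density(core), k)
    return out


def mcode(net: nx.Graph, params: MCODEParams | None = None) -> list[ModuleResult]:
    """MCODE module detection (vertex weighting, seeded expansion,
    post-processing).

    Stage 2 grows each complex from the highest-weight unassigned vertex,
    including unassigned neighbors whose weight is within
    ``node_score_cutoff`` of the seed weight, breadth-first to
    ``max_depth``. Expansion never descends into vertices whose
    neighborhood core level is below the seed's: a complex seeded inside a
    k-core cannot absorb a lower-order clique through a single bridge.
    Stage 3 drops complexes without a ``k_core``-core and, with
    ``haircut``, removes singly-connected members (which become available
    to later seeds). Modules are ranked by density x size.
    """
    params = params or MCODEParams()
    wk = _vertex_weights_and_cores(net, params)
    weights = {v: w for v, (w, _) in wk.items()}
    assigned: set = set()
    complexes: list[tuple[str, set]] = []
    for seed in sorted(weights, key=lambda v: (-weights[v], str(v))):
        if seed in assigned or weights[seed] <= 0.0:
            continue
        threshold = weights[seed] * (1.0 - params.node_score_cutoff)
        seed_core = wk[seed][1]
        members = {seed}
        frontier = [seed]
        depth = 0
        while frontier and depth < params.max_depth:
            nxt = []
            for u in frontier:
                for w in net.neighbors(u):
                    if w in members or w in assigned:
                        continue
                    if weights[w] >= threshold and wk[w][1] >= seed_core:
                        members.add(w)
                        nxt.append(w)
            frontier = nxt
            depth += 1
        assigned |= members

        sub = nx.Graph(net.subgraph(members))
        k, _ = _highest_k_core(sub)
        if k < params.k_core:
            assigned -= members  # failed complexes do not lock their vertices
            continue
        if params.haircut:
            pruned = True
            while pruned:
                ones = [v for v in sub.nodes if sub.degree(v) <= 1]
                pruned = bool(ones)
                for v in ones:
                    sub.remove_node(v)
                    members.discard(v)
                    assigned.discard(v)
        if not members:
            continue
        complexes.append((seed, members))

    results = [
        ModuleResult(members=m, seed=s, score=_density(net.subgraph(m)) * len(m))
        for s, m in complexes
    ]
    results.sort(key=lambda r: (-r.score, str(r.seed)))
    for i, r in enumerate(results, 1):
        r.rank = i
    return results


# ------------------------------------------------------------ enrichment


def node_set_enrichment(net: nx.Graph, node_set, target_set) -> tuple[float, float]:
    """Two-sided Fisher's exact test of node_set membership against
    target_set membership over all network nodes. Returns (odds ratio, p);
    degenerate tables yield (nan, 1.0)."""
    nodes = set(net.nodes)
    node_set = set(node_set) & nodes
    target_set = set(target_set) & nodes
    if not node_set:
        raise ValueError("node_set is empty (or disjoint from the network)")
    a = len(node_set & target_set)
    b = len(node_set - target_set)
    c = len(target_set - node_set)
    d = len(nodes - node_set - target_set)
    return fisher_exact_2x2([[a, b], [c, d]])


# ------------------------------------------------------------ path test


def mean_shortest_path(net: nx.Graph, node_set) -> tuple[float, int]:
    """Mean pairwise shortest-path length within node_set.

    Pairs in different components are excluded; returns (mean, number of
    excluded pairs). Raises if every pair is disconnected.
    """
    nodes = sorted(set(node_set))
    if len(nodes) < 2:
        raise ValueError("need at least two nodes")
    lengths, excluded = [], 0
    for i, u in enumerate(nodes):
        dist = nx.single_source_shortest_path_length(net, u)
        for v in nodes[i + 1:]:
            if v in dist:
                lengths.append(dist[v])
            else:
                excluded += 1
    if not lengths:
        raise ValueError("all node pairs are disconnected")
    return float(np.mean(lengths)), excluded


def shortest_path_permutation_test(
    net: nx.Graph, node_set, B: int = 1000, seed: int = 0
) -> dict:
    """Are the nodes of ``node_set`` closer together than random node sets?

    B random sets of the same size are drawn uniformly (without
    replacement) from all network nodes; empirical
    p = (1 + #{mean_b <= observed}) / (B + 1).
    """
    node_set = sorted(set(node_set) & set(net.nodes))
    observed, excluded = mean_shortest_path(net, node_set)
    rng = np.random.default_rng(seed)
    all_nodes = sorted(net.nodes)
    count = 0
    null_means = np.empty(B)
    for b in range(B):
        sample = rng.choice(len(all_nodes), size=len(node_set), replace=False)
        m, _ = mean_shortest_path(net, [all_nodes[i] for i in sample])
        null_means[b] = m
        if m <= observed:
            count += 1
    return {
        "observed_mean": observed,
        "excluded_pairs": excluded,
        "empirical_p": (1 + count) / (B + 1),
        "null_means": null_means,
    }


def compare_degree_distributions(net: nx.Graph, set_a, set_b) -> float:
    """One-sided rank-sum p that set_a degrees exceed set_b degrees."""
    set_a, set_b = set(set_a), set(set_b)
    if set_a & set_b:
        raise ValueError("node sets overlap")
    if not set_a or not set_b:
        raise ValueError("both node sets must be non-empty")
    deg = dict(net.degree())
    da = [deg[v] for v in set_a]
    db = [deg[v] for v in set_b]
    return ranksum_test(da, db, alternative="greater")
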