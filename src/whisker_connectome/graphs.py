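"""Directed graph metrics, hub detection, ER null models and permutation tests.

All analyses run on binarized directed connectomes (self-connections ignored).
Nodal metrics follow the standard binary-directed definitions: degrees and
degree centrality (in + out), the Fagiolo directed clustering coefficient,
mean geodesic distance to reachable nodes, nodal efficiency (mean inverse
geodesic, unreachable pairs contributing 0), local efficiency (efficiency of
the subgraph induced by a node's in- and out-neighbours), and normalized
betweenness centrality.

Hubs are nodes whose degree centrality strictly exceeds the network mean plus
one (population) standard deviation.  The null model is an Erdős–Rényi graph
with the same number of nodes and *exactly* the same number of edges.  The
neuromodulator-ablation comparison is a pooled two-sample permutation test on
the nodal metric vectors of the graph with and without the removed nuclei.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .calibration import BinaryConnectome
from .errors import DegenerateInputError

NODAL_METRICS = (
    "in_degree",
    "out_degree",
    "degree_centrality",
    "clustering",
    "shortest_path",
    "efficiency",
    "local_efficiency",
    "betweenness",
)

#: Metrics eligible for the ablation permutation test.
TESTABLE_METRICS = (
    "degree_centrality",
    "clustering",
    "shortest_path",
    "efficiency",
    "local_efficiency",
    "betweenness",
)


@dataclass
class GraphReport:
    """Nodal metric table plus global summaries for one binary connectome."""

    nodal: pd.DataFrame  # index: node acronym, columns: NODAL_METRICS
    global_mean: dict[str, float]
    global_sd: dict[str, float]
    hub_set: set[str]
    group_shares: dict[str, float] = field(default_factory=dict)
    n_edges: int = 0


@dataclass
class SmallWorldVerdict:
    """ER comparison on mean clustering and mean shortest path."""

    clustering_graph: float
    clustering_er: float
    path_graph: float
    path_er: float
    is_small_world: bool


@dataclass
class PermutationResult:
    metric: str
    observed_statistic: float
    p_value: float
    n_permutations: int
    seed: int


def to_digraph(bc: BinaryConnectome) -> nx.DiGraph:
    """Directed graph over all panel nodes; the diagonal is dropped."""
    g = nx.DiGraph()
    g.add_nodes_from(bc.nodes)
    a = bc.adjacency
    for i, s in enumerate(bc.nodes):
        for j, t in enumerate(bc.nodes):
            if i != j and a[i, j]:
                g.add_edge(s, t)
    return g


def _geodesic_metrics(g: nx.DiGraph) -> tuple[dict, dict]:
    """Per-node mean geodesic to reachable nodes, and nodal efficiency."""
    n = g.number_of_nodes()
    sp: dict[str, float] = {}
    eff: dict[str, float] = {}
    for v in g.nodes:
        lengths = nx.single_source_shortest_path_length(g, v)
        dists = [d for u, d in lengths.items() if u != v]
        sp[v] = float(np.mean(dists)) if dists else 0.0
        eff[v] = sum(1.0 / d for d in dists) / (n - 1) if n > 1 else 0.0
    return sp, eff


def _local_efficiency(g: nx.DiGraph, v) -> float:
    """Global efficiency of the subgraph induced by v's in/out neighbours."""
    nbrs = (set(g.successors(v)) | set(g.predecessors(v))) - {v}
    k = len(nbrs)
    if k < 2:
        return 0.0
    sub = g.subgraph(nbrs)
    total = 0.0
    for u in sub.nodes:
        lengths = nx.single_source_shortest_path_length(sub, u)
        total += sum(1.0 / d for w, d in lengths.items() if w != u)
    return total / (k * (k - 1))


def nodal_metrics(
    bc: BinaryConnectome, groups: Mapping[str, str] | None = None
) -> GraphReport:
    """All nodal metrics, global mean/SD, hub set and group incidence shares."""
    if bc.n == 0:
        raise DegenerateInputError("graph has no nodes")
    g = to_digraph(bc)
    sp, eff = _geodesic_metrics(g)
    clustering = nx.clustering(g)  # Fagiolo directed clustering
    betweenness = nx.betweenness_centrality(g, normalized=True)
    rows = {}
    for v in bc.nodes:
        indeg = g.in_degree(v)
        outdeg = g.out_degree(v)
        rows[v] = {
            "in_degree": indeg,
            "out_degree": outdeg,
            "degree_centrality": indeg + outdeg,
            "clustering": clustering[v],
            "shortest_path": sp[v],
            "efficiency": eff[v],
            "local_efficiency": _local_efficiency(g, v),
            "betweenness": betweenness[v],
        }
    nodal = pd.DataFrame.from_dict(rows, orient="index").loc[bc.nodes, list(NODAL_METRICS)]
    global_mean = {m: float(nodal[m].mean()) for m in NODAL_METRICS}
    global_sd = {m: float(nodal[m].std(ddof=0)) for m in NODAL_METRICS}
    hub_set = detect_hubs(nodal["degree_centrality"])
    shares: dict[str, float] = {}
    m_edges = g.number_of_edges()
    if groups is not None and m_edges > 0:
        dc = nodal["degree_centrality"]
        for v in bc.nodes:
            grp = groups.get(v)
            if grp is not None:
                shares[grp] = shares.get(grp, 0.0) + dc[v]
        shares = {k: v / (2.0 * m_edges) for k, v in shares.items()}
    return GraphReport(
        nodal=nodal,
        global_mean=global_mean,
        global_sd=global_sd,
        hub_set=hub_set,
        group_shares=shares,
        n_edges=m_edges,
    )


def detect_hubs(degree_centrality: pd.Series | Mapping[str, float]) -> set[str]:
    """Nodes with degree centrality strictly above mean + one population SD."""
    s = pd.Series(degree_centrality, dtype=float)
    cut = s.mean() + s.std(ddof=0)
    return set(s.index[s > cut])


def er_null(n: int, m: int, seed: int, nodes: list[str] | None = None) -> BinaryConnectome:
    """Directed Erdős–Rényi draw with exactly ``m`` edges and no self-loops."""
    if not (0 <= m <= n * (n - 1)):
        raise ValueError(f"edge count {m} out of range for {n} nodes")
    g = nx.gnm_random_graph(n, m, seed=seed, directed=True)
    names = nodes if nodes is not None else [f"n{i}" for i in range(n)]
    adj = np.zeros((n, n), dtype=int)
    for u, v in g.edges:
        adj[u, v] = 1
    return BinaryConnectome(nodes=names, adjacency=adj, measured=np.ones(n, dtype=bool))


def small_world_verdict(
    bc: BinaryConnectome, n_null: int = 100, seed: int = 0
) -> SmallWorldVerdict:
    """Compare mean clustering and mean shortest path against matched ER draws.

    Small-world iff the graph clusters more *and* reaches other nodes in
    strictly fewer steps than the average of ``n_null`` seeded ER graphs with
    the same node and edge counts; ties fail the strict comparison.
    """
    if bc.n == 0:
        raise DegenerateInputError("graph has no nodes")
    report = nodal_metrics(bc)
    m = report.n_edges
    c_er, l_er = [], []
    for k in range(n_null):
        null = er_null(bc.n, m, seed=seed + k)
        r = nodal_metrics(null)
        c_er.append(r.global_mean["clustering"])
        l_er.append(r.global_mean["shortest_path"])
    c_g = report.global_mean["clustering"]
    l_g = report.global_mean["shortest_path"]
    c_e, l_e = float(np.mean(c_er)), float(np.mean(l_er))
    return SmallWorldVerdict(
        clustering_graph=c_g,
        clustering_er=c_e,
        path_graph=l_g,
        path_er=l_e,
        is_small_world=bool(c_g > c_e and l_g < l_e),
    )


def permutation_pvalue(
    a: np.ndarray, b: np.ndarray, n_perm: int, seed: int
) -> tuple[float, float]:
    """Pooled two-sample permutation test on |mean(a) − mean(b)|.

    The pooled values are re-split at the original sizes ``n_perm`` times;
    p = (#{null ≥ observed} + 1) / (n_perm + 1).  A tiny absolute tolerance
    guards tie counting against float summation order.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    obs = abs(a.mean() - b.mean())
    pooled = np.concatenate([a, b])
    na, n = len(a), len(pooled)
    rng = np.random.default_rng(seed)
    order = np.argsort(rng.random((n_perm, n)), axis=1)
    perm = pooled[order]
    stat = np.abs(perm[:, :na].mean(axis=1) - perm[:, na:].mean(axis=1))
    tol = 1e-12 * (1.0 + obs)
    count = int(np.sum(stat >= obs - tol))
    return obs, (count + 1) / (n_perm + 1)


def ablation_permutation_test(
    bc: BinaryConnectome,
    remove: Iterable[str],
    metric: str,
    n_perm: int = 10_000,
    seed: int = 0,
) -> PermutationResult:
    """Does deleting ``remove`` (e.g. the neuromodulatory nuclei) shift a metric?

    The nodal ``metric`` vector is computed on the full graph and on the
    induced subgraph without the removed nuclei, and compared with the pooled
    permutation test.
    """
    if metric not in TESTABLE_METRICS:
        raise ValueError(f"metric must be one of {TESTABLE_METRICS}, got {metric!r}")
    remove = set(remove)
    unknown = remove - set(bc.nodes)
    if unknown:
        raise DegenerateInputError(f"cannot remove unknown nodes {sorted(unknown)}")
    keep_idx = [i for i, v in enumerate(bc.nodes) if v not in remove]
    if not keep_idx:
        raise DegenerateInputError("cannot remove every node")
    full = nodal_metrics(bc).nodal[metric].to_numpy()
    sub_bc = BinaryConnectome(
        nodes=[bc.nodes[i] for i in keep_idx],
        adjacency=bc.adjacency[np.ix_(keep_idx, keep_idx)],
        measured=bc.measured[keep_idx],
    )
    reduced = nodal_metrics(sub_bc).nodal[metric].to_numpy()
    obs, p = permutation_pvalue(full, reduced, n_perm=n_perm, seed=seed)
    return PermutationResult(
        metric=metric,
        observed_statistic=obs,
        p_value=p,
        n_permutations=n_perm,
        seed=seed,
    )
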