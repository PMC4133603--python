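"""Network modules: Girvan-Newman partitioning, topology and χ² statistics.

Association networks are treated as simple, unweighted, undirected graphs;
any edge weights present in the input are carried as annotations but every
metric and the community detection use connectivity only. The divisive
Girvan-Newman procedure repeatedly removes the edge with largest edge
betweenness (recomputed after every removal) until the requested number of
connected components is reached, or — in "auto" mode — returns the
partition of maximal Newman modularity encountered along the removal
sequence.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from typing import Hashable, Mapping

import networkx as nx
import numpy as np
from scipy import stats

from grffl.datatypes import ContingencyTable, TestResult, ValidationError

__all__ = [
    "CommunityPartition",
    "TopologyReport",
    "edge_betweenness",
    "girvan_newman",
    "topology_report",
    "hub_edge_fraction",
    "chi_square_yates",
    "module_composition_test",
]

Edge = tuple[Hashable, Hashable]


def _canon(u: Hashable, v: Hashable) -> Edge:
    return (u, v) if str(u) <= str(v) else (v, u)


@dataclass
class CommunityPartition:
    """Assignment of nodes to modules plus the edge-removal audit trail."""

    membership: dict[Hashable, int]
    n_modules: int
    removal_history: list[tuple[Edge, float]] = field(default_factory=list)
    modularity: float | None = None

    def module(self, node: Hashable) -> int:
        return self.membership[node]

    def modules(self) -> dict[int, set]:
        out: dict[int, set] = {}
        for node, m in self.membership.items():
            out.setdefault(m, set()).add(node)
        return out


@dataclass
class TopologyReport:
    """Network-wide and per-node topology statistics.

    density = 2E / (N(N-1)); heterogeneity = coefficient of variation of the
    degree distribution (population sd); neighborhood connectivity of a node
    is the mean degree of its neighbors; the shared-neighbor histogram counts
    node pairs by their number of common neighbors.
    """

    n_nodes: int
    n_edges: int
    density: float
    avg_clustering: float
    heterogeneity: float
    avg_neighborhood_connectivity: float
    shared_neighbor_histogram: dict[int, int]
    degree: dict[Hashable, int]
    clustering: dict[Hashable, float]
    neighborhood_connectivity: dict[Hashable, float]


def _check_simple(g: nx.Graph) -> None:
    if any(u == v for u, v in g.edges()):
        raise ValidationError("graph has self-loops")


def edge_betweenness(g: nx.Graph) -> dict[Edge, float]:
    """Edge betweenness: per edge, the summed fraction of shortest paths
    between all unordered node pairs that pass through it (unweighted BFS)."""
    _check_simple(g)
    raw = nx.edge_betweenness_centrality(g, normalized=False, weight=None)
    return {_canon(u, v): float(b) for (u, v), b in raw.items()}


def girvan_newman(g: nx.Graph, target_modules: int | str = "auto") -> CommunityPartition:
    """Divisive community detection by iterative betweenness-edge removal.

    Numeric ``target_modules`` stops as soon as that many connected
    components exist; ``"auto"`` runs the full removal sequence and returns
    the partition with maximal Newman modularity (evaluated on the original
    graph). Betweenness ties are broken lexicographically by edge id so the
    removal history is reproducible.
    """
    _check_simple(g)
    n = g.number_of_nodes()
    work = nx.Graph()
    work.add_nodes_from(g.nodes())
    work.add_edges_from(g.edges())

    def components_partition(h: nx.Graph) -> dict[Hashable, int]:
        comps = sorted(nx.connected_components(h), key=lambda c: sorted(map(str, c))[0])
        return {node: i for i, comp in enumerate(comps) for node in comp}

    n_comp0 = nx.number_connected_components(work)
    if isinstance(target_modules, int):
        if target_modules > n:
            raise ValidationError(f"target {target_modules} exceeds {n} nodes")
        if target_modules < n_comp0:
            raise ValidationError(
                f"target {target_modules} below current component count {n_comp0}"
            )
    elif target_modules != "auto":
        raise ValidationError("target_modules must be an int or 'auto'")

    history: list[tuple[Edge, float]] = []
    best_membership = components_partition(work)
    best_q = _modularity(g, best_membership) if target_modules == "auto" else None

    while work.number_of_edges() > 0:
        n_comp = nx.number_connected_components(work)
        if isinstance(target_modules, int) and n_comp >= target_modules:
            break
        eb = edge_betweenness(work)
        max_b = max(eb.values())
        edge = min(e for e, b in eb.items() if b == max_b)
        work.remove_edge(*edge)
        history.append((edge, max_b))
        if target_modules == "auto":
            membership = components_partition(work)
            q = _modularity(g, membership)
            if q > best_q:
                best_q, best_membership = q, membership

    if isinstance(target_modules, int):
        best_membership = components_partition(work)
        best_q = _modularity(g, best_membership)
    return CommunityPartition(
        membership=best_membership,
        n_modules=len(set(best_membership.values())),
        removal_history=history,
        modularity=best_q,
    )


def _modularity(g: nx.Graph, membership: Mapping[Hashable, int]) -> float:
    if g.number_of_edges() == 0:
        return 0.0
    groups: dict[int, set] = {}
    for node, m in membership.items():
        groups.setdefault(m, set()).add(node)
    return nx.community.modularity(g, groups.values(), weight=None)


def topology_report(g: nx.Graph) -> TopologyReport:
    """Cytoscape NetworkAnalyzer-style topology metrics."""
    _check_simple(g)
    n = g.number_of_nodes()
    if n < 2:
        raise ValidationError("need >= 2 nodes")
    e = g.number_of_edges()
    degree = dict(g.degree())
    deg = np.array([degree[v] for v in g.nodes()], dtype=float)
    clustering = {v: float(c) for v, c in nx.clustering(g).items()}
    nbh = {}
    for v in g.nodes():
        nbrs = list(g.neighbors(v))
        nbh[v] = float(np.mean([degree[u] for u in nbrs])) if nbrs else 0.0
    hist: Counter[int] = Counter()
    nodes = list(g.nodes())
    adj = {v: set(g.neighbors(v)) for v in nodes}
    for u, v in itertools.combinations(nodes, 2):
        hist[len(adj[u] & adj[v])] += 1
    mean_deg = deg.mean()
    heterogeneity = float(deg.std(ddof=0) / mean_deg) if mean_deg > 0 else 0.0
    return TopologyReport(
        n_nodes=n,
        n_edges=e,
        density=2.0 * e / (n * (n - 1)),
        avg_clustering=float(np.mean(list(clustering.values()))),
        heterogeneity=heterogeneity,
        avg_neighborhood_connectivity=float(np.mean(list(nbh.values()))),
        shared_neighbor_histogram=dict(hist),
        degree=degree,
        clustering=clustering,
        neighborhood_connectivity=nbh,
    )


def hub_edge_fraction(g: nx.Graph, top_n: int, mode: str = "incident") -> float:
    """Fraction of all edges accounted for by the ``top_n`` highest-degree nodes.

    ``mode='incident'`` counts edges touching at least one hub (hub-hub edges
    once); ``mode='degree'`` uses the summed hub degree over 2E, which counts
    hub-hub edges twice. Degree ties are broken by node id for determinism.
    """
    if top_n > g.number_of_nodes():
        raise ValidationError("top_n exceeds node count")
    if g.number_of_edges() == 0 or top_n == 0:
        return 0.0
    ranked = sorted(g.nodes(), key=lambda v: (-g.degree(v), str(v)))
    hubs = set(ranked[:top_n])
    if mode == "incident":
        covered = sum(1 for u, v in g.edges() if u in hubs or v in hubs)
        return covered / g.number_of_edges()
    if mode == "degree":
        return sum(g.degree(v) for v in hubs) / (2.0 * g.number_of_edges())
    raise ValidationError("mode must be 'incident' or 'degree'")


def chi_square_yates(t: ContingencyTable) -> TestResult:
    """Yates-corrected χ² on a 2×2 table (df = 1).

    χ² = n (|ad − bc| − n/2)² / ((a+b)(c+d)(a+c)(b+d)), with the continuity
    correction floored at zero when |ad − bc| < n/2.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    n = t.n
    marginals = [(a + b), (c + d), (a + c), (b + d)]
    if any(m == 0 for m in marginals):
        raise ValidationError("zero marginal; chi-square undefined")
    diff = abs(a * d - b * c)
    corrected = max(diff - n / 2.0, 0.0)
    chi2 = n * corrected**2 / np.prod([float(m) for m in marginals])
    return TestResult(statistic=float(chi2),
                      p_value=float(stats.chi2.sf(chi2, df=1)),
                      method="chi2-yates")


def module_composition_test(partition: CommunityPartition,
                            node_class: Mapping[Hashable, bool]) -> list[dict]:
    """Per-module 2×2 χ² test of class enrichment.

    For each module: rows are (in module / out of module), columns are
    (in class / out of class). Modules smaller than 2 nodes are flagged and
    skipped. ``node_class`` must cover every partitioned node.
    """
    missing = set(partition.membership) - set(node_class)
    if missing:
        raise ValidationError(f"node_class missing nodes: {sorted(map(str, missing))[:5]}")
    total_in_class = sum(1 for v in partition.membership if node_class[v])
    n = len(partition.membership)
    rows = []
    for mod, members in sorted(partition.modules().items()):
        k = sum(1 for v in members if node_class[v])
        size = len(members)
        row = {"module": mod, "size": size, "in_class": k}
        if size < 2:
            row.update({"skipped": True, "chi2": None, "p_value": None})
        else:
            table = ContingencyTable(k, size - k,
                                     total_in_class - k, n - size - (total_in_class - k))
            try:
                tr = chi_square_yates(table)
                row.update({"skipped": False, "chi2": tr.statistic,
                            "p_value": tr.p_value, "stars": tr.stars})
            except ValidationError:
                row.update({"skipped": True, "chi2": None, "p_value": None,
                            "note": "degenerate marginal"})
        rows.append(row)
    return rows
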