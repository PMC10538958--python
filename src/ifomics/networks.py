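"""Interaction-network analysis: overlay of diet-responsive proteins,
cohesiveness-based greedy clustering (Cluster ONE style), and topology
summaries.

Cluster quality is the cohesiveness f(V) = w_in / (w_in + w_bound +
penalty*|V|): internal edge weight against boundary weight plus a
per-node penalty for untested incident edges.  Clusters grow greedily
from high-degree seeds by single add/remove steps, overlapping results
are merged, and surviving clusters are screened for significance — a
one-sided Mann-Whitney of internal vs boundary edge weights for weighted
graphs, or a degree-preserving rewiring null for unweighted graphs,
where constant weights make the rank test degenerate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from . import stats
from .containers import EdgeList

REGIMEN_ORDER = ["IF12", "IF16", "EOD"]


@dataclass
class ClusterRecord:
    nodes: frozenset
    cohesiveness: float
    p_penalty: float
    p: float
    regimen_counts: dict[str, int] = field(default_factory=dict)


def overlay_responsive(
    ppi: EdgeList,
    differential: dict[str, set],
    order: list[str] | None = None,
    logger=None,
) -> EdgeList:
    """Annotate network nodes with the earliest regimen that altered them.

    ``differential`` maps regimen -> significant protein set; a protein
    significant in several regimens is labelled with the earliest one in
    ``order`` (default IF12 < IF16 < EOD, i.e. shortest daily fast first).
    Duplicate edges are already collapsed by the EdgeList container; the
    mapped-coverage fraction is logged.
    """
    order = order or REGIMEN_ORDER
    out = EdgeList(edges=dict(ppi.edges), node_attributes={})
    responsive = set().union(*differential.values()) if differential else set()
    nodes = set(out.nodes())
    mapped = 0
    for node in sorted(nodes):
        label = ""
        for regimen in order:
            if node in differential.get(regimen, set()):
                label = regimen
                break
        if label:
            mapped += 1
        out.node_attributes[node] = {"regimen": label}
    if logger is not None and responsive:
        in_network = len(responsive & nodes)
        frac = in_network / len(responsive)
        logger.log(f"overlay_responsive: mapped {in_network}/{len(responsive)} "
                   f"responsive proteins ({frac:.0%}) onto the network",
                   mapped=in_network, responsive=len(responsive))
    return out


def cohesiveness(graph: nx.Graph, subset, p_penalty: float = 2.0) -> float:
    """f(V) = w_in / (w_in + w_bound + p_penalty * |V|)."""
    nodes = set(subset)
    if not nodes:
        raise ValueError("empty node subset")
    w_in = 0.0
    w_bound = 0.0
    for u, v, data in graph.edges(nodes, data=True):
        w = data.get("weight", 1.0)
        if u in nodes and v in nodes:
            w_in += w
        else:
            w_bound += w
    denom = w_in + w_bound + p_penalty * len(nodes)
    return w_in / denom if denom > 0 else 0.0


def _grow_cluster(graph: nx.Graph, seed: str, p_penalty: float) -> frozenset:
    """Greedy local search maximizing cohesiveness from a single seed.

    w_in and w_bound are maintained incrementally, so evaluating a
    candidate add/remove costs O(degree) instead of re-scanning the
    cluster's edge set.
    """
    def w(u, v):
        return graph[u][v].get("weight", 1.0)

    current = {seed}
    w_in = 0.0
    w_bound = sum(w(seed, n) for n in graph.neighbors(seed))

    def f_of(wi, wb, size):
        denom = wi + wb + p_penalty * size
        return wi / denom if denom > 0 else 0.0

    f = f_of(w_in, w_bound, 1)
    while True:
        best_f, best_change = f, None
        boundary = sorted({n for m in current for n in graph.neighbors(m)} - current)
        for cand in boundary:
            k_in = sum(w(cand, n) for n in graph.neighbors(cand) if n in current)
            k_out = sum(w(cand, n) for n in graph.neighbors(cand) if n not in current)
            nf = f_of(w_in + k_in, w_bound - k_in + k_out, len(current) + 1)
            if nf > best_f + 1e-12:
                best_f, best_change = nf, ("add", cand, k_in, k_out)
        best_equal_removal = None
        if len(current) > 1:
            for cand in sorted(current):
                k_in = sum(w(cand, n) for n in graph.neighbors(cand) if n in current)
                k_out = sum(w(cand, n) for n in graph.neighbors(cand) if n not in current)
                nf = f_of(w_in - k_in, w_bound + k_in - k_out, len(current) - 1)
                if nf > best_f + 1e-12:
                    best_f, best_change = nf, ("remove", cand, k_in, k_out)
                elif best_equal_removal is None and nf >= f - 1e-12:
                    best_equal_removal = ("remove", cand, k_in, k_out)
        if best_change is None:
            # tie-break toward the smaller cluster: an f-preserving removal
            # (e.g. a pendant vertex that is exactly cohesiveness-neutral)
            # is applied once no strictly improving change exists
            if best_equal_removal is not None:
                best_change = best_equal_removal
            else:
                return frozenset(current)
        op, cand, k_in, k_out = best_change
        if op == "add":
            current.add(cand)
            w_in += k_in
            w_bound += k_out - k_in
        else:
            current.remove(cand)
            w_in -= k_in
            w_bound += k_in - k_out
        f = best_f


def _overlap(a: frozenset, b: frozenset) -> float:
    inter = len(a & b)
    return inter * inter / (len(a) * len(b))


def _rewired_ensemble(
    graph: nx.Graph, n_rewires: int, rng: np.random.Generator
) -> list[nx.Graph]:
    """Degree-preserving rewired copies, shared by every cluster's test."""
    ensemble = []
    for _ in range(n_rewires):
        g2 = graph.copy()
        n_swaps = max(1, g2.number_of_edges())
        try:
            nx.double_edge_swap(g2, nswap=n_swaps, max_tries=20 * n_swaps,
                                seed=int(rng.integers(2**31)))
        except nx.NetworkXException:
            pass
        ensemble.append(g2)
    return ensemble


def _cluster_significance(
    graph: nx.Graph, nodes: frozenset, p_penalty: float,
    weighted: bool, ensemble: list[nx.Graph],
) -> float:
    """Mann-Whitney internal-vs-boundary weights (weighted graphs) or an
    empirical rewiring null of the cohesiveness (unweighted graphs)."""
    if weighted:
        internal, boundary = [], []
        for u, v, data in graph.edges(nodes, data=True):
            (internal if (u in nodes and v in nodes) else boundary).append(
                data.get("weight", 1.0))
        if not internal or not boundary:
            return 0.0 if internal else 1.0
        flags = np.array([True] * len(internal) + [False] * len(boundary))
        vals = np.array(internal + boundary, dtype=float)
        # one-sided: internal weights larger
        s, p_two = stats.position_score_1d(vals, flags)
        return p_two / 2.0 if s > 0 else 1.0 - p_two / 2.0
    boundary_w = sum(
        data.get("weight", 1.0)
        for u, v, data in graph.edges(nodes, data=True)
        if (u in nodes) != (v in nodes)
    )
    if boundary_w == 0.0:
        return 0.0  # no boundary: maximally separated cluster
    f_obs = cohesiveness(graph, nodes, p_penalty)
    hits = sum(
        cohesiveness(g2, nodes, p_penalty) >= f_obs - 1e-12 for g2 in ensemble
    )
    return (1 + hits) / (1 + len(ensemble))


def greedy_clusters(
    graph: nx.Graph,
    min_size: int = 3,
    p_penalty: float = 2.0,
    overlap_threshold: float = 0.8,
    p_threshold: float = 0.1,
    n_rewires: int = 100,
    seed: int = 0,
    logger=None,
) -> list[ClusterRecord]:
    """Cluster ONE-style greedy growth with overlap merging and a
    significance screen.

    Seeds are unvisited nodes in descending degree (lexicographic
    tie-break); each seed grows by the single add/remove step that most
    increases cohesiveness until a local maximum; cluster pairs with
    overlap |A∩B|^2/(|A||B|) >= overlap_threshold merge; clusters of size
    >= min_size are kept when significant at p < p_threshold.
    Deterministic for fixed seed and input.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    rng = np.random.default_rng(seed)
    weighted = any("weight" in d and d["weight"] != 1.0
                   for _u, _v, d in graph.edges(data=True))
    order = sorted(graph.nodes, key=lambda n: (-graph.degree(n), n))
    covered: set = set()
    raw: list[frozenset] = []
    for node in order:
        if node in covered or graph.degree(node) == 0:
            continue
        cluster = _grow_cluster(graph, node, p_penalty)
        covered |= cluster
        if cluster not in raw:
            raw.append(cluster)
    # merge highly overlapping clusters until stable
    merged = list(raw)
    changed = True
    while changed:
        changed = False
        for i in range(len(merged)):
            for j in range(i + 1, len(merged)):
                if _overlap(merged[i], merged[j]) >= overlap_threshold:
                    union = merged[i] | merged[j]
                    merged = [c for k, c in enumerate(merged) if k not in (i, j)]
                    merged.append(union)
                    changed = True
                    break
            if changed:
                break
    candidates = [c for c in sorted(merged, key=lambda c: sorted(c))
                  if len(c) >= min_size]
    ensemble = (_rewired_ensemble(graph, n_rewires, rng)
                if (candidates and not weighted) else [])
    records = []
    for cluster in candidates:
        p = _cluster_significance(graph, cluster, p_penalty, weighted, ensemble)
        if p < p_threshold:
            counts: dict[str, int] = {}
            for n in cluster:
                regimen = graph.nodes[n].get("regimen", "")
                if regimen:
                    counts[regimen] = counts.get(regimen, 0) + 1
            records.append(ClusterRecord(
                nodes=cluster, cohesiveness=cohesiveness(graph, cluster, p_penalty),
                p_penalty=p_penalty, p=p, regimen_counts=counts))
    if logger is not None:
        logger.log(f"greedy_clusters: {len(records)} significant clusters "
                   f"(of {len(merged)} candidates)",
                   clusters=len(records), candidates=len(merged))
    return records


def degree_summary(graph: nx.Graph, top_k: int = 10) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-node degree table plus the degree distribution; includes hubs."""
    table = pd.DataFrame(
        [{"node": n, "degree": d} for n, d in sorted(graph.degree, key=lambda x: (-x[1], x[0]))],
        columns=["node", "degree"],
    )
    dist = (table["degree"].value_counts().sort_index()
            .rename_axis("degree").reset_index(name="n_nodes"))
    table["hub"] = False
    table.loc[table.index[:top_k], "hub"] = True
    return table, dist


def clusters_frame(records: list[ClusterRecord]) -> pd.DataFrame:
    rows = []
    for i, r in enumerate(records, start=1):
        rows.append({
            "cluster": f"C{i}", "size": len(r.nodes),
            "cohesiveness": r.cohesiveness, "p": r.p,
            "members": ";".join(sorted(r.nodes)),
            "regimen_counts": ";".join(f"{k}:{v}" for k, v in sorted(r.regimen_counts.items())),
        })
    return pd.DataFrame(rows, columns=["cluster", "size", "cohesiveness", "p",
                                       "members", "regimen_counts"])
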