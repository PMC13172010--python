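"""Global/local network metrics, k-core decomposition, weighted distances,
and cross-network comparison of node-metric distributions."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GlobalMetrics",
    "to_distance_graph",
    "extract_lcc",
    "global_metrics",
    "node_metrics",
    "kcore_histogram",
    "compare_node_distributions",
]


@dataclass(frozen=True)
class GlobalMetrics:
    """Network-level summary; means are computed on the LCC."""

    order: int
    size: int
    pct_negative_edges: float
    edge_density: float
    n_components: int
    lcc_order: int
    mean_degree: float
    mean_shortest_path: float
    mean_betweenness: float
    mean_closeness: float

    def to_series(self) -> pd.Series:
        return pd.Series(
            {
                "order": self.order,
                "size": self.size,
                "pct_negative_edges": self.pct_negative_edges,
                "edge_density": self.edge_density,
                "n_components": self.n_components,
                "lcc_order": self.lcc_order,
                "mean_degree": self.mean_degree,
                "mean_shortest_path": self.mean_shortest_path,
                "mean_betweenness": self.mean_betweenness,
                "mean_closeness": self.mean_closeness,
            }
        )


def _as_graph(network) -> nx.Graph:
    return network.graph if hasattr(network, "graph") and isinstance(
        getattr(network, "graph"), nx.Graph
    ) else network


def to_distance_graph(graph: nx.Graph) -> nx.Graph:
    """Attach per-edge distance d = 1 - w (association strength to cost)."""
    g = graph.copy()
    for u, v, data in g.edges(data=True):
        w = data.get("weight", 1.0)
        data["distance"] = 1.0 - w
    return g


def extract_lcc(network) -> nx.Graph:
    """Induced subgraph on the largest connected component.

    Ties are broken by the lexicographically smallest member node identifier.
    """
    g = _as_graph(network)
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    comps = list(nx.connected_components(g))
    comps.sort(key=lambda c: (-len(c), min(str(n) for n in c)))
    return g.subgraph(comps[0]).copy()


def global_metrics(network, weighted: bool = True) -> GlobalMetrics:
    """Order/size/% negative/density on the full graph; means on the LCC.

    With ``weighted=True``, shortest-path based means use the d = 1 - w
    distance transform; degree is always unweighted.
    """
    g = _as_graph(network)
    n = g.number_of_nodes()
    m = g.number_of_edges()
    n_neg = sum(1 for _, _, d in g.edges(data=True) if d.get("weight", 1.0) < 0)
    pct_neg = 100.0 * n_neg / m if m else 0.0
    density = 2.0 * m / (n * (n - 1)) if n > 1 else 0.0
    n_comp = nx.number_connected_components(g) if n else 0
    lcc = extract_lcc(g)
    nm = node_metrics(lcc, weighted=weighted)
    if lcc.number_of_nodes() > 1:
        dg = to_distance_graph(lcc) if weighted else lcc
        msp = nx.average_shortest_path_length(dg, weight="distance" if weighted else None)
    else:
        msp = 0.0
    return GlobalMetrics(
        order=n,
        size=m,
        pct_negative_edges=pct_neg,
        edge_density=density,
        n_components=n_comp,
        lcc_order=lcc.number_of_nodes(),
        mean_degree=float(nm["degree"].mean()),
        mean_shortest_path=float(msp),
        mean_betweenness=float(nm["betweenness"].mean()),
        mean_closeness=float(nm["closeness"].mean()),
    )


def node_metrics(network, weighted: bool = True) -> pd.DataFrame:
    """Per-node degree, betweenness, closeness and coreness.

    Betweenness/closeness use d = 1 - w distances when ``weighted``;
    betweenness is normalized by (n-1)(n-2)/2. The graph must be connected
    (run on the LCC first).
    """
    g = _as_graph(network)
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if not nx.is_connected(g):
        raise ValueError("graph is disconnected; call extract_lcc first")
    dist = "distance" if weighted else None
    h = to_distance_graph(g) if weighted else g
    betw = nx.betweenness_centrality(h, weight=dist, normalized=True)
    close = nx.closeness_centrality(h, distance=dist)
    core = nx.core_number(nx.Graph(g))  # strip attrs; core_number rejects self-loops
    df = pd.DataFrame(
        {
            "degree": pd.Series(dict(g.degree()), dtype=float),
            "betweenness": pd.Series(betw),
            "closeness": pd.Series(close),
            "coreness": pd.Series(core, dtype=int),
        }
    )
    df.index.name = "node"
    return df.sort_index()


def kcore_histogram(network) -> dict[int, float]:
    """Percentage of all nodes at each coreness value (full graph, not LCC)."""
    g = _as_graph(network)
    n = g.number_of_nodes()
    if n == 0:
        return {}
    core = nx.core_number(nx.Graph(g))
    hist: dict[int, float] = {}
    for k in sorted(set(core.values())):
        hist[k] = 100.0 * sum(1 for v in core.values() if v == k) / n
    return hist


def compare_node_distributions(
    groups: Mapping[str, pd.DataFrame],
    metrics: tuple[str, ...] = ("degree", "betweenness", "closeness"),
    alpha: float = 0.05,
    posthoc: bool = False,
) -> pd.DataFrame:
    """Kruskal–Wallis comparison of node-metric distributions across networks.

    ``groups`` maps group name to a node-metrics frame. P-values are
    Benjamini–Hochberg adjusted across the metric family. With ``posthoc``,
    Dunn-style pairwise rank tests (BH-adjusted) are appended.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    rows = []
    for metric in metrics:
        samples = [np.asarray(df[metric], dtype=float) for df in groups.values()]
        if any(len(s) < 3 for s in samples):
            raise ValueError("each group needs >= 3 nodes")
        pooled = np.concatenate(samples)
        if np.ptp(pooled) == 0:
            warnings.warn(f"metric {metric!r} constant in all groups; p set to 1", stacklevel=2)
            rows.append({"metric": metric, "statistic": 0.0, "pvalue": 1.0})
            continue
        stat, p = stats.kruskal(*samples)
        rows.append({"metric": metric, "statistic": float(stat), "pvalue": float(p)})
    out = pd.DataFrame(rows).set_index("metric")
    out["pvalue_adj"] = multipletests(out["pvalue"], alpha=alpha, method="fdr_bh")[1]
    if posthoc:
        out = pd.concat([out, _dunn_posthoc(groups, metrics)], axis=1)
    return out


def _dunn_posthoc(groups, metrics) -> pd.DataFrame:
    """Pairwise two-sided Mann–Whitney tests with BH correction per metric."""
    names = list(groups)
    cols = {}
    for metric in metrics:
        pvals, labels = [], []
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                a = np.asarray(groups[names[i]][metric], dtype=float)
                b = np.asarray(groups[names[j]][metric], dtype=float)
                if np.ptp(np.concatenate([a, b])) == 0:
                    p = 1.0
                else:
                    p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
                pvals.append(p)
                labels.append(f"{names[i]}|{names[j]}")
        adj = multipletests(pvals, method="fdr_bh")[1]
        cols[metric] = dict(zip(labels, adj))
    frame = pd.DataFrame(cols).T
    frame.index.name = "metric"
    frame.columns = [f"posthoc_{c}" for c in frame.columns]
    return frame
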