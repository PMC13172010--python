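"""Percolation framework: node-removal attacks, LCC decay curves, NR50, p_c.

Attacks operate on the positive-edge subgraph's largest connected component.
Decay curves are computed with a reverse union-find pass, which makes the
1000-repetition random-attack protocol cheap.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from gutnet.topology import extract_lcc, to_distance_graph

logger = logging.getLogger(__name__)

__all__ = [
    "AttackSpec",
    "DecayCurve",
    "RobustnessResult",
    "strip_negative_edges",
    "attack_order",
    "attack_once",
    "nr50",
    "percolation_threshold",
    "run_attack_suite",
]

STRATEGIES = ("random", "degree", "betweenness", "abundance_desc", "abundance_asc")


@dataclass(frozen=True)
class AttackSpec:
    strategy: str = "degree"
    n_reps: int = 1000
    seed: int = 0
    adaptive: bool = False
    weighted_betweenness: bool = True

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}; choose from {STRATEGIES}")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")


@dataclass
class DecayCurve:
    """LCC size after each removal; index k = k nodes removed (k = 0..N)."""

    fraction_removed: np.ndarray
    lcc_size: np.ndarray

    def __post_init__(self) -> None:
        self.fraction_removed = np.asarray(self.fraction_removed, dtype=float)
        self.lcc_size = np.asarray(self.lcc_size, dtype=float)
        if len(self.fraction_removed) != len(self.lcc_size):
            raise ValueError("curve arrays must have equal length")

    @property
    def initial_size(self) -> float:
        return float(self.lcc_size[0])

    @property
    def lcc_norm(self) -> np.ndarray:
        return self.lcc_size / self.initial_size


@dataclass
class RobustnessResult:
    strategy: str
    nr50: float
    pc: Optional[float]
    curve: DecayCurve
    nr50_sd: Optional[float] = None
    nr50_per_rep: Optional[np.ndarray] = None
    curve_sd: Optional[np.ndarray] = None
    order: Optional[Sequence] = field(default=None, repr=False)


def _as_graph(network) -> nx.Graph:
    g = getattr(network, "graph", None)
    return g if isinstance(g, nx.Graph) else network


def strip_negative_edges(network) -> nx.Graph:
    """Keep only positive-weight edges; all nodes are retained."""
    g = _as_graph(network)
    out = nx.Graph()
    out.add_nodes_from(g.nodes(data=True))
    pos = [(u, v, d) for u, v, d in g.edges(data=True) if d.get("weight", 1.0) > 0]
    out.add_edges_from(pos)
    if g.number_of_edges() and not pos:
        warnings.warn("all edges were negative; result has an empty edge set", stacklevel=2)
    return out


def attack_order(network, spec: AttackSpec, rng: Optional[np.random.Generator] = None) -> list:
    """Static node-removal ordering on the intact graph.

    Deterministic strategies sort by the metric (descending for degree /
    betweenness / abundance_desc, ascending abundance for abundance_asc)
    with ties broken by ascending node identifier. ``random`` draws a
    uniform permutation from ``rng``.
    """
    g = _as_graph(network)
    nodes = sorted(g.nodes(), key=str)
    if spec.strategy == "random":
        if rng is None:
            rng = np.random.default_rng(spec.seed)
        perm = rng.permutation(len(nodes))
        return [nodes[i] for i in perm]
    if spec.strategy == "degree":
        metric = dict(g.degree())
    elif spec.strategy == "betweenness":
        if spec.weighted_betweenness:
            metric = nx.betweenness_centrality(
                to_distance_graph(g), weight="distance", normalized=True
            )
        else:
            metric = nx.betweenness_centrality(g, normalized=True)
    else:
        metric = {n: g.nodes[n].get("abundance") for n in g.nodes()}
        if any(v is None for v in metric.values()):
            raise ValueError("abundance-ordered attack requires node 'abundance' attributes")
        if spec.strategy == "abundance_asc":
            return sorted(nodes, key=lambda n: (metric[n], str(n)))
    return sorted(nodes, key=lambda n: (-metric[n], str(n)))


def attack_once(network, order: Sequence) -> DecayCurve:
    """Remove nodes in ``order``, recording LCC size after each removal.

    Implemented by adding nodes in reverse with union-find, so one pass
    costs O(N + E). The curve starts at (0, N0) and ends at (1, 0).
    """
    g = _as_graph(network)
    nodes = list(g.nodes())
    n = len(nodes)
    if sorted(map(str, order)) != sorted(map(str, nodes)):
        raise ValueError("order must be a permutation of the node set")
    pos = {node: i for i, node in enumerate(order)}
    # adjacency in removal-order indices
    adj: list[list[int]] = [[] for _ in range(n)]
    for u, v in g.edges():
        adj[pos[u]].append(pos[v])
        adj[pos[v]].append(pos[u])

    parent = list(range(n))
    size = [1] * n
    active = [False] * n

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    largest = 0
    sizes_after = np.zeros(n + 1)
    # sizes_after[k] = LCC size when nodes order[0..k-1] are removed
    for k in range(n, 0, -1):
        idx = k - 1  # re-insert order[idx]
        active[idx] = True
        for nb in adj[idx]:
            if active[nb]:
                ra, rb = find(idx), find(nb)
                if ra != rb:
                    if size[ra] < size[rb]:
                        ra, rb = rb, ra
                    parent[rb] = ra
                    size[ra] += size[rb]
        largest = max(largest, size[find(idx)])
        sizes_after[idx] = largest
    fractions = np.arange(n + 1) / n if n else np.array([0.0])
    return DecayCurve(fraction_removed=fractions, lcc_size=sizes_after)


def nr50(curve: DecayCurve) -> float:
    """Percentage of removals at which the LCC first holds <= half its
    original node count."""
    n0 = curve.initial_size
    below = np.where(curve.lcc_size <= n0 / 2.0)[0]
    k = int(below[0])
    return 100.0 * k / (len(curve.lcc_size) - 1)


def percolation_threshold(
    curve: DecayCurve, detect_factor: float = 1.5
) -> Optional[float]:
    """Fraction of removed nodes (as %) at the steepest drop of the curve.

    Returns None when the most negative finite-difference slope does not
    exceed the uniform-decay slope by ``detect_factor`` (no clear phase
    transition).
    """
    if len(curve.lcc_size) < 3:
        raise ValueError("curve needs >= 3 points")
    norm = curve.lcc_norm
    frac = curve.fraction_removed
    slopes = np.diff(norm) / np.diff(frac)
    uniform = (norm[-1] - norm[0]) / (frac[-1] - frac[0])
    i = int(np.argmin(slopes))  # earliest on ties
    if slopes[i] > detect_factor * uniform:  # both negative: closer to 0 = shallower
        return None
    return 100.0 * float(frac[i + 1])


def run_attack_suite(
    network,
    specs: Sequence[AttackSpec],
    strip_negatives: bool = True,
    on_lcc: bool = True,
) -> dict[str, RobustnessResult]:
    """Run every attack spec on the (positive-edge, LCC) graph.

    Random attacks report per-rep NR50 values, their mean ± sd, and the
    mean decay curve with a per-point sd band; deterministic strategies
    report a single curve. Per-rep random generators are spawned from the
    spec seed, so results do not depend on evaluation order.
    """
    g = _as_graph(network)
    if strip_negatives:
        g = strip_negative_edges(g)
    if on_lcc:
        g = extract_lcc(g)
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph after preprocessing")
    results: dict[str, RobustnessResult] = {}
    for spec in specs:
        if spec.strategy == "random":
            child_seeds = np.random.SeedSequence(spec.seed).spawn(spec.n_reps)
            curves = []
            vals = np.empty(spec.n_reps)
            for r in range(spec.n_reps):
                rng = np.random.default_rng(child_seeds[r])
                order = attack_order(g, spec, rng=rng)
                c = attack_once(g, order)
                curves.append(c.lcc_size)
                vals[r] = nr50(c)
            stack = np.vstack(curves)
            mean_curve = DecayCurve(
                fraction_removed=np.arange(stack.shape[1]) / max(1, stack.shape[1] - 1),
                lcc_size=stack.mean(axis=0),
            )
            pc_mean = (
                percolation_threshold(mean_curve) if len(mean_curve.lcc_size) >= 3 else None
            )
            results[spec.strategy] = RobustnessResult(
                strategy=spec.strategy,
                nr50=float(vals.mean()),
                pc=pc_mean,
                curve=mean_curve,
                nr50_sd=float(vals.std(ddof=1)) if spec.n_reps > 1 else 0.0,
                nr50_per_rep=vals,
                curve_sd=stack.std(axis=0, ddof=1) if spec.n_reps > 1 else None,
            )
        else:
            order = attack_order(g, spec)
            if spec.adaptive:
                order = _adaptive_order(g, spec)
            c = attack_once(g, order)
            results[spec.strategy] = RobustnessResult(
                strategy=spec.strategy,
                nr50=nr50(c),
                pc=percolation_threshold(c) if len(c.lcc_size) >= 3 else None,
                curve=c,
                order=order,
            )
    return results


def _adaptive_order(g: nx.Graph, spec: AttackSpec) -> list:
    """Recompute the target metric after each removal (sensitivity mode)."""
    h = g.copy()
    order = []
    while h.number_of_nodes():
        sub_spec = AttackSpec(
            strategy=spec.strategy,
            n_reps=1,
            seed=spec.seed,
            adaptive=False,
            weighted_betweenness=spec.weighted_betweenness,
        )
        if spec.strategy == "betweenness" and not nx.is_connected(h) and h.number_of_edges():
            # metric per component; fall back to global ordering on the union
            metric = nx.betweenness_centrality(
                to_distance_graph(h), weight="distance", normalized=True
            )
            target = sorted(h.nodes(), key=lambda n: (-metric[n], str(n)))[0]
        else:
            target = attack_order(h, sub_spec)[0]
        order.append(target)
        h.remove_node(target)
    return order
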