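"""Keystone-taxon detection and ensemble keystone-composition stability."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from gutnet.topology import extract_lcc, node_metrics

__all__ = [
    "KeystoneConfig",
    "detect_keystones",
    "keystones_of_network",
    "ensemble_keystones",
    "presence_pca",
]


@dataclass(frozen=True)
class KeystoneConfig:
    """Keystones = nodes strictly above the q-quantile in BOTH degree and
    betweenness; quantiles use linear interpolation between order statistics."""

    q: float = 0.90
    weighted: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.q < 1:
            raise ValueError("q must lie in (0, 1)")


def detect_keystones(metrics: pd.DataFrame, config: KeystoneConfig = KeystoneConfig()) -> set[str]:
    """Taxa strictly exceeding the q-quantile of both degree and betweenness."""
    if len(metrics) < 10:
        warnings.warn(
            f"only {len(metrics)} nodes; the {config.q:.0%} quantile is unstable", stacklevel=2
        )
    deg_q = float(np.quantile(metrics["degree"], config.q, method="linear"))
    bet_q = float(np.quantile(metrics["betweenness"], config.q, method="linear"))
    mask = (metrics["degree"] > deg_q) & (metrics["betweenness"] > bet_q)
    return set(metrics.index[mask])


def keystones_of_network(network, config: KeystoneConfig = KeystoneConfig()) -> set[str]:
    """Keystones of a CoNetwork/graph, computed on its LCC."""
    lcc = extract_lcc(network)
    metrics = node_metrics(lcc, weighted=config.weighted)
    return detect_keystones(metrics, config)


def ensemble_keystones(
    keystone_sets: Mapping[str, Sequence[set[str]]],
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame, dict[str, set[str]]]:
    """Aggregate keystone sets across an ensemble of networks.

    ``keystone_sets`` maps group name to the list of per-replicate keystone
    sets. Returns (presence matrix, per-group union sizes, pairwise
    group-union intersection counts, per-group core sets present in every
    replicate).
    """
    n_members = sum(len(v) for v in keystone_sets.values())
    if n_members < 2:
        raise ValueError("need >= 2 ensemble members")
    universe = sorted(set().union(*(s for sets in keystone_sets.values() for s in sets)))
    rows, index = [], []
    for group, sets in keystone_sets.items():
        for rep, s in enumerate(sets):
            rows.append([1 if t in s else 0 for t in universe])
            index.append((group, rep))
    presence = pd.DataFrame(
        rows, index=pd.MultiIndex.from_tuples(index, names=["group", "rep"]), columns=universe
    )
    unions = {g: set().union(*sets) if sets else set() for g, sets in keystone_sets.items()}
    set_sizes = pd.Series({g: len(u) for g, u in unions.items()}, name="set_size")
    names = list(keystone_sets)
    inter = pd.DataFrame(0, index=names, columns=names, dtype=int)
    for a in names:
        inter.loc[a, a] = len(unions[a])
    for a, b in combinations(names, 2):
        c = len(unions[a] & unions[b])
        inter.loc[a, b] = inter.loc[b, a] = c
    cores = {
        g: (set.intersection(*map(set, sets)) if sets else set())
        for g, sets in keystone_sets.items()
    }
    return presence, set_sizes, inter, cores


def presence_pca(presence: pd.DataFrame, n_components: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of the centered binary presence matrix.

    Returns per-network coordinates and explained-variance fractions.
    """
    if len(presence) < 3:
        raise ValueError("need >= 3 ensemble members for PCA")
    x = presence.to_numpy(dtype=float)
    xc = x - x.mean(axis=0)
    total_var = float((xc**2).sum())
    if total_var == 0:
        warnings.warn("constant presence matrix; zero-variance PCA", stacklevel=2)
        coords = np.zeros((len(presence), n_components))
        evr = np.zeros(n_components)
    else:
        u, s, _ = np.linalg.svd(xc, full_matrices=False)
        k = min(n_components, len(s))
        coords = np.zeros((len(presence), n_components))
        coords[:, :k] = u[:, :k] * s[:k]
        evr = np.zeros(n_components)
        evr[:k] = (s[:k] ** 2) / (s**2).sum()
    out = pd.DataFrame(
        coords, index=presence.index, columns=[f"PC{i + 1}" for i in range(n_components)]
    )
    return out, evr
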