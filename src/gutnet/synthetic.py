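"""Synthetic compositional data with known conditional-dependence structure.

Generates sparse ground-truth graphs, turns them into positive-definite
precision matrices, and samples compositional count tables under a
logistic-normal-multinomial model so that downstream inference, topology,
keystone and robustness stages can be benchmarked against known truth.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from gutnet.abundance import AbundanceTable

__all__ = [
    "SyntheticSpec",
    "SyntheticDataset",
    "generate_true_graph",
    "graph_to_precision",
    "sample_compositions",
    "generate_dataset",
    "make_group_dataset",
]

#: minimum eigenvalue enforced on generated precision matrices
MIN_EIGENVALUE = 0.05

TOPOLOGIES = ("erdos_renyi", "scale_free", "band", "modular")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic group.

    ``depth_log_mean``/``depth_log_sd`` parameterize the log-normal
    sequencing-depth model (natural-log scale); the default mean depth is
    ``exp(depth_log_mean)`` ~ 1e5 reads.
    """

    n_taxa: int = 30
    n_samples: int = 200
    topology: str = "erdos_renyi"
    target_edge_density: float = 0.1
    edge_weight_range: tuple[float, float] = (0.2, 0.6)
    negative_edge_fraction: float = 0.1
    depth_log_mean: float = math.log(1e5)
    depth_log_sd: float = 0.3
    band_width: int = 1
    n_modules: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 3:
            raise ValueError("n_taxa must be >= 3")
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")
        if self.topology not in TOPOLOGIES:
            raise ValueError(f"unknown topology {self.topology!r}; choose from {TOPOLOGIES}")
        if not 0.0 < self.target_edge_density <= 1.0:
            raise ValueError("target_edge_density must lie in (0, 1]")
        if not 0.0 <= self.negative_edge_fraction <= 1.0:
            raise ValueError("negative_edge_fraction must lie in [0, 1]")
        if self.depth_log_sd < 0:
            raise ValueError("depth_log_sd must be >= 0")
        lo, hi = self.edge_weight_range
        if not 0 < lo <= hi:
            raise ValueError("edge_weight_range must satisfy 0 < lo <= hi")

    def replace(self, **kwargs) -> "SyntheticSpec":
        return dataclasses.replace(self, **kwargs)


@dataclass
class SyntheticDataset:
    """Ground truth plus generated observations for one synthetic group."""

    spec: SyntheticSpec
    true_adjacency: np.ndarray
    precision: np.ndarray
    counts: np.ndarray
    relabund: np.ndarray
    taxon_ids: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)
    group_labels: list[str] = field(default_factory=list)

    @property
    def covariance(self) -> np.ndarray:
        return np.linalg.inv(self.precision)

    def true_edge_set(self) -> set[tuple[int, int]]:
        i, j = np.nonzero(np.triu(self.true_adjacency, k=1))
        return set(zip(i.tolist(), j.tolist()))

    def to_table(self, group: str | None = None) -> AbundanceTable:
        values = pd.DataFrame(self.relabund, index=self.sample_ids, columns=self.taxon_ids)
        meta = pd.DataFrame(index=values.index)
        meta["group"] = self.group_labels if self.group_labels else (group or "synthetic")
        return AbundanceTable(values=values, metadata=meta)


def generate_true_graph(spec: SyntheticSpec) -> np.ndarray:
    """Generate a symmetric binary adjacency matrix with the requested topology.

    Random topologies hit the target density in expectation; the band
    topology is deterministic (width ``spec.band_width``).
    """
    p = spec.n_taxa
    rng = np.random.default_rng(spec.seed)
    if spec.topology == "erdos_renyi":
        g = nx.gnp_random_graph(p, spec.target_edge_density, seed=int(rng.integers(2**31)))
    elif spec.topology == "scale_free":
        # Barabási–Albert with m chosen to approximate the target density
        m = max(1, round(spec.target_edge_density * (p - 1) / 2))
        if m >= p:
            raise ValueError("target_edge_density too high for scale_free topology")
        g = nx.barabasi_albert_graph(p, m, seed=int(rng.integers(2**31)))
    elif spec.topology == "band":
        w = spec.band_width
        if not 1 <= w <= p - 1:
            raise ValueError(f"band_width must lie in [1, {p - 1}]")
        g = nx.Graph()
        g.add_nodes_from(range(p))
        for i in range(p):
            for j in range(i + 1, min(i + w + 1, p)):
                g.add_edge(i, j)
    else:  # modular
        k = spec.n_modules
        sizes = [p // k + (1 if i < p % k else 0) for i in range(k)]
        # dense within modules, sparse between, tuned to overall target density
        p_in = min(1.0, 3.0 * spec.target_edge_density)
        total_pairs = p * (p - 1) / 2
        in_pairs = sum(s * (s - 1) / 2 for s in sizes)
        out_pairs = total_pairs - in_pairs
        p_out = 0.0
        if out_pairs > 0:
            p_out = max(0.0, (spec.target_edge_density * total_pairs - p_in * in_pairs) / out_pairs)
            p_out = min(p_out, 1.0)
        probs = [[p_in if a == b else p_out for b in range(k)] for a in range(k)]
        g = nx.stochastic_block_model(sizes, probs, seed=int(rng.integers(2**31)))
    adj = nx.to_numpy_array(g, nodelist=range(p), dtype=float)
    adj = ((adj + adj.T) > 0).astype(float)
    np.fill_diagonal(adj, 0.0)
    return adj


def graph_to_precision(
    adjacency: np.ndarray,
    edge_weight_range: tuple[float, float] = (0.2, 0.6),
    negative_edge_fraction: float = 0.1,
    seed: int = 0,
    min_eigenvalue: float = MIN_EIGENVALUE,
) -> np.ndarray:
    """Assign signed weights to adjacency support and boost the diagonal to PD.

    The off-diagonal support of the result equals the adjacency exactly;
    positive definiteness is guaranteed by raising the diagonal until the
    smallest eigenvalue exceeds ``min_eigenvalue``.
    """
    adjacency = np.asarray(adjacency, dtype=float)
    if adjacency.shape[0] != adjacency.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(adjacency, adjacency.T):
        raise ValueError("adjacency must be symmetric")
    if np.any(np.diag(adjacency) != 0):
        raise ValueError("adjacency must have zero diagonal")
    rng = np.random.default_rng(seed)
    p = adjacency.shape[0]
    lo, hi = edge_weight_range
    iu = np.triu_indices(p, k=1)
    mags = rng.uniform(lo, hi, size=len(iu[0]))
    signs = np.where(rng.random(len(iu[0])) < negative_edge_fraction, -1.0, 1.0)
    # convention: precision entry -w encodes a positive partial correlation
    omega = np.zeros((p, p))
    omega[iu] = -mags * signs * adjacency[iu]
    omega = omega + omega.T
    np.fill_diagonal(omega, 1.0)
    min_eig = np.linalg.eigvalsh(omega)[0]
    if min_eig < min_eigenvalue:
        omega += np.eye(p) * (min_eigenvalue - min_eig)
    return omega


def sample_compositions(
    precision: np.ndarray,
    n_samples: int,
    depth_log_mean: float = math.log(1e5),
    depth_log_sd: float = 0.3,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw compositional counts under the logistic-normal-multinomial model.

    Latent vectors come from N(0, precision⁻¹); compositions are their
    softmax; counts are multinomial with log-normally distributed depths.
    Returns ``(counts, relabund)`` with each relabund row summing to 1.
    """
    precision = np.asarray(precision, dtype=float)
    eigs = np.linalg.eigvalsh(precision)
    if eigs[0] <= 0:
        raise np.linalg.LinAlgError(
            f"precision matrix is not positive definite (min eigenvalue {eigs[0]:.3g})"
        )
    rng = np.random.default_rng(seed)
    latent = draw_latent(precision, n_samples, rng)
    # row-wise softmax with max subtraction for numerical stability
    shifted = latent - latent.max(axis=1, keepdims=True)
    expz = np.exp(shifted)
    comps = expz / expz.sum(axis=1, keepdims=True)
    depths = np.round(rng.lognormal(depth_log_mean, depth_log_sd, size=n_samples)).astype(np.int64)
    depths = np.maximum(depths, 1)
    counts = np.vstack([rng.multinomial(depths[i], comps[i]) for i in range(n_samples)])
    relabund = counts / depths[:, None]
    return counts, relabund


def draw_latent(precision: np.ndarray, n_samples: int, rng: np.random.Generator) -> np.ndarray:
    """Sample N(0, precision⁻¹) via Cholesky of the precision matrix."""
    p = precision.shape[0]
    chol = np.linalg.cholesky(precision)
    z = rng.standard_normal((n_samples, p))
    # solve L' x = z  =>  cov(x) = (L L')^{-1} = precision^{-1}
    return np.linalg.solve(chol.T, z.T).T


def generate_dataset(spec: SyntheticSpec, group: str = "synthetic") -> SyntheticDataset:
    """Full generator: true graph -> precision -> compositional counts."""
    adj = generate_true_graph(spec)
    omega = graph_to_precision(
        adj, spec.edge_weight_range, spec.negative_edge_fraction, seed=spec.seed + 1
    )
    counts, relabund = sample_compositions(
        omega, spec.n_samples, spec.depth_log_mean, spec.depth_log_sd, seed=spec.seed + 2
    )
    taxa = [f"sp_{i:04d}" for i in range(spec.n_taxa)]
    samples = [f"{group}_s{i:04d}" for i in range(spec.n_samples)]
    return SyntheticDataset(
        spec=spec,
        true_adjacency=adj,
        precision=omega,
        counts=counts,
        relabund=relabund,
        taxon_ids=taxa,
        sample_ids=samples,
        group_labels=[group] * spec.n_samples,
    )


def make_group_dataset(
    specs: Mapping[str, SyntheticSpec],
) -> tuple[AbundanceTable, dict[str, SyntheticDataset]]:
    """Concatenate per-group synthetic datasets into one labeled table.

    Returns the combined abundance table plus per-group ground truth for
    recovery scoring. Taxon identifiers are shared across groups.
    """
    if not specs:
        raise ValueError("at least one group spec is required")
    truths: dict[str, SyntheticDataset] = {}
    frames = []
    metas = []
    seen: set[str] = set()
    for group, spec in specs.items():
        ds = generate_dataset(spec, group=group)
        truths[group] = ds
        dup = seen.intersection(ds.sample_ids)
        if dup:
            raise ValueError(f"duplicate sample identifiers: {sorted(dup)[:5]}")
        seen.update(ds.sample_ids)
        frames.append(pd.DataFrame(ds.relabund, index=ds.sample_ids, columns=ds.taxon_ids))
        metas.append(pd.DataFrame({"group": group}, index=ds.sample_ids))
    values = pd.concat(frames).fillna(0.0)
    metadata = pd.concat(metas)
    return AbundanceTable(values=values, metadata=metadata), truths
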