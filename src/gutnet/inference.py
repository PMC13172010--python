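"""Sparse signed co-occurrence network inference from CLR data.

Per-taxon L1-penalized neighborhood regressions (the Meinshausen–Bühlmann
construction) combined across taxa with an OR rule, with the penalty chosen
by StARS stability selection over repeated subsamples.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.linear_model import lasso_path

logger = logging.getLogger(__name__)

__all__ = [
    "LambdaPath",
    "StarsResult",
    "CoNetwork",
    "InferenceConfig",
    "standardize",
    "compute_lambda_max",
    "fit_mb_graph",
    "symmetrize",
    "make_lambda_path",
    "stars_select",
    "infer_network",
]

_COEF_TOL = 1e-10


@dataclass(frozen=True)
class LambdaPath:
    """Strictly decreasing penalty path starting at the empty-graph penalty."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or len(v) < 2:
            raise ValueError("lambda path needs >= 2 values")
        if np.any(v <= 0) or np.any(np.diff(v) >= 0):
            raise ValueError("lambda path must be strictly decreasing and positive")
        object.__setattr__(self, "values", v)

    @property
    def n_lambda(self) -> int:
        return len(self.values)

    @property
    def min_ratio(self) -> float:
        return float(self.values[-1] / self.values[0])


@dataclass
class StarsResult:
    """Output of StARS stability selection."""

    lambda_path: LambdaPath
    instability: np.ndarray  # raw per-lambda average edge instability
    instability_monotone: np.ndarray
    beta: float
    selected_index: int
    selected_lambda: float
    edge_stability: np.ndarray  # p×p symmetric selection frequencies at selected lambda
    n_subsamples: int
    subsample_size: int
    seed: int
    criterion_met: bool = True


@dataclass
class CoNetwork:
    """Signed, weighted undirected co-occurrence graph over taxa.

    Edge attributes: ``weight`` (signed, on the standardized regression
    scale), ``sign`` ('+'/'-') and, for StARS-derived networks,
    ``stability``. Node attribute ``abundance`` carries the mean relative
    abundance used for abundance-ordered attacks.
    """

    graph: nx.Graph
    provenance: dict = field(default_factory=dict)

    @property
    def order(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def size(self) -> int:
        return self.graph.number_of_edges()


@dataclass(frozen=True)
class InferenceConfig:
    min_abund: float = 0.001
    min_prev: float = 0.10
    pseudocount: float | str = "half-min"
    n_lambda: int = 30
    lambda_min_ratio: float = 0.01
    n_subsamples: int = 100
    beta: float = 0.05
    seed: int = 0


def standardize(x: np.ndarray, drop_constant: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Center and scale columns to unit (population) variance.

    Returns the standardized matrix and the indices of retained columns;
    constant columns are dropped with a warning.
    """
    x = np.asarray(x, dtype=float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    keep = np.where(sd > 1e-12)[0]
    if len(keep) < x.shape[1]:
        if not drop_constant:
            raise ValueError("constant column in CLR matrix")
        warnings.warn(
            f"dropped {x.shape[1] - len(keep)} constant column(s) before standardization",
            stacklevel=2,
        )
    z = (x[:, keep] - mu[keep]) / sd[keep]
    return z, keep


def compute_lambda_max(clr) -> float:
    """Smallest penalty at which every neighborhood regression is empty.

    Computed as the largest absolute cross-correlation between any pair of
    distinct standardized columns (the lasso path endpoint for the
    1/(2n)·RSS + λ·L1 objective on standardized data).
    """
    x = clr.to_numpy() if isinstance(clr, pd.DataFrame) else np.asarray(clr, dtype=float)
    if x.shape[1] < 2 or x.shape[0] < 3:
        raise ValueError("need >= 2 taxa and >= 3 samples")
    z, _ = standardize(x)
    n = z.shape[0]
    c = np.abs(z.T @ z) / n
    np.fill_diagonal(c, 0.0)
    return float(c.max())


def _fit_neighborhoods(z: np.ndarray, lambdas: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Coefficient cube for all nodes over a decreasing penalty path.

    Returns shape (n_lambda, p, p): entry [l, j, k] is the coefficient of
    predictor k in the lasso regression of column j at penalty lambdas[l];
    the diagonal is zero.
    """
    n, p = z.shape
    out = np.zeros((len(lambdas), p, p))
    idx = np.arange(p)
    for j in range(p):
        mask = idx != j
        xj = z[:, mask]
        yj = z[:, j]
        _, coefs, _ = lasso_path(xj, yj, alphas=lambdas, max_iter=5000, tol=tol)
        # lasso_path returns coefs for alphas in decreasing order
        out[:, j, mask] = coefs.T
    return out


def fit_mb_graph(clr, lam: float) -> np.ndarray:
    """Directed neighborhood coefficient matrix at a single penalty.

    Row j holds the coefficients of taxon j's lasso regression on all other
    (standardized) CLR columns.
    """
    if lam <= 0:
        raise ValueError("lambda must be positive")
    x = clr.to_numpy() if isinstance(clr, pd.DataFrame) else np.asarray(clr, dtype=float)
    z, keep = standardize(x)
    if len(keep) != x.shape[1]:
        raise ValueError("constant CLR column; filter before fitting")
    lam_hi = max(lam * 2, lam + 1.0)
    cube = _fit_neighborhoods(z, np.array([lam_hi, lam]))
    return cube[1]


def symmetrize(coefficients: np.ndarray, rule: str = "or") -> tuple[np.ndarray, int]:
    """Merge directed neighborhoods into symmetric signed weights.

    OR rule: an edge exists when either direction is nonzero; the weight is
    the entry of larger magnitude (sign preserved). AND rule: both
    directions must be nonzero. Returns (weights, n_sign_conflicts).
    """
    b = np.asarray(coefficients, dtype=float)
    bt = b.T
    pick_b = np.abs(b) >= np.abs(bt)
    w = np.where(pick_b, b, bt)
    if rule == "or":
        present = (np.abs(b) > _COEF_TOL) | (np.abs(bt) > _COEF_TOL)
    elif rule == "and":
        present = (np.abs(b) > _COEF_TOL) & (np.abs(bt) > _COEF_TOL)
    else:
        raise ValueError("rule must be 'or' or 'and'")
    w = np.where(present, w, 0.0)
    both = (np.abs(b) > _COEF_TOL) & (np.abs(bt) > _COEF_TOL)
    conflicts = both & (np.sign(b) != np.sign(bt))
    n_conflicts = int(np.triu(conflicts, k=1).sum())
    if n_conflicts:
        logger.info("sign conflicts between directed coefficients: %d edge(s)", n_conflicts)
    np.fill_diagonal(w, 0.0)
    return w, n_conflicts


def make_lambda_path(clr, n_lambda: int = 30, min_ratio: float = 0.01) -> LambdaPath:
    lmax = compute_lambda_max(clr)
    return LambdaPath(np.geomspace(lmax, lmax * min_ratio, n_lambda))


def _support_cube(z: np.ndarray, lambdas: np.ndarray) -> np.ndarray:
    """Boolean (n_lambda, p, p) OR-symmetrized edge indicators along a path.

    Subsample fits use a looser solver tolerance than the final full-data
    fit: only the support matters here.
    """
    cube = _fit_neighborhoods(z, lambdas, tol=1e-5)
    nz = np.abs(cube) > _COEF_TOL
    return nz | np.swapaxes(nz, 1, 2)


def stars_select(
    clr,
    path: Optional[LambdaPath] = None,
    n_subsamples: int = 100,
    beta: float = 0.05,
    seed: int = 0,
    n_lambda: int = 30,
    lambda_min_ratio: float = 0.01,
) -> StarsResult:
    """StARS penalty selection for the MB neighborhood graph.

    Draws ``n_subsamples`` subsamples without replacement of size
    ``b = min(floor(10*sqrt(n)), floor(0.8*n))``, computes per-edge selection
    frequencies along the path, averages the edge instability 2θ(1−θ),
    monotonizes it along decreasing λ, and selects the smallest λ whose
    monotonized instability stays within ``beta``.
    """
    x = clr.to_numpy() if isinstance(clr, pd.DataFrame) else np.asarray(clr, dtype=float)
    n, p = x.shape
    if n < 20:
        raise ValueError("StARS needs >= 20 samples")
    if path is None:
        path = make_lambda_path(x, n_lambda=n_lambda, min_ratio=lambda_min_ratio)
    lambdas = path.values
    b = min(int(np.floor(10 * np.sqrt(n))), int(np.floor(0.8 * n)))
    rng = np.random.default_rng(seed)
    counts = np.zeros((len(lambdas), p, p))
    for _ in range(n_subsamples):
        rows = rng.choice(n, size=b, replace=False)
        zs, keep = standardize(x[rows])
        sup = _support_cube(zs, lambdas)
        if len(keep) != p:  # map back through dropped constant columns
            full = np.zeros((len(lambdas), p, p), dtype=bool)
            full[np.ix_(range(len(lambdas)), keep, keep)] = sup
            sup = full
        counts += sup
    theta = counts / n_subsamples
    iu = np.triu_indices(p, k=1)
    inst_per_edge = 2.0 * theta * (1.0 - theta)
    instability = inst_per_edge[:, iu[0], iu[1]].mean(axis=1)
    monotone = np.maximum.accumulate(instability)
    ok = np.where(monotone <= beta)[0]
    criterion_met = True
    if len(ok):
        selected = int(ok[-1])  # smallest lambda (densest) still within beta
    else:
        selected = int(np.argmin(monotone))
        criterion_met = False
        warnings.warn(
            f"no lambda reaches instability <= {beta}; returning the most stable point",
            stacklevel=2,
        )
    return StarsResult(
        lambda_path=path,
        instability=instability,
        instability_monotone=monotone,
        beta=beta,
        selected_index=selected,
        selected_lambda=float(lambdas[selected]),
        edge_stability=theta[selected],
        n_subsamples=n_subsamples,
        subsample_size=b,
        seed=seed,
        criterion_met=criterion_met,
    )


def network_from_weights(
    weights: np.ndarray,
    taxon_ids: list[str],
    abundances: Optional[dict[str, float]] = None,
    stability: Optional[np.ndarray] = None,
    provenance: Optional[dict] = None,
) -> CoNetwork:
    """Build a CoNetwork from a symmetric signed weight matrix."""
    g = nx.Graph()
    for i, t in enumerate(taxon_ids):
        g.add_node(t, abundance=float(abundances.get(t, 0.0)) if abundances else 0.0)
    iu = np.triu_indices(len(taxon_ids), k=1)
    for i, j in zip(*iu):
        w = weights[i, j]
        if abs(w) > _COEF_TOL:
            attrs = {"weight": float(w), "sign": "+" if w > 0 else "-"}
            if stability is not None:
                attrs["stability"] = float(stability[i, j])
            g.add_edge(taxon_ids[i], taxon_ids[j], **attrs)
    return CoNetwork(graph=g, provenance=provenance or {})


def infer_network(table, config: InferenceConfig = InferenceConfig()) -> CoNetwork:
    """Full inference pipeline: filter → CLR → λ path → StARS → CoNetwork."""
    from gutnet.abundance import clr_transform, prevalence_abundance_filter

    if table.n_taxa == 0 or table.n_samples == 0:
        raise ValueError("empty abundance table")
    filtered = prevalence_abundance_filter(table, config.min_abund, config.min_prev)
    clr = clr_transform(filtered, config.pseudocount)
    path = make_lambda_path(clr, n_lambda=config.n_lambda, min_ratio=config.lambda_min_ratio)
    stars = stars_select(
        clr,
        path=path,
        n_subsamples=config.n_subsamples,
        beta=config.beta,
        seed=config.seed,
    )
    z, keep = standardize(clr.to_numpy())
    taxa = [filtered.taxon_ids[i] for i in keep]
    cube = _fit_neighborhoods(z, np.array([path.values[0] * 1.01, stars.selected_lambda]))
    weights, n_conflicts = symmetrize(cube[1])
    abunds = filtered.values.mean(axis=0).to_dict()
    prov = {
        "min_abund": config.min_abund,
        "min_prev": config.min_prev,
        "n_lambda": config.n_lambda,
        "lambda_min_ratio": config.lambda_min_ratio,
        "n_subsamples": config.n_subsamples,
        "beta": config.beta,
        "seed": config.seed,
        "selected_lambda": stars.selected_lambda,
        "stars_criterion_met": stars.criterion_met,
        "sign_conflicts": n_conflicts,
    }
    stab = stars.edge_stability
    if len(keep) != clr.shape[1]:
        stab = stab[np.ix_(keep, keep)]
    return network_from_weights(weights, taxa, abunds, stability=stab, provenance=prov)
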