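"""Abundance-table and edge-list I/O, prevalence filtering, CLR transform."""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AbundanceTable",
    "read_metaphlan_table",
    "write_metaphlan_table",
    "read_abundance_tsv",
    "write_abundance_tsv",
    "prevalence_abundance_filter",
    "clr_transform",
    "read_edge_list",
    "write_edge_list",
    "write_graphml",
]

_SOURCE_ALIASES = ("source", "from", "node1", "taxon1", "v1")
_TARGET_ALIASES = ("target", "to", "node2", "taxon2", "v2")
_WEIGHT_ALIASES = ("weight", "value", "w", "assoc")


@dataclass
class AbundanceTable:
    """Samples × taxa relative abundances with per-sample metadata.

    ``values`` rows are samples, columns are taxa. Per-sample totals may be
    slightly below 1 for species-level tables (unclassified mass removed).
    """

    values: pd.DataFrame
    metadata: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate sample identifiers")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate taxon identifiers")
        if (self.values.values < 0).any():
            raise ValueError("abundances must be nonnegative")
        totals = self.values.sum(axis=1)
        if (totals > 1 + 1e-6).any():
            bad = totals[totals > 1 + 1e-6].index[0]
            raise ValueError(f"sample {bad!r} has total abundance > 1")
        if self.metadata is None or self.metadata.empty:
            self.metadata = pd.DataFrame(index=self.values.index)
        else:
            self.metadata = self.metadata.reindex(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids: Iterable[str]) -> "AbundanceTable":
        ids = list(sample_ids)
        return AbundanceTable(self.values.loc[ids], self.metadata.loc[ids])

    def groups(self, column: str = "group") -> dict[str, "AbundanceTable"]:
        if column not in self.metadata.columns:
            raise KeyError(f"metadata column {column!r} not found")
        out = {}
        for g, sub in self.metadata.groupby(column, sort=True):
            out[str(g)] = self.subset_samples(sub.index)
        return out


def _is_species_clade(clade: str) -> bool:
    return "s__" in clade and "t__" not in clade


def _species_name(clade: str) -> str:
    for part in reversed(clade.split("|")):
        if part.startswith("s__"):
            return part[3:]
    return clade


def read_metaphlan_table(path, species_only: bool = True) -> AbundanceTable:
    """Read a MetaPhlAn-style merged profile table (taxa rows × sample columns).

    Keeps species-level rows (clade contains a species rank and no strain
    rank) and rescales percentages to fractions when column maxima exceed 1.5.
    """
    df = pd.read_csv(path, sep="\t", comment="#", header=0, index_col=0)
    if df.empty:
        raise ValueError(f"no data rows found in {path}")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from exc
    if species_only:
        keep = [c for c in df.index if _is_species_clade(str(c))]
        df = df.loc[keep]
        df.index = [_species_name(str(c)) for c in df.index]
    if (df.max(axis=0) > 1.5).any():
        df = df / 100.0
    values = df.T  # samples × taxa
    values.index.name = "sample_id"
    return AbundanceTable(values=values)


def write_metaphlan_table(table: AbundanceTable, path, as_percent: bool = True) -> None:
    df = table.values.T
    if as_percent:
        df = df * 100.0
    df.index.name = "clade_name"
    df.to_csv(path, sep="\t")


def read_abundance_tsv(path, metadata_path=None) -> AbundanceTable:
    """Read a plain samples × taxa TSV (first column = sample id)."""
    values = pd.read_csv(path, sep="\t", comment="#", index_col=0).astype(float)
    meta = None
    if metadata_path is not None:
        meta = pd.read_csv(metadata_path, sep="\t", comment="#", index_col=0)
    return AbundanceTable(values=values, metadata=meta if meta is not None else pd.DataFrame())


def write_abundance_tsv(table: AbundanceTable, path) -> None:
    df = table.values.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def prevalence_abundance_filter(
    table: AbundanceTable,
    min_abund: float = 0.001,
    min_prev: float = 0.10,
    per_group: str | None = None,
) -> AbundanceTable:
    """Keep taxa exceeding ``min_abund`` in at least ``ceil(min_prev * n)`` samples.

    With ``per_group`` set to a metadata column, a taxon is kept if it passes
    the criterion within at least one group.
    """
    if not 0 < min_abund < 1:
        raise ValueError("min_abund must lie in (0, 1)")
    if not 0 < min_prev <= 1:
        raise ValueError("min_prev must lie in (0, 1]")

    def _passes(values: pd.DataFrame) -> pd.Series:
        n = values.shape[0]
        required = math.ceil(min_prev * n)
        return (values > min_abund).sum(axis=0) >= required

    if per_group is None:
        keep = _passes(table.values)
    else:
        if per_group not in table.metadata.columns:
            raise KeyError(f"metadata column {per_group!r} not found")
        keep = pd.Series(False, index=table.values.columns)
        for _, sub in table.metadata.groupby(per_group):
            keep |= _passes(table.values.loc[sub.index])
    kept = [t for t in table.taxon_ids if keep[t]]
    if not kept:
        raise ValueError("prevalence/abundance filter removed all taxa")
    logger.info("filter kept %d/%d taxa", len(kept), table.n_taxa)
    return AbundanceTable(values=table.values[kept], metadata=table.metadata)


def clr_transform(table: AbundanceTable, pseudocount: float | str = "half-min") -> pd.DataFrame:
    """Centered log-ratio transform of a nonnegative abundance table.

    Zeros are replaced by a pseudocount (default: half the smallest nonzero
    value of the whole table), each row is re-closed to sum 1, then logged
    and centered so every CLR row sums to 0.
    """
    values = table.values.to_numpy(dtype=float)
    zero_rows = np.where(values.sum(axis=1) == 0)[0]
    if zero_rows.size:
        raise ValueError(f"sample {table.sample_ids[zero_rows[0]]!r} is all zeros")
    if pseudocount == "half-min":
        nonzero = values[values > 0]
        pc = float(nonzero.min()) / 2.0
    else:
        pc = float(pseudocount)
        if pc <= 0:
            raise ValueError("pseudocount must be positive")
    filled = np.where(values > 0, values, pc)
    closed = filled / filled.sum(axis=1, keepdims=True)
    logged = np.log(closed)
    clr = logged - logged.mean(axis=1, keepdims=True)
    return pd.DataFrame(clr, index=table.values.index, columns=table.values.columns)


def _resolve_columns(columns: list[str]) -> tuple[str, str, str] | None:
    low = {c.lower().strip(): c for c in columns}
    src = next((low[a] for a in _SOURCE_ALIASES if a in low), None)
    tgt = next((low[a] for a in _TARGET_ALIASES if a in low), None)
    wgt = next((low[a] for a in _WEIGHT_ALIASES if a in low), None)
    if src and tgt and wgt:
        return src, tgt, wgt
    return None


def read_edge_list(path) -> nx.Graph:
    """Read a signed, weighted undirected edge list from TSV.

    Column names are matched tolerantly (source/target/from/to, weight/value);
    a headerless three-column file is also accepted. Duplicate undirected
    pairs are collapsed (first occurrence wins, warning logged); self-loops
    are rejected.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    resolved = _resolve_columns(list(df.columns))
    if resolved is None:
        # maybe headerless: re-read without header
        df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
        if df.shape[1] < 3:
            raise ValueError(f"edge list {path} needs >= 3 columns (source, target, weight)")
        df = df.iloc[:, :3]
        df.columns = ["source", "target", "weight"]
        resolved = ("source", "target", "weight")
    src, tgt, wgt = resolved
    g = nx.Graph()
    n_dup = 0
    i_src, i_tgt, i_wgt = (df.columns.get_loc(c) for c in (src, tgt, wgt))
    for row in df.itertuples(index=False):
        u = str(row[i_src])
        v = str(row[i_tgt])
        raw_w = row[i_wgt]
        try:
            w = float(raw_w)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"non-numeric weight {raw_w!r} for edge ({u}, {v})") from exc
        if u == v:
            raise ValueError(f"self-loop on node {u!r} not allowed")
        if g.has_edge(u, v):
            n_dup += 1
            continue
        g.add_edge(u, v, weight=w, sign="+" if w >= 0 else "-")
    if n_dup:
        warnings.warn(f"collapsed {n_dup} duplicate undirected edge(s)", stacklevel=2)
    return g


def write_edge_list(graph: nx.Graph, path, header_lines: Iterable[str] = ()) -> None:
    """Write an undirected weighted graph as a source/target/weight TSV."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("source\ttarget\tweight\n")
        for u, v, data in sorted(graph.edges(data=True)):
            fh.write(f"{u}\t{v}\t{data.get('weight', 1.0):.17g}\n")


def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, path)
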