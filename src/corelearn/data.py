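"""Gene universe, typed multi-network graphs and robust feature scaling.

The data model mirrors how gene-level machine learning on molecular networks
is usually set up: a fixed, ordered universe of genes (the nodes), one or more
edge sets sourced from different networks (protein-protein interaction
networks are undirected, gene-regulatory networks run TF -> target), and a
genes x features numeric matrix of node features.  All networks share the
same node set; genes absent from the feature table are excluded everywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("corelearn")


class EdgeListParseError(ValueError):
    """Raised when an edge-list file cannot be parsed."""


@dataclass(frozen=True)
class EdgeRecord:
    """A raw (source, target) gene pair tagged with its network of origin."""

    source: str
    target: str
    network: str
    directed: bool


@dataclass
class GeneUniverse:
    """Ordered, unique gene identifiers with a gene -> position map."""

    genes: list[str]
    index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene identifiers must be unique")
        self.index = {g: i for i, g in enumerate(self.genes)}

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.index


@dataclass
class GeneGraph:
    """Typed directed edge sets from one or more networks over a universe.

    Undirected source networks are stored with both directions present;
    directed networks keep only the TF -> target orientation.  Each edge
    carries an implicit weight of 1; the self-loop used by spectral graph
    convolutions is added inside the layer, not here.
    """

    universe: GeneUniverse
    edge_sets: dict[str, np.ndarray]  # name -> (E, 2) int array of (src, dst)
    directed_flags: dict[str, bool]

    def __post_init__(self) -> None:
        n = len(self.universe)
        for name, edges in self.edge_sets.items():
            edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
            if edges.size and (edges.min() < 0 or edges.max() >= n):
                raise ValueError(f"network {name!r}: endpoint index out of range")
            self.edge_sets[name] = edges

    @property
    def network_names(self) -> list[str]:
        return list(self.edge_sets)

    def n_edges(self, network: str | None = None) -> int:
        if network is not None:
            return len(self.edge_sets[network])
        return sum(len(e) for e in self.edge_sets.values())

    def merged_edges(self) -> np.ndarray:
        """Union of all edge sets as one (E, 2) array (types dropped)."""
        parts = [e for e in self.edge_sets.values() if len(e)]
        if not parts:
            return np.empty((0, 2), dtype=np.int64)
        return np.vstack(parts)

    def to_edge_list_files(self, directory: str | Path) -> list[Path]:
        """Write one TSV per network (undirected networks written once per pair)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = []
        genes = self.universe.genes
        for name, edges in self.edge_sets.items():
            path = directory / f"{name}.tsv"
            if not self.directed_flags[name]:
                # keep one representative per unordered pair (self-loops once)
                seen = set()
                rows = []
                for s, t in edges:
                    key = (min(s, t), max(s, t))
                    if key not in seen:
                        seen.add(key)
                        rows.append((s, t))
            else:
                rows = [tuple(e) for e in edges]
            with open(path, "w") as fh:
                for s, t in rows:
                    fh.write(f"{genes[s]}\t{genes[t]}\n")
            paths.append(path)
        return paths


@dataclass
class FeatureMatrix:
    """Genes x features numeric matrix with optional robust-scaling metadata."""

    universe: GeneUniverse
    values: np.ndarray
    feature_names: list[str]
    scaling: dict[str, np.ndarray] | None = None  # {"median": (p,), "iqr": (p,)}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if self.values.shape[0] != len(self.universe):
            raise ValueError("row count must match universe size")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length must match column count")
        if self.values.shape[1] == 0:
            raise ValueError("feature matrix needs at least one column")
        if np.isnan(self.values).any():
            raise ValueError("feature matrix contains missing values")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class LabelSet:
    """Positive-label gene indices for one disease/trait."""

    positives: set[int]
    name: str = "positives"

    def validate(self, universe: GeneUniverse) -> None:
        n = len(universe)
        if any(i < 0 or i >= n for i in self.positives):
            raise ValueError("positive index outside universe")


# ---------------------------------------------------------------------------
# Reading and assembling
# ---------------------------------------------------------------------------

def read_edge_list(
    path: str | Path,
    network_name: str,
    directed: bool,
    *,
    header: bool = False,
) -> list[EdgeRecord]:
    """Read a two-column (or wider) TSV edge list into raw edge records.

    Extra columns beyond source/target are ignored.  Self-edges are preserved
    as given.  With ``header=True`` the first non-empty line is skipped.
    """
    path = Path(path)
    records: list[EdgeRecord] = []
    skipped_header = not header
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if not skipped_header:
                skipped_header = True
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise EdgeListParseError(
                    f"{path}:{lineno}: expected >=2 tab-separated gene "
                    f"identifiers, got {line!r}"
                )
            records.append(
                EdgeRecord(fields[0].strip(), fields[1].strip(), network_name, directed)
            )
    if not records:
        raise EdgeListParseError(f"{path}: no edges found")
    return records


def assemble_graph(records: Iterable[EdgeRecord], universe: GeneUniverse) -> GeneGraph:
    """Build a typed GeneGraph, expanding undirected records to both directions.

    Records with endpoints outside the universe are dropped (count logged);
    duplicate (source, target) rows within one network are deduplicated
    (count logged).  Isolated universe genes are retained.
    """
    idx = universe.index
    per_network: dict[str, list[tuple[int, int]]] = {}
    directed_flags: dict[str, bool] = {}
    seen: dict[str, set[tuple[int, int]]] = {}
    dropped = 0
    duplicates = 0
    for rec in records:
        if rec.network in directed_flags and directed_flags[rec.network] != rec.directed:
            raise ValueError(f"network {rec.network!r} has inconsistent directedness")
        directed_flags.setdefault(rec.network, rec.directed)
        per_network.setdefault(rec.network, [])
        seen.setdefault(rec.network, set())
        if rec.source not in idx or rec.target not in idx:
            dropped += 1
            continue
        s, t = idx[rec.source], idx[rec.target]
        if (s, t) in seen[rec.network]:
            duplicates += 1
            continue
        if rec.directed:
            seen[rec.network].add((s, t))
            per_network[rec.network].append((s, t))
        else:
            seen[rec.network].add((s, t))
            seen[rec.network].add((t, s))
            per_network[rec.network].append((s, t))
            if s != t:
                per_network[rec.network].append((t, s))
    if dropped:
        logger.info("assemble_graph: dropped %d edges outside universe", dropped)
    if duplicates:
        logger.info("assemble_graph: skipped %d duplicate rows", duplicates)
    edge_sets = {
        name: np.asarray(edges, dtype=np.int64).reshape(-1, 2)
        for name, edges in per_network.items()
    }
    return GeneGraph(universe=universe, edge_sets=edge_sets, directed_flags=directed_flags)


def resolve_gene_universe(
    feature_table: pd.DataFrame,
    label_genes: Sequence[str],
    label_name: str = "positives",
) -> tuple[GeneUniverse, FeatureMatrix, LabelSet]:
    """Filter to genes with complete features; intersect labels with survivors.

    The first column of ``feature_table`` must hold gene identifiers; all
    remaining columns must be numeric.  Genes with any missing feature are
    excluded (the universe is feature-driven).
    """
    table = feature_table.copy()
    gene_col = table.columns[0]
    table = table.set_index(gene_col)
    for col in table.columns:
        if not np.issubdtype(table[col].dtype, np.number):
            coerced = pd.to_numeric(table[col], errors="coerce")
            if coerced.isna().sum() > table[col].isna().sum():
                raise ValueError(f"feature column {col!r} is not numeric")
            table[col] = coerced
    complete = table.dropna(axis=0)
    n_excluded = len(table) - len(complete)
    if n_excluded:
        logger.info("resolve_gene_universe: excluded %d genes with missing features",
                    n_excluded)
    if complete.empty:
        raise ValueError("no genes with complete features remain")
    universe = GeneUniverse(list(complete.index.astype(str)))
    fm = FeatureMatrix(
        universe=universe,
        values=complete.to_numpy(dtype=np.float64),
        feature_names=list(complete.columns.astype(str)),
    )
    positives = set()
    n_missing = 0
    for g in label_genes:
        if g in universe:
            positives.add(universe.index[g])
        else:
            n_missing += 1
    if n_missing:
        logger.warning("resolve_gene_universe: %d label genes absent from the "
                       "feature table were dropped", n_missing)
    if not positives:
        raise ValueError("no positive labels survive universe filtering")
    return universe, fm, LabelSet(positives=positives, name=label_name)


def read_label_file(path: str | Path) -> list[str]:
    """One gene identifier per line; '#' comments and blank lines allowed."""
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                genes.append(line)
    return genes


def scale_features_robust(fm: FeatureMatrix) -> FeatureMatrix:
    """Scale each column to (x - median) / IQR, IQR = q75 - q25.

    Quantiles use linear interpolation between order statistics.  Columns with
    zero IQR are centered only.  Scaling parameters are recorded on the
    returned matrix.
    """
    if fm.scaling is not None:
        raise ValueError("feature matrix is already scaled")
    X = fm.values
    median = np.median(X, axis=0)
    q25, q75 = np.percentile(X, [25, 75], axis=0)
    iqr = q75 - q25
    denom = np.where(iqr == 0, 1.0, iqr)
    scaled = (X - median) / denom
    return FeatureMatrix(
        universe=fm.universe,
        values=scaled,
        feature_names=list(fm.feature_names),
        scaling={"median": median, "iqr": iqr},
    )
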