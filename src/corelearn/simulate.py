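"""Seeded synthetic benchmark: multi-network graphs, features, PU labels.

The generator plants a latent per-gene "coreness" (standard normal) and builds
everything downstream of it:

* networks — Erdos-Renyi or preferential-attachment random graphs over the
  gene universe (PPI-like undirected, GRN-like directed);
* features — informative columns are ``effect_size * coreness + N(0,1)``,
  noise columns pure ``N(0,1)``;
* positive-unlabeled labels — the top ``core_fraction`` of coreness are true
  cores, and each core is labeled independently with probability
  ``logistic(slope * (coreness - core_threshold))``.  With slope > 0 the label
  frequency rises toward the extreme of the positive distribution, emulating
  the selected-at-random-with-probabilistic-gap (SAR-PGPU) regime in which
  "extreme" positives (e.g. Mendelian disorder genes) are over-represented
  among the labels while milder true positives stay unlabeled;
* a validation gene set whose membership odds ratio for cores vs non-cores is
  controlled, emulating external validation resources such as mouse-knockout
  phenotype gene sets.

Identical config + seed give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path


import networkx as nx
import numpy as np

from .data import FeatureMatrix, GeneGraph, GeneUniverse, LabelSet

_MAX_SLOPE = 1e6  # cap for "infinite" label-frequency slope


@dataclass(frozen=True)
class NetworkSpec:
    name: str
    model: str  # "erdos-renyi" | "preferential-attachment"
    mean_degree: float
    directed: bool = False


@dataclass(frozen=True)
class SimulationConfig:
    n_genes: int = 2000
    networks: tuple[NetworkSpec, ...] = (
        NetworkSpec("ppi", "erdos-renyi", 4.0, directed=False),
        NetworkSpec("grn", "preferential-attachment", 4.0, directed=True),
    )
    n_informative_features: int = 5
    n_noise_features: int = 5
    effect_size: float = 2.0
    core_fraction: float = 0.05
    label_frequency_slope: float = 3.0
    validation_or: float = 5.0
    validation_base_rate: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.core_fraction < 0.5:
            raise ValueError("core_fraction must be in (0, 0.5)")
        if self.n_genes <= 0 or self.n_informative_features <= 0:
            raise ValueError("counts must be positive")
        if self.n_noise_features < 0:
            raise ValueError("n_noise_features must be >= 0")
        if self.label_frequency_slope < 0:
            raise ValueError("label_frequency_slope must be >= 0")


@dataclass
class PlantedTruth:
    """Ground truth of one simulation draw."""

    coreness: np.ndarray
    true_cores: set[int]
    labeled_positives: set[int]
    hidden_positives: set[int] = field(init=False)
    validation_members: set[int] = field(default_factory=set)

    def __post_init__(self):
        if not self.labeled_positives <= self.true_cores:
            raise ValueError("labeled positives must be true cores")
        self.hidden_positives = self.true_cores - self.labeled_positives


def _universe(n_genes: int) -> GeneUniverse:
    width = len(str(n_genes - 1))
    return GeneUniverse([f"G{i:0{width}d}" for i in range(n_genes)])


def simulate_networks(cfg: SimulationConfig, universe: GeneUniverse | None = None) -> GeneGraph:
    """One random edge set per configured network, deterministic under seed."""
    universe = universe or _universe(cfg.n_genes)
    n = len(universe)
    edge_sets: dict[str, np.ndarray] = {}
    directed_flags: dict[str, bool] = {}
    for k, spec in enumerate(cfg.networks):
        net_seed = (cfg.seed * 1000003 + 7919 * k + 1) % (2**31)
        if spec.mean_degree <= 0:
            edges = np.empty((0, 2), dtype=np.int64)
        elif spec.model == "erdos-renyi":
            p = min(spec.mean_degree / max(n - 1, 1), 1.0)
            g = nx.gnp_random_graph(n, p, seed=net_seed, directed=spec.directed)
            edges = np.asarray(list(g.edges()), dtype=np.int64).reshape(-1, 2)
        elif spec.model == "preferential-attachment":
            m = max(1, int(round(spec.mean_degree / 2)))
            g = nx.barabasi_albert_graph(n, m, seed=net_seed)
            edges = np.asarray(list(g.edges()), dtype=np.int64).reshape(-1, 2)
        else:
            raise ValueError(f"unknown network model {spec.model!r}")
        if not spec.directed and len(edges):
            # emit both directions for undirected models
            edges = np.vstack([edges, edges[:, ::-1]])
        edge_sets[spec.name] = edges
        directed_flags[spec.name] = spec.directed
    return GeneGraph(universe=universe, edge_sets=edge_sets, directed_flags=directed_flags)


def draw_coreness(cfg: SimulationConfig) -> np.ndarray:
    rng = np.random.default_rng(cfg.seed)
    return rng.standard_normal(cfg.n_genes)


def simulate_features(
    cfg: SimulationConfig,
    coreness: np.ndarray,
    universe: GeneUniverse | None = None,
) -> FeatureMatrix:
    """Linear-Gaussian features: informative columns track coreness.

    Column names carry an ``inf_``/``noise_`` prefix so tests can introspect
    which columns are informative.
    """
    universe = universe or _universe(cfg.n_genes)
    rng = np.random.default_rng((cfg.seed * 1000003 + 13) % (2**31))
    n = len(coreness)
    p = cfg.n_informative_features + cfg.n_noise_features
    X = rng.standard_normal((n, p))
    X[:, : cfg.n_informative_features] += cfg.effect_size * coreness[:, None]
    names = [f"inf_{i}" for i in range(cfg.n_informative_features)] + [
        f"noise_{i}" for i in range(cfg.n_noise_features)
    ]
    return FeatureMatrix(universe=universe, values=X, feature_names=names)


def assign_pu_labels(cfg: SimulationConfig, coreness: np.ndarray) -> PlantedTruth:
    """Top ``core_fraction`` genes are cores; labels follow a logistic ramp.

    Each core is labeled independently with probability
    ``logistic(slope * (coreness - threshold))``; slope 0 gives uniform 0.5
    labeling, large slopes approach a sharp cut above the core threshold.
    Non-cores are never labeled.  If no core is labeled, labels are redrawn
    (training needs at least one positive).
    """
    rng = np.random.default_rng((cfg.seed * 1000003 + 29) % (2**31))
    n = len(coreness)
    n_cores = max(1, int(round(cfg.core_fraction * n)))
    order = np.argsort(coreness)[::-1]
    core_idx = order[:n_cores]
    threshold = coreness[core_idx].min()
    slope = min(cfg.label_frequency_slope, _MAX_SLOPE)
    with np.errstate(over="ignore"):
        p_label = 1.0 / (1.0 + np.exp(-slope * (coreness[core_idx] - threshold)))
    labeled = rng.random(n_cores) < p_label
    while not labeled.any():
        labeled = rng.random(n_cores) < p_label
    return PlantedTruth(
        coreness=np.asarray(coreness, dtype=np.float64),
        true_cores=set(int(i) for i in core_idx),
        labeled_positives=set(int(i) for i in core_idx[labeled]),
    )


def simulate_validation_geneset(cfg: SimulationConfig, truth: PlantedTruth) -> set[int]:
    """Gene set enriched among planted cores at the configured odds ratio.

    Non-cores join with probability ``validation_base_rate`` q; cores with
    probability p solving p/(1-p) = OR * q/(1-q), so the expected membership
    odds ratio of cores vs non-cores equals ``cfg.validation_or``.
    """
    if not truth.true_cores:
        raise ValueError("empty core set")
    rng = np.random.default_rng((cfg.seed * 1000003 + 47) % (2**31))
    n = len(truth.coreness)
    q = cfg.validation_base_rate
    odds = cfg.validation_or * q / (1.0 - q)
    p_core = odds / (1.0 + odds)
    probs = np.full(n, q)
    probs[list(truth.true_cores)] = p_core
    members = set(int(i) for i in np.nonzero(rng.random(n) < probs)[0])
    truth.validation_members = members
    return members


def simulate_dataset(
    cfg: SimulationConfig,
) -> tuple[GeneGraph, FeatureMatrix, LabelSet, PlantedTruth]:
    """Full deterministic draw: graph, features, PU labels, validation set."""
    universe = _universe(cfg.n_genes)
    coreness = draw_coreness(cfg)
    graph = simulate_networks(cfg, universe)
    features = simulate_features(cfg, coreness, universe)
    truth = assign_pu_labels(cfg, coreness)
    simulate_validation_geneset(cfg, truth)
    labels = LabelSet(positives=set(truth.labeled_positives), name="simulated")
    return graph, features, labels, truth


def write_simulation(
    cfg: SimulationConfig, directory: str | Path
) -> dict[str, Path]:
    """Write edge-list TSVs, feature TSV, label file and truth TSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    graph, features, labels, truth = simulate_dataset(cfg)
    paths: dict[str, Path] = {}
    for p in graph.to_edge_list_files(directory):
        paths[p.stem] = p

    feat_path = directory / "features.tsv"
    with open(feat_path, "w") as fh:
        fh.write("gene\t" + "\t".join(features.feature_names) + "\n")
        for i, g in enumerate(features.universe.genes):
            row = "\t".join(f"{v:.10g}" for v in features.values[i])
            fh.write(f"{g}\t{row}\n")
    paths["features"] = feat_path

    label_path = directory / "labels.txt"
    with open(label_path, "w") as fh:
        for i in sorted(labels.positives):
            fh.write(features.universe.genes[i] + "\n")
    paths["labels"] = label_path

    truth_path = directory / "truth.tsv"
    with open(truth_path, "w") as fh:
        fh.write("gene\tcoreness\tis_core\tis_labeled\tin_validation_set\n")
        for i, g in enumerate(features.universe.genes):
            fh.write(
                f"{g}\t{truth.coreness[i]:.10g}\t{int(i in truth.true_cores)}\t"
                f"{int(i in truth.labeled_positives)}\t"
                f"{int(i in truth.validation_members)}\n"
            )
    paths["truth"] = truth_path

    cfg_path = directory / "simulation_config.txt"
    with open(cfg_path, "w") as fh:
        fh.write(repr(cfg) + "\n")
    paths["config"] = cfg_path
    return paths
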