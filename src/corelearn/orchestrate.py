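"""Config-driven end-to-end runs, reproducibility and output writing.

An experiment is described by a YAML file with five sections — ``input``
(paths to edge lists / feature table / label file, or a ``simulate`` block),
``classifier``, ``loss``, ``ensemble`` and ``embedding`` — plus a global
``seed`` and an ``output_dir``.  Unknown keys are rejected.  A run executes
data assembly, optional network embedding, the m x n nested ensemble and
consensus scoring, then writes the consensus TSV, per-fold threshold
diagnostics, the trained-model store, a resolved-config snapshot, a log file
and a checksummed manifest.  The resolved config plus the seed reproduce
every artifact bit for bit on a single thread.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import (GeneGraph, assemble_graph, read_edge_list, read_label_file,
                   resolve_gene_universe, scale_features_robust)
from .ensemble import EnsembleRun, run_nested_ensemble
from .nn import (ArchitectureSpec, CLASSIFIER_REGISTRY,
                 embed_networks_randomwalk, make_classifier)
from .simulate import NetworkSpec, SimulationConfig, simulate_dataset
from .train import LossConfig

logger = logging.getLogger("corelearn")

_ALLOWED = {
    "top": {"name", "seed", "output_dir", "overwrite", "input", "classifier",
            "loss", "ensemble", "embedding"},
    "input": {"simulate", "networks", "features", "labels", "scale_features"},
    "simulate": {"n_genes", "networks", "n_informative_features",
                 "n_noise_features", "effect_size", "core_fraction",
                 "label_frequency_slope", "validation_or",
                 "validation_base_rate"},
    "classifier": {"name", "hidden_dim", "pre_layers", "post_layers",
                   "mp_layers", "tag_hops", "network"},
    "loss": {"dilution", "amplification"},
    "ensemble": {"m", "n", "B", "fdr_level", "max_epochs"},
    "embedding": {"d_emb", "walk_length", "context", "epochs",
                  "walks_per_node"},
}


class ConfigError(ValueError):
    pass


def _check_keys(section: dict, name: str) -> None:
    unknown = set(section) - _ALLOWED[name]
    if unknown:
        raise ConfigError(f"unknown keys in {name!r} section: {sorted(unknown)}")


@dataclass
class ExperimentConfig:
    name: str = "experiment"
    seed: int = 0
    output_dir: str = "corelearn_out"
    overwrite: bool = False
    input: dict = field(default_factory=dict)
    classifier: dict = field(default_factory=lambda: {"name": "mlp"})
    loss: dict = field(default_factory=dict)
    ensemble: dict = field(default_factory=dict)
    embedding: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "ExperimentConfig":
        _check_keys(raw, "top")
        cfg = cls(**raw)
        _check_keys(cfg.input, "input")
        if "simulate" in cfg.input:
            _check_keys(cfg.input["simulate"], "simulate")
        _check_keys(cfg.classifier, "classifier")
        _check_keys(cfg.loss, "loss")
        _check_keys(cfg.ensemble, "ensemble")
        _check_keys(cfg.embedding, "embedding")
        if cfg.classifier.get("name", "mlp") not in CLASSIFIER_REGISTRY:
            raise ConfigError(f"unknown classifier {cfg.classifier.get('name')!r}")
        return cfg

    def arch_spec(self) -> ArchitectureSpec:
        c = {k: v for k, v in self.classifier.items() if k != "name"}
        return ArchitectureSpec(**c)

    def loss_cfg(self) -> LossConfig:
        return LossConfig(**self.loss)


@dataclass
class RunArtifacts:
    output_dir: Path
    consensus_path: Path
    diagnostics_path: Path
    model_store_path: Path
    config_path: Path
    log_path: Path
    manifest_path: Path
    run: EnsembleRun


def load_inputs(cfg: ExperimentConfig):
    """Load (or simulate) graph, scaled features and labels per the config."""
    inp = cfg.input
    if "simulate" in inp:
        sim_kwargs = dict(inp["simulate"])
        nets = sim_kwargs.pop("networks", None)
        if nets is not None:
            sim_kwargs["networks"] = tuple(NetworkSpec(**ns) for ns in nets)
        sim = SimulationConfig(seed=cfg.seed, **sim_kwargs)
        graph, features, labels, truth = simulate_dataset(sim)
    else:
        records = []
        for net in inp.get("networks", []):
            records += read_edge_list(net["path"], net["name"],
                                      bool(net.get("directed", False)),
                                      header=bool(net.get("header", False)))
        table = pd.read_csv(inp["features"], sep=None, engine="python")
        label_genes = read_label_file(inp["labels"])
        universe, features, labels = resolve_gene_universe(table, label_genes)
        graph = assemble_graph(records, universe)
        truth = None
    if inp.get("scale_features", True):
        features = scale_features_robust(features)
    return graph, features, labels, truth


def run_experiment(config: str | Path | ExperimentConfig) -> RunArtifacts:
    """Execute the full pipeline described by a config and write artifacts."""
    cfg = (config if isinstance(config, ExperimentConfig)
           else ExperimentConfig.from_yaml(config))
    out = Path(cfg.output_dir)
    if out.exists() and any(out.iterdir()) and not cfg.overwrite:
        raise FileExistsError(
            f"output directory {out} is non-empty; set overwrite: true")
    out.mkdir(parents=True, exist_ok=True)

    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter(
        "%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        graph, features, labels, _ = load_inputs(cfg)
        name = cfg.classifier.get("name", "mlp")
        spec = cfg.arch_spec()
        emb = None
        if name == "n2v+mlp":
            emb_kwargs = dict(cfg.embedding)
            emb = embed_networks_randomwalk(graph, seed=cfg.seed, **emb_kwargs)
        ens = cfg.ensemble
        run = run_nested_ensemble(
            name, graph, features.values, labels.positives,
            m=ens.get("m", 11), n=ens.get("n", 10), B=ens.get("B", 1000),
            fdr_level=ens.get("fdr_level", 0.05), spec=spec,
            loss_cfg=cfg.loss_cfg(), seed=cfg.seed,
            max_epochs=ens.get("max_epochs", 1000), embedding=emb,
            keep_models=True,
        )
        paths = write_outputs(run, graph, out, cfg)
    finally:
        logger.removeHandler(handler)
        handler.close()
    return RunArtifacts(
        output_dir=out, consensus_path=paths["consensus"],
        diagnostics_path=paths["diagnostics"],
        model_store_path=paths["models"], config_path=paths["config"],
        log_path=log_path, manifest_path=paths["manifest"], run=run,
    )


def write_outputs(run: EnsembleRun, graph: GeneGraph, out: Path,
                  cfg: ExperimentConfig) -> dict[str, Path]:
    """Write consensus, diagnostics, model store, config snapshot, manifest."""
    genes = graph.universe.genes
    cons = run.consensus
    consensus_path = out / "consensus.tsv"
    with open(consensus_path, "w") as fh:
        fh.write("gene\tCS\tflag\n")
        for i, g in enumerate(genes):
            cs = "" if np.isnan(cons.cs[i]) else str(int(cons.cs[i]))
            fh.write(f"{g}\t{cs}\t{cons.flags[i]}\n")

    diagnostics_path = out / "fold_diagnostics.tsv"
    with open(diagnostics_path, "w") as fh:
        fh.write("fold\tbin\tobserved\tbackground_mean\tbackground_sd\t"
                 "p_value\tfdr\tchosen\tbranch\n")
        for j, diag in enumerate(run.fold_diagnostics):
            for c in range(len(diag.observed)):
                is_chosen = diag.chosen is not None and c + 1 == diag.chosen
                fh.write(
                    f"{j}\t{c + 1}\t{diag.observed[c]:g}\t"
                    f"{diag.background_mean[c]:.6g}\t{diag.background_sd[c]:.6g}\t"
                    f"{diag.p_values[c]:.6g}\t{diag.fdr[c]:.6g}\t"
                    f"{int(is_chosen)}\t{diag.branch or ''}\n")

    models_path = out / "models.npz"
    arrays = {}
    if run.model_weights is not None:
        for j, fold in enumerate(run.model_weights):
            for i, weights in enumerate(fold):
                for k, w in enumerate(weights):
                    arrays[f"f{j}_m{i}_p{k}"] = w
    np.savez(models_path, **arrays)

    config_path = out / "resolved_config.yaml"
    with open(config_path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=True)

    paths = {"consensus": consensus_path, "diagnostics": diagnostics_path,
             "models": models_path, "config": config_path}
    manifest_path = out / "manifest.json"
    manifest = {}
    for p in sorted(paths.values()):
        manifest[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    paths["manifest"] = manifest_path
    return paths


def load_model_store(artifacts_dir: str | Path, cfg: ExperimentConfig,
                     graph: GeneGraph, in_dim: int,
                     embedding: np.ndarray | None = None) -> list:
    """Rebuild every trained ensemble model from the npz weight store."""
    store = np.load(Path(artifacts_dir) / "models.npz")
    name = cfg.classifier.get("name", "mlp")
    spec = cfg.arch_spec()
    models = []
    key_re = re.compile(r"^f(\d+)_m(\d+)_p(\d+)$")
    fold_model_ids = sorted({
        (int(mo.group(1)), int(mo.group(2)))
        for k in store.files if (mo := key_re.match(k))
    })
    for j, i in fold_model_ids:
        model = make_classifier(name, in_dim, graph, spec=spec,
                                seed=0, embedding=embedding)
        n_params = len(model.params)
        weights = [store[f"f{j}_m{i}_p{k}"] for k in range(n_params)]
        model.set_weights(weights)
        models.append(model)
    return models
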