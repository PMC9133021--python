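"""Reproducible experiment driver: config schema, presets, run outputs.

An :class:`ExperimentConfig` fully determines a run: dataset synthesis,
noise injection, node partitioning, topology, training plan, distillation
settings, and model choice.  Identical config + seed reproduces metrics
bit-for-bit.  Each run writes a directory containing ``metrics.csv``,
``ledger.jsonl``, ``manifest.json`` (config hash, seeds, selection record,
privacy audit), and the final weights (``final_weights.npy`` plus a JSON
header).

Preset names follow the experiment ids of the evaluation protocol:
``baseline-centralized``, ``dc-m2-5node`` (closing pass over 5 nodes),
``cluster-3x5`` (15 nodes in 3 clusters), ``dc-1e-5t``/``dc-2e-5t``
(5 traversals at 1 or 2 epochs per node), and ``dc-3e`` … ``dc-20e``
(single traversal at k epochs per node).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from daita.distillation import DistillationConfig
from daita.evaluation import compute_metrics
from daita.models import make_model
from daita.orchestrator import (
    DataAccessLog,
    TrainPlan,
    closing_pass,
    cluster_train,
    daita_train,
    derive_seed,
    privacy_guard,
    train_locally,
    train_specialists,
)
from daita.synthetic_data import (
    clinic_profile_sizes,
    inject_asymmetric_noise,
    make_synthetic_dataset,
    partition_nodes,
    split_train_validation,
)
from daita.topology import TransferLedger, build_clustered, build_ring

__all__ = ["ExperimentConfig", "PRESETS", "run_experiment", "compare_runs"]


@dataclass
class DatasetSpec:
    kind: str = "gaussian_blobs"
    n_per_class: int = 2250
    n_test_per_class: int = 1000
    class_separation: float = 3.0
    fraction_validation: float = 0.2
    noise_rates: dict = field(default_factory=lambda: {0: 0.5, 1: 0.1})
    noisy: bool = True


@dataclass
class TopologySpec:
    n_nodes: int = 5
    clusters: Optional[list[int]] = None  # e.g. [5, 5, 5]; None = flat ring
    partition: str = "even"  # or "clinic_profile"


@dataclass
class ModelSpec:
    architecture: str = "softmax_regression"
    hidden: int = 16


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one run."""

    name: str = "custom"
    scenario: str = "decentralized"  # decentralized | centralized | ensemble
    dataset: DatasetSpec = field(default_factory=DatasetSpec)
    topology: TopologySpec = field(default_factory=TopologySpec)
    plan: TrainPlan = field(default_factory=TrainPlan)
    distillation: DistillationConfig = field(default_factory=DistillationConfig)
    model: ModelSpec = field(default_factory=ModelSpec)
    seed: int = 0

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "scenario": self.scenario,
            "dataset": dataclasses.asdict(self.dataset),
            "topology": dataclasses.asdict(self.topology),
            "plan": dataclasses.asdict(self.plan),
            "distillation": self.distillation.to_dict(),
            "model": dataclasses.asdict(self.model),
            "seed": self.seed,
        }
        d["dataset"]["noise_rates"] = {
            int(k): float(v) for k, v in d["dataset"]["noise_rates"].items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(d) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        ds = d.get("dataset", {})
        if "noise_rates" in ds:
            ds = {**ds, "noise_rates": {int(k): float(v) for k, v in ds["noise_rates"].items()}}
        return cls(
            name=d.get("name", "custom"),
            scenario=d.get("scenario", "decentralized"),
            dataset=DatasetSpec(**ds),
            topology=TopologySpec(**d.get("topology", {})),
            plan=TrainPlan(**d.get("plan", {})),
            distillation=DistillationConfig.from_dict(d.get("distillation", {})),
            model=ModelSpec(**d.get("model", {})),
            seed=d.get("seed", 0),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _preset(name: str, **overrides) -> ExperimentConfig:
    cfg = ExperimentConfig(name=name)
    for key, value in overrides.items():
        parts = key.split(".")
        obj = cfg
        for p in parts[:-1]:
            obj = getattr(obj, p)
        setattr(obj, parts[-1], value)
    return cfg


def PRESETS() -> dict[str, ExperimentConfig]:
    """Named experiment configurations mirroring the evaluation protocol."""
    presets = {
        "baseline-centralized": _preset(
            "baseline-centralized", scenario="centralized", **{"topology.n_nodes": 1}
        ),
        "dc-m2-5node": _preset(
            "dc-m2-5node", **{"plan.closing_pass": True, "plan.rounds": 2}
        ),
        "dc-m1": _preset("dc-m1", **{"plan.mode": "single_transfer_set"}),
        "ensemble-m2": _preset("ensemble-m2", scenario="ensemble"),
        "cluster-3x5": _preset(
            "cluster-3x5",
            **{"topology.n_nodes": 15, "topology.clusters": [5, 5, 5], "plan.rounds": 1},
        ),
        "dc-1e-5t": _preset(
            "dc-1e-5t", **{"plan.epochs_per_node": 1, "plan.rounds": 5}
        ),
        "dc-2e-5t": _preset(
            "dc-2e-5t", **{"plan.epochs_per_node": 2, "plan.rounds": 5}
        ),
        "clinic-5node": _preset(
            "clinic-5node",
            **{
                "topology.partition": "clinic_profile",
                "dataset.n_per_class": 1097,
                "plan.selection_metric": "log_loss",
            },
        ),
    }
    for k in (3, 5, 8, 10, 15, 20):
        presets[f"dc-{k}e"] = _preset(
            f"dc-{k}e",
            **{
                "topology.n_nodes": 15,
                "plan.epochs_per_node": k,
                "plan.rounds": 1,
                "dataset.n_per_class": 2250,
            },
        )
    return presets


def _build_data(cfg: ExperimentConfig):
    ds = cfg.dataset
    full = make_synthetic_dataset(
        ds.n_per_class, ds.kind, ds.class_separation, derive_seed(cfg.seed, "train_pool")
    )
    train, validation = split_train_validation(
        full, ds.fraction_validation, derive_seed(cfg.seed, "split")
    )
    test = make_synthetic_dataset(
        ds.n_test_per_class, ds.kind, ds.class_separation, derive_seed(cfg.seed, "test")
    )
    if ds.noisy:
        validation = inject_asymmetric_noise(
            validation, ds.noise_rates, derive_seed(cfg.seed, "val_noise")
        )
    return train, validation, test


def _partition_and_poison(cfg: ExperimentConfig, train):
    """Partition the clean training set, then inject noise node-by-node."""
    topo_spec = cfg.topology
    if topo_spec.partition == "clinic_profile":
        sizes = clinic_profile_sizes(len(train))
        nodes = partition_nodes(train, sizes, seed=derive_seed(cfg.seed, "partition"))
    else:
        nodes = partition_nodes(
            train, "even", topo_spec.n_nodes, derive_seed(cfg.seed, "partition")
        )
    if cfg.dataset.noisy:
        for node in nodes:
            node.data = inject_asymmetric_noise(
                node.data, cfg.dataset.noise_rates, derive_seed(cfg.seed, "noise", node.node_id)
            )
    return nodes


def run_experiment(config: ExperimentConfig, out_dir) -> Path:
    """Execute one configured run and write its output directory.

    Pipeline: data synthesis → partition + noise → specialists → student
    traversal (or centralized / ensemble alternative) → optional closing
    pass → evaluation on the clean test set → privacy audit.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    train, validation, test = _build_data(config)
    n_features = train.samples.shape[1]

    def factory(seed: int):
        return make_model(
            config.model.architecture,
            n_features,
            2,
            seed=seed,
            **({"hidden": config.model.hidden} if config.model.architecture == "tiny_mlp" else {}),
        )

    plan = config.plan
    ledger = TransferLedger()
    access_log = DataAccessLog(ledger)
    mode = "decentralized"
    rows = []

    if config.scenario == "centralized":
        mode = "centralized"
        noisy_train = (
            inject_asymmetric_noise(
                train, config.dataset.noise_rates, derive_seed(config.seed, "noise", "central")
            )
            if config.dataset.noisy
            else train
        )
        baseline_plan = TrainPlan(
            seed=config.seed,
            batch_size=plan.batch_size,
            learning_rate=plan.learning_rate,
            class_weighting="uniform",
        )
        epochs = plan.rounds * plan.epochs_per_node * max(1, config.topology.n_nodes)
        access_log.record("baseline", "central", "central", "train")
        final = train_locally(
            noisy_train, factory, epochs, config.seed, plan=baseline_plan
        )
        selection = {"scenario": "centralized", "epochs": epochs}
    else:
        nodes = _partition_and_poison(config, train)
        if config.topology.clusters:
            ids = [n.node_id for n in nodes]
            bounds = np.cumsum([0] + list(config.topology.clusters))
            topo = build_clustered(
                [ids[bounds[i] : bounds[i + 1]] for i in range(len(config.topology.clusters))]
            )
            result = cluster_train(
                topo, nodes, plan, config.distillation, validation, factory, ledger, access_log
            )
        else:
            topo = build_ring([n.node_id for n in nodes])
            spec_epochs = plan.specialist_epochs or max(
                1, plan.rounds * plan.epochs_per_node
            )
            teachers = train_specialists(
                nodes, factory, spec_epochs, config.seed, plan, access_log
            )
            if config.scenario == "ensemble":
                from daita.distillation import ensemble_predict

                result = daita_train(
                    topo, nodes, teachers, plan, config.distillation, validation,
                    factory, ledger, access_log,
                )
                probs = ensemble_predict(list(teachers.values()), test.samples)
                report = compute_metrics(probs, test.true_labels)
                rows.append({"model": "ensemble", "split": "test", **report.as_dict()})
            else:
                result = daita_train(
                    topo, nodes, teachers, plan, config.distillation, validation,
                    factory, ledger, access_log,
                )
            if plan.mode == "single_transfer_set":
                # the designated transfer node hosts one last distillation step
                node = nodes[0]
                ledger.record("student", "__eval_host__", node.node_id, plan.rounds, 0)
                cfg = config.distillation
                from daita.orchestrator import _node_config, _plain_if_no_teachers, _teacher_soft_on

                cfg = _node_config(cfg, node, plan)
                combined = _teacher_soft_on(teachers, node, cfg, access_log)
                access_log.record("student", node.node_id, node.node_id, "train")
                result.final_model.train_epochs(
                    node.data.samples,
                    node.data.labels,
                    plan.epochs_per_node,
                    _plain_if_no_teachers(cfg, combined),
                    teacher_soft=combined,
                    rng=np.random.default_rng(derive_seed(plan.seed, "final_transfer")),
                    batch_size=plan.batch_size,
                    learning_rate=plan.learning_rate,
                )
            if plan.closing_pass:
                per_node = [result.final_model.clone() for _ in nodes]
                for m, node in zip(per_node, nodes):
                    # each node refines its own copy locally before the pass
                    access_log.record(
                        f"final@{node.node_id}", node.node_id, node.node_id, "train"
                    )
                    rng = np.random.default_rng(
                        derive_seed(plan.seed, "refine", node.node_id)
                    )
                    m.train_epochs(
                        node.data.samples,
                        node.data.labels,
                        plan.closing_epochs,
                        DistillationConfig(alpha=1.0),
                        rng=rng,
                        batch_size=plan.batch_size,
                        learning_rate=plan.learning_rate,
                    )
                result = closing_pass(
                    per_node, topo, nodes, plan.closing_epochs, config.distillation,
                    validation, plan, ledger, access_log,
                )
        final = result.final_model
        selection = result.selection

    report = compute_metrics(final.predict_proba(test.samples), test.true_labels)
    rows.append({"model": config.name, "split": "test", **report.as_dict()})
    val_report = compute_metrics(final.predict_proba(validation.samples), validation.labels)
    rows.append({"model": config.name, "split": "validation", **val_report.as_dict()})
    pd.DataFrame(rows).to_csv(out / "metrics.csv", index=False)

    ledger.to_jsonl(out / "ledger.jsonl")
    violations = privacy_guard(ledger, access_log, mode)
    weights = final.export_weights()
    np.save(out / "final_weights.npy", weights)
    with open(out / "final_weights.json", "w") as fh:
        json.dump(
            {"architecture": final.architecture, "n_weights": int(weights.size)}, fh
        )
    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "test_hash": hashlib.sha256(test.samples.tobytes()).hexdigest()[:16],
        "selection": selection,
        "transfer_count": ledger.count("train"),
        "eval_move_count": ledger.count("eval"),
        "privacy": {
            "passed": not any(not v.get("informational") for v in violations),
            "violations": violations,
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    config.to_yaml(out / "config.yaml")
    return out


def compare_runs(run_dirs: list) -> pd.DataFrame:
    """Side-by-side test-set metric deltas relative to the first run.

    Refuses to compare runs whose test sets differ (hash check).
    """
    if len(run_dirs) < 2:
        raise ValueError("need at least two run directories")
    frames, hashes, names = [], [], []
    for d in run_dirs:
        d = Path(d)
        with open(d / "manifest.json") as fh:
            manifest = json.load(fh)
        hashes.append(manifest["test_hash"])
        names.append(manifest["config"]["name"])
        df = pd.read_csv(d / "metrics.csv")
        frames.append(df[df["split"] == "test"].iloc[-1])
    if len(set(hashes)) != 1:
        raise ValueError(f"test sets differ between runs: {hashes}")
    metric_cols = [
        c for c in frames[0].index if c not in ("model", "split", "n_samples")
    ]
    rows = []
    for name, row in zip(names, frames):
        entry = {"run": name}
        for c in metric_cols:
            entry[c] = row[c]
            entry[f"delta_{c}"] = row[c] - frames[0][c]
        rows.append(entry)
    return pd.DataFrame(rows)
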