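"""Decentralized training: specialists, student traversal, closing pass, clusters.

The training schedule: each data-silo node first trains a *specialist*
(teacher) on its own data, never moving any sample.  A *student* model then
traverses the ring for ``R`` rounds accompanied by the teacher models; at
each node it trains ``k`` epochs on the node's local data (the transfer set)
under the distillation loss, guided by the frozen teachers' temperature
softened outputs.  Every model-weight movement is appended to the transfer
ledger; at the end of each round the traveling models pass through the
evaluation host, where the student is scored on the shared validation set
and checkpointed.  An optional *closing pass* then transfers all per-node
final models around the ring for exactly one round, distilling them together
on each node's data in turn.  For clustered topologies, training happens
within each cluster first; cluster generalists are weight-averaged into one
representative per cluster and the representatives traverse the ring of
clusters.

Privacy invariant, enforced by :func:`privacy_guard`: only model weights ever
cross node boundaries, and every data access is executed on the node where
both the data and the model currently reside.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from daita.distillation import (
    DistillationConfig,
    combine_teachers,
    inverse_frequency_class_weights,
    soften,
)
from daita.evaluation import MetricsReport, compute_metrics, select_best
from daita.models import ModelContract
from daita.synthetic_data import LabeledDataset, NodeDataset
from daita.topology import EVAL_HOST, Topology, TransferLedger

__all__ = [
    "TrainPlan",
    "TrainedModelSet",
    "DataAccessLog",
    "derive_seed",
    "train_specialists",
    "train_locally",
    "daita_train",
    "closing_pass",
    "cluster_train",
    "average_weights",
    "privacy_guard",
]


def derive_seed(seed: int, *names) -> int:
    """Fan a global seed out to an independent stream, by stable hashing.

    Adding a node does not perturb any other node's stream; results stay
    below 2**31 so they are safe for any RNG API.
    """
    digest = hashlib.sha256(("/".join([str(seed), *map(str, names)])).encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class TrainPlan:
    """Schedule of a decentralized run.

    ``epochs_per_node`` is the node-level epoch count ``k`` before the student
    moves on; ``rounds`` the number of full traversals ``R``.  The closing
    pass, when enabled, runs ``closing_epochs`` epochs per node for exactly
    one extra traversal of all per-node models together.
    """

    epochs_per_node: int = 2
    rounds: int = 2
    closing_pass: bool = False
    closing_epochs: int = 2
    mode: str = "per_node_transfer_sets"  # or "single_transfer_set"
    selection_metric: str = "balanced_accuracy"  # or "log_loss"
    class_weighting: str = "inverse_frequency"  # or "uniform"
    seed: int = 0
    batch_size: int = 32
    learning_rate: float = 0.1
    specialist_epochs: Optional[int] = None  # default: round-count budget

    def __post_init__(self) -> None:
        if self.epochs_per_node < 1 or self.rounds < 1:
            raise ValueError("epochs_per_node and rounds must be >= 1")
        if self.mode not in ("per_node_transfer_sets", "single_transfer_set"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.selection_metric not in ("balanced_accuracy", "log_loss"):
            raise ValueError(f"unknown selection metric {self.selection_metric!r}")
        if self.class_weighting not in ("inverse_frequency", "uniform"):
            raise ValueError(f"unknown class weighting {self.class_weighting!r}")


class DataAccessLog:
    """Append-only record of every dataset read: who, whose data, where.

    Each entry also captures the ledger length at access time, so the
    privacy guard can replay model residences.
    """

    def __init__(self, ledger: Optional[TransferLedger] = None) -> None:
        self.entries: list[dict] = []
        self._ledger = ledger

    def record(
        self,
        model_id: str,
        data_node: str,
        exec_node: str,
        purpose: str = "train",
        detail: str = "",
    ) -> None:
        self.entries.append(
            {
                "model_id": model_id,
                "data_node": data_node,
                "exec_node": exec_node,
                "purpose": purpose,
                "detail": detail,
                "ledger_position": 0 if self._ledger is None else len(self._ledger.entries),
            }
        )


@dataclass
class TrainedModelSet:
    """Everything a decentralized run produces."""

    specialists: dict[str, ModelContract] = field(default_factory=dict)
    students: list[ModelContract] = field(default_factory=list)
    final_model: Optional[ModelContract] = None
    checkpoints: list[tuple[np.ndarray, MetricsReport]] = field(default_factory=list)
    selection: Optional[dict] = None
    ledger: TransferLedger = field(default_factory=TransferLedger)
    access_log: Optional[DataAccessLog] = None


def _node_config(
    base: DistillationConfig, node: NodeDataset, plan: TrainPlan
) -> DistillationConfig:
    """Per-node view of the distillation config (class weights resolved)."""
    cw = base.class_weights
    if cw is None and plan.class_weighting == "inverse_frequency":
        labels = node.data.labels
        if len(np.unique(labels)) < 2:
            warnings.warn(
                f"{node.node_id} is missing a class; renormalizing class weights",
                stacklevel=3,
            )
        cw = inverse_frequency_class_weights(labels)
    return DistillationConfig(
        temperature=base.temperature,
        alpha=base.alpha,
        teacher_weights=base.teacher_weights,
        class_weights=cw,
        node_weight=base.node_weight,
        sample_weights=base.sample_weights,
        per_teacher_kl=base.per_teacher_kl,
    )


def train_locally(
    data: LabeledDataset,
    model_factory: Callable[[int], ModelContract],
    epochs: int,
    seed: int,
    config: Optional[DistillationConfig] = None,
    plan: Optional[TrainPlan] = None,
    stream: str = "student",
) -> ModelContract:
    """Plain supervised training on one dataset (the reduction baseline).

    Uses the same seed fan-out, initialization, and batch schedule as the
    traversing student, so a single-node, single-stream decentralized run
    with ``alpha=1`` is weight-identical to this direct path.
    """
    plan = plan or TrainPlan()
    config = config or DistillationConfig(alpha=1.0, class_weights=np.ones(2))
    model = model_factory(derive_seed(seed, stream, "init"))
    rng = np.random.default_rng(derive_seed(seed, stream, "batches"))
    model.train_epochs(
        data.samples,
        data.labels,
        epochs,
        config,
        rng=rng,
        batch_size=plan.batch_size,
        learning_rate=plan.learning_rate,
    )
    return model


def train_specialists(
    nodes: Sequence[NodeDataset],
    model_factory: Callable[[int], ModelContract],
    local_epochs: int,
    seed: int,
    plan: Optional[TrainPlan] = None,
    access_log: Optional[DataAccessLog] = None,
) -> dict[str, ModelContract]:
    """One teacher per node, trained exclusively on that node's local data.

    No ledger entries are generated: nothing moves.  A node missing a class
    triggers a warning and per-node class-weight renormalization.
    """
    if not nodes:
        raise ValueError("need at least one node")
    plan = plan or TrainPlan()
    teachers: dict[str, ModelContract] = {}
    for node in nodes:
        if len(node.data) == 0:
            raise ValueError(f"{node.node_id} has no samples")
        cfg = _node_config(
            DistillationConfig(alpha=1.0), node, plan
        )  # plain CE; class weights per plan
        model = model_factory(derive_seed(seed, node.node_id, "init"))
        rng = np.random.default_rng(derive_seed(seed, node.node_id, "batches"))
        if access_log is not None:
            access_log.record(
                f"specialist@{node.node_id}", node.node_id, node.node_id, "train"
            )
        model.train_epochs(
            node.data.samples,
            node.data.labels,
            local_epochs,
            cfg,
            rng=rng,
            batch_size=plan.batch_size,
            learning_rate=plan.learning_rate,
        )
        teachers[node.node_id] = model
    return teachers


def _teacher_soft_on(
    teachers: dict[str, ModelContract],
    node: NodeDataset,
    config: DistillationConfig,
    access_log: Optional[DataAccessLog],
) -> Optional[np.ndarray]:
    if not teachers or config.alpha >= 1.0:
        return None
    softs = []
    for tid, teacher in teachers.items():
        if access_log is not None:
            access_log.record(
                f"teacher@{tid}", node.node_id, node.node_id, "teacher_inference"
            )
        softs.append(soften(teacher.predict_logits(node.data.samples), config.temperature))
    return combine_teachers(softs, config.teacher_weights)


def _plain_if_no_teachers(
    config: DistillationConfig, combined: Optional[np.ndarray]
) -> DistillationConfig:
    """Fall back to pure hard-label loss when no teacher signal exists."""
    if combined is not None or config.alpha >= 1.0:
        return config
    return DistillationConfig(
        temperature=config.temperature,
        alpha=1.0,
        class_weights=config.class_weights,
        node_weight=config.node_weight,
        sample_weights=config.sample_weights,
    )


def _evaluate(
    model: ModelContract,
    validation: LabeledDataset,
    model_id: str,
    access_log: Optional[DataAccessLog],
) -> MetricsReport:
    if access_log is not None:
        access_log.record(model_id, EVAL_HOST, EVAL_HOST, "validate")
    return compute_metrics(model.predict_proba(validation.samples), validation.labels)


def daita_train(
    topology: Topology,
    nodes: Sequence[NodeDataset],
    teachers: dict[str, ModelContract],
    plan: TrainPlan,
    distill_config: DistillationConfig,
    validation: LabeledDataset,
    model_factory: Callable[[int], ModelContract],
    ledger: Optional[TransferLedger] = None,
    access_log: Optional[DataAccessLog] = None,
    student: Optional[ModelContract] = None,
    model_id: str = "student",
) -> TrainedModelSet:
    """Student traversal of a (single-cluster) topology with co-traveling teachers.

    For each of ``plan.rounds`` rounds the student and every teacher are
    delivered to each node in traversal order (one ledger entry per model per
    visit, ``n * R * (n_teachers + 1)`` in total); the student trains
    ``plan.epochs_per_node`` epochs on the local transfer set under the
    distillation loss.  After each round the traveling models pass through
    the evaluation host, where the student is scored on the shared
    validation set and checkpointed; the best checkpoint by
    ``plan.selection_metric`` becomes the final model.
    """
    if topology.n_clusters != 1:
        raise ValueError("daita_train expects a single-cluster topology; see cluster_train")
    node_map = {n.node_id: n for n in nodes}
    order = topology.traversal_order[0]
    if set(order) - set(node_map):
        raise ValueError("every topology node needs a NodeDataset")
    ledger = ledger if ledger is not None else TransferLedger()
    access_log = access_log if access_log is not None else DataAccessLog(ledger)

    if student is None:
        student = model_factory(derive_seed(plan.seed, model_id, "init"))
    rng = np.random.default_rng(derive_seed(plan.seed, model_id, "batches"))

    traveling = [(model_id, student)] + [(f"teacher@{tid}", t) for tid, t in teachers.items()]
    location = {mid: EVAL_HOST for mid, _ in traveling}

    result = TrainedModelSet(ledger=ledger, access_log=access_log)
    result.specialists = dict(teachers)

    for r in range(plan.rounds):
        for step, node_id in enumerate(order):
            node = node_map[node_id]
            for mid, _ in traveling:
                ledger.record(mid, location[mid], node_id, r, step, kind="train")
                location[mid] = node_id
            cfg = _node_config(distill_config, node, plan)
            combined = _teacher_soft_on(teachers, node, cfg, access_log)
            cfg = _plain_if_no_teachers(cfg, combined)
            access_log.record(model_id, node_id, node_id, "train")
            student.train_epochs(
                node.data.samples,
                node.data.labels,
                plan.epochs_per_node,
                cfg,
                teacher_soft=combined,
                rng=rng,
                batch_size=plan.batch_size,
                learning_rate=plan.learning_rate,
            )
        # round boundary: convoy passes through the evaluation host
        for mid, _ in traveling:
            ledger.record(mid, location[mid], EVAL_HOST, r, len(order), kind="eval")
            location[mid] = EVAL_HOST
        report = _evaluate(student, validation, model_id, access_log)
        result.checkpoints.append((student.export_weights().copy(), report))

    best = select_best([m for _, m in result.checkpoints], plan.selection_metric)
    final = model_factory(derive_seed(plan.seed, model_id, "init"))
    final.import_weights(result.checkpoints[best][0])
    result.final_model = final
    result.students = [student]
    result.selection = {
        "checkpoint": best,
        "metric": plan.selection_metric,
        "value": getattr(result.checkpoints[best][1], plan.selection_metric),
    }
    return result


def closing_pass(
    students: Sequence[ModelContract],
    topology: Topology,
    nodes: Sequence[NodeDataset],
    k: int,
    distill_config: DistillationConfig,
    validation: LabeledDataset,
    plan: Optional[TrainPlan] = None,
    ledger: Optional[TransferLedger] = None,
    access_log: Optional[DataAccessLog] = None,
    rounds: int = 1,
) -> TrainedModelSet:
    """One convoy traversal where all final models distill together at each node.

    The ``n`` per-node models travel as one convoy; at every node each model
    trains ``k`` epochs on the local data with the *other* models' softened
    outputs (snapshotted before any update at that node) as its teachers.
    A model already resident at a node is not counted as transferred to it.
    Exactly one traversal is performed; asking for more is a config error
    (``rounds`` is exposed only to make the restriction explicit).
    """
    if rounds != 1:
        raise ValueError("the closing pass makes exactly one traversal")
    if topology.n_clusters != 1:
        raise ValueError("closing_pass expects a single-cluster topology")
    order = topology.traversal_order[0]
    if len(students) != len(order):
        raise ValueError("need exactly one student per node")
    plan = plan or TrainPlan()
    node_map = {n.node_id: n for n in nodes}
    ledger = ledger if ledger is not None else TransferLedger()
    access_log = access_log if access_log is not None else DataAccessLog(ledger)

    ids = [f"final@{nid}" for nid in order]
    location = {mid: nid for mid, nid in zip(ids, order)}  # resident at home
    rngs = {
        mid: np.random.default_rng(derive_seed(plan.seed, mid, "closing"))
        for mid in ids
    }

    for step, node_id in enumerate(order):
        node = node_map[node_id]
        for mid in ids:
            if location[mid] != node_id:
                ledger.record(mid, location[mid], node_id, 0, step, kind="train")
                location[mid] = node_id
        cfg = _node_config(distill_config, node, plan)
        # snapshot soft labels of all models before any update at this node
        softs = {}
        for mid, model in zip(ids, students):
            access_log.record(mid, node_id, node_id, "teacher_inference")
            softs[mid] = soften(model.predict_logits(node.data.samples), cfg.temperature)
        for mid, model in zip(ids, students):
            others = [softs[o] for o in ids if o != mid]
            combined = combine_teachers(others) if others else None
            access_log.record(mid, node_id, node_id, "train")
            model.train_epochs(
                node.data.samples,
                node.data.labels,
                k,
                _plain_if_no_teachers(cfg, combined),
                teacher_soft=combined,
                rng=rngs[mid],
                batch_size=plan.batch_size,
                learning_rate=plan.learning_rate,
            )

    result = TrainedModelSet(ledger=ledger, access_log=access_log)
    result.students = list(students)
    reports = []
    for mid, model in zip(ids, students):
        ledger.record(mid, location[mid], EVAL_HOST, 0, len(order), kind="eval")
        location[mid] = EVAL_HOST
        reports.append(_evaluate(model, validation, mid, access_log))
    best = select_best(reports, plan.selection_metric)
    result.final_model = students[best]
    result.checkpoints = [(m.export_weights().copy(), r) for m, r in zip(students, reports)]
    result.selection = {
        "checkpoint": best,
        "model_id": ids[best],
        "metric": plan.selection_metric,
        "value": getattr(reports[best], plan.selection_metric),
    }
    return result


def average_weights(models: Sequence) -> np.ndarray:
    """Element-wise arithmetic mean of same-architecture weight vectors.

    Accepts models (``export_weights`` is called) or flat vectors.  Averaging
    is what makes the cluster representative non-invertible back to any
    member's exact parameters.
    """
    if len(models) == 0:
        raise ValueError("need at least one model")
    vectors = [
        np.asarray(m.export_weights() if hasattr(m, "export_weights") else m, dtype=float)
        for m in models
    ]
    length = vectors[0].shape
    if any(v.shape != length for v in vectors):
        raise ValueError("weight vectors must have equal length (same architecture)")
    return np.mean(np.stack(vectors), axis=0)


def cluster_train(
    topology: Topology,
    nodes: Sequence[NodeDataset],
    plan: TrainPlan,
    distill_config: DistillationConfig,
    validation: LabeledDataset,
    model_factory: Callable[[int], ModelContract],
    ledger: Optional[TransferLedger] = None,
    access_log: Optional[DataAccessLog] = None,
) -> TrainedModelSet:
    """Hierarchical training over a clustered topology.

    Within each cluster (simulated sequentially with independent seed
    streams, result-equivalent to concurrent execution): every node trains a
    specialist, each specialist then circuits the cluster ring once as a
    student — ``s`` deliveries per model, ``s**2`` per cluster — distilling
    at every stop against the resident node's specialist.  The cluster's
    generalists are weight-averaged into one representative.  The ``m``
    representatives then circuit the ring of clusters the same way (``m**2``
    deliveries), training at each cluster's head node with the resident
    representative as teacher.  One full circuit therefore ledgers exactly
    ``sum(s_i**2) + m**2`` training transfers.
    """
    if topology.n_clusters < 2:
        single = Topology(node_ids=topology.node_ids, clusters=[list(topology.node_ids)])
        node_map = {n.node_id: n for n in nodes}
        teachers = train_specialists(
            list(nodes),
            model_factory,
            plan.specialist_epochs or plan.rounds * plan.epochs_per_node,
            plan.seed,
            plan,
            access_log,
        )
        return daita_train(
            single, nodes, teachers, plan, distill_config, validation,
            model_factory, ledger, access_log,
        )

    node_map = {n.node_id: n for n in nodes}
    ledger = ledger if ledger is not None else TransferLedger()
    access_log = access_log if access_log is not None else DataAccessLog(ledger)
    result = TrainedModelSet(ledger=ledger, access_log=access_log)

    arch = None
    representatives: list[ModelContract] = []
    rep_home: list[str] = []  # head node of each cluster hosts its representative
    spec_epochs = plan.specialist_epochs or plan.epochs_per_node

    for ci, ring in enumerate(topology.traversal_order):
        cluster_nodes = [node_map[nid] for nid in ring]
        teachers = train_specialists(
            cluster_nodes, model_factory, spec_epochs,
            derive_seed(plan.seed, "cluster", ci), plan, access_log,
        )
        result.specialists.update(teachers)
        archs = {t.architecture for t in teachers.values()}
        if len(archs) > 1:
            raise ValueError(
                f"cluster {ci} mixes architectures {sorted(archs)}; cannot weight-average"
            )
        arch = arch or archs.pop()

        # each specialist circuits the cluster ring once as a student
        generalists = []
        s = len(ring)
        for start_pos, nid in enumerate(ring):
            mid = f"generalist@{nid}"
            student = teachers[nid].clone()
            rng = np.random.default_rng(derive_seed(plan.seed, mid, "batches"))
            pos = start_pos
            if s == 1:
                ledger.record(mid, EVAL_HOST, ring[0], 0, 0, kind="train")
            for step in range(s if s > 1 else 0):
                nxt = (pos + 1) % s
                ledger.record(mid, ring[pos], ring[nxt], 0, step, kind="train")
                pos = nxt
                node = cluster_nodes[pos]
                cfg = _node_config(distill_config, node, plan)
                combined = _teacher_soft_on(
                    {ring[pos]: teachers[ring[pos]]}, node, cfg, access_log
                )
                access_log.record(mid, node.node_id, node.node_id, "train")
                student.train_epochs(
                    node.data.samples, node.data.labels, plan.epochs_per_node,
                    _plain_if_no_teachers(cfg, combined),
                    teacher_soft=combined, rng=rng,
                    batch_size=plan.batch_size, learning_rate=plan.learning_rate,
                )
            generalists.append(student)
            result.students.append(student)
        rep = model_factory(derive_seed(plan.seed, "rep", ci))
        rep.import_weights(average_weights(generalists))
        representatives.append(rep)
        rep_home.append(ring[0])

    # inter-cluster circuit: each representative visits every cluster head once
    m = len(representatives)
    reports = []
    for start_pos in range(m):
        mid = f"representative@cluster{start_pos}"
        rep = representatives[start_pos]
        rng = np.random.default_rng(derive_seed(plan.seed, mid, "batches"))
        pos = start_pos
        for step in range(m):
            nxt = (pos + 1) % m
            ledger.record(mid, rep_home[pos], rep_home[nxt], 1, step, kind="train")
            pos = nxt
            node = node_map[rep_home[pos]]
            cfg = _node_config(distill_config, node, plan)
            combined = _teacher_soft_on(
                {f"rep_teacher@{pos}": representatives[pos]}
                if pos != start_pos
                else {},
                node,
                cfg,
                access_log,
            )
            access_log.record(mid, node.node_id, node.node_id, "train")
            rep.train_epochs(
                node.data.samples, node.data.labels, plan.epochs_per_node,
                _plain_if_no_teachers(cfg, combined),
                teacher_soft=combined, rng=rng,
                batch_size=plan.batch_size, learning_rate=plan.learning_rate,
            )
        ledger.record(mid, rep_home[pos], EVAL_HOST, 1, m, kind="eval")
        reports.append(_evaluate(rep, validation, mid, access_log))

    best = select_best(reports, plan.selection_metric)
    result.final_model = representatives[best]
    result.checkpoints = [
        (r.export_weights().copy(), rep) for r, rep in zip(representatives, reports)
    ]
    result.selection = {
        "checkpoint": best,
        "metric": plan.selection_metric,
        "value": getattr(reports[best], plan.selection_metric),
    }
    return result


def privacy_guard(
    ledger: TransferLedger,
    access_log: DataAccessLog,
    mode: str = "decentralized",
) -> list[dict]:
    """Audit a run: raw data must never move; models compute where they live.

    Returns a list of violation records (empty means the run passed).  Two
    checks: (a) every data access executed on the node owning the data —
    a mismatch means raw samples crossed a node boundary; (b) every access
    by a traveling model happened at the model's current residence per the
    ledger replay.  In ``mode="centralized"`` check (a) is reported as an
    informational ``centralized_mode`` note, not a violation.
    """
    violations: list[dict] = []
    for entry in access_log.entries:
        if entry["data_node"] != entry["exec_node"]:
            record = {
                "check": "raw_data_movement",
                "model_id": entry["model_id"],
                "data_node": entry["data_node"],
                "exec_node": entry["exec_node"],
                "detail": entry.get("detail", ""),
            }
            if mode == "centralized":
                record["check"] = "centralized_mode"
                record["informational"] = True
            violations.append(record)

    # replay residences: a model's location is the destination of its latest move
    for entry in access_log.entries:
        mid = entry["model_id"]
        pos = entry["ledger_position"]
        residence = None
        for move in ledger.entries[:pos]:
            if move.model_id == mid:
                residence = move.to_node
        if residence is not None and entry["exec_node"] != residence:
            violations.append(
                {
                    "check": "remote_evaluation",
                    "model_id": mid,
                    "exec_node": entry["exec_node"],
                    "residence": residence,
                }
            )
    return [v for v in violations if not v.get("informational")] + [
        v for v in violations if v.get("informational")
    ]
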