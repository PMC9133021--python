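"""Ring and clustered-DAG topologies with exact model-transfer cost accounting.

A topology is a partition of data-silo nodes into ordered clusters.  Within a
cluster, models travel the ring of member nodes; between clusters, one
representative model per cluster travels a ring over clusters.  Every movement
of a model's full weights between two distinct locations is one *transfer
operation* — the unit of communication cost — and is recorded in an
append-only :class:`TransferLedger`.

Closed-form counts:

* a flat ring of ``n`` nodes, each of the ``n`` per-node models completing one
  full circuit, costs ``n**2`` transfers per circuit;
* ``m`` clusters of sizes ``s_1..s_m`` cost ``sum(s_i**2) + m**2`` per circuit
  (intra-cluster circuits plus one circuit of the ``m`` representatives);
* a student plus ``t`` co-traveling teachers visiting ``n`` nodes for ``R``
  rounds costs ``n * R * (t + 1)``;
* a client–server run with ``w`` workers moves weights twice per worker per
  batch, so ``(images_per_worker / batch_size) * 2w * epochs``.

Each closed form is cross-checkable against a brute-force enumeration of the
ledger entries of a simulated circuit (:func:`simulate_circuit`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "Topology",
    "TransferEntry",
    "TransferLedger",
    "build_ring",
    "build_clustered",
    "transfers_per_circuit",
    "simulate_circuit",
    "decentralized_transfer_count",
    "clientserver_transfer_count",
    "reduction_factor",
]

#: Virtual location models depart from before their first delivery, and the
#: host holding the shared validation set.  Not a data node.
EVAL_HOST = "__eval_host__"


@dataclass(frozen=True)
class TransferEntry:
    """One full-weight movement of one model between two distinct locations."""

    model_id: str
    from_node: str
    to_node: str
    round_index: int
    step_index: int
    kind: str = "train"  # "train" = delivery to a training node, "eval" = move to the evaluation host

    def __post_init__(self) -> None:
        if self.from_node == self.to_node:
            raise ValueError(
                f"transfer requires distinct locations, got {self.from_node!r} twice"
            )


class TransferLedger:
    """Append-only record of model-weight movements.

    The count of ``kind == "train"`` entries is the single source of truth for
    all communication-cost reports; movements to the evaluation host are
    recorded but reported separately.
    """

    def __init__(self) -> None:
        self.entries: list[TransferEntry] = []

    def record(
        self,
        model_id: str,
        from_node: str,
        to_node: str,
        round_index: int = 0,
        step_index: int = 0,
        kind: str = "train",
    ) -> TransferEntry:
        entry = TransferEntry(model_id, from_node, to_node, round_index, step_index, kind)
        self.entries.append(entry)
        return entry

    def count(self, kind: str = "train") -> int:
        return sum(1 for e in self.entries if e.kind == kind)

    def __len__(self) -> int:
        return len(self.entries)

    def to_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            for e in self.entries:
                fh.write(json.dumps(e.__dict__) + "\n")

    @classmethod
    def from_jsonl(cls, path) -> "TransferLedger":
        ledger = cls()
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line:
                    ledger.entries.append(TransferEntry(**json.loads(line)))
        return ledger


@dataclass
class Topology:
    """A partition of nodes into ordered clusters with ring traversal orders.

    Attributes
    ----------
    node_ids
        All node identifiers, in declaration order.
    clusters
        Partition of ``node_ids`` into ordered groups.
    traversal_order
        Per-cluster ring sequence (the listed node order; the first node is
        the head of the ring).
    inter_cluster_order
        Ring over cluster indices, traversed by cluster representatives.
    """

    node_ids: list[str]
    clusters: list[list[str]]
    traversal_order: list[list[str]] = field(default_factory=list)
    inter_cluster_order: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.traversal_order:
            self.traversal_order = [list(c) for c in self.clusters]
        if not self.inter_cluster_order:
            self.inter_cluster_order = list(range(len(self.clusters)))
        self.validate()

    def validate(self) -> None:
        if not self.node_ids:
            raise ValueError("topology requires at least one node")
        if len(set(self.node_ids)) != len(self.node_ids):
            raise ValueError("duplicate node ids")
        flat = [n for c in self.clusters for n in c]
        if sorted(flat) != sorted(self.node_ids):
            raise ValueError("clusters must partition node_ids exactly")
        for c, order in zip(self.clusters, self.traversal_order):
            if not c:
                raise ValueError("empty cluster")
            if sorted(order) != sorted(c):
                raise ValueError("traversal order must permute its cluster")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def cluster_sizes(self) -> list[int]:
        return [len(c) for c in self.clusters]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "node_ids": self.node_ids,
                    "clusters": self.clusters,
                    "traversal_order": self.traversal_order,
                    "inter_cluster_order": self.inter_cluster_order,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "Topology":
        with open(path) as fh:
            return cls(**json.load(fh))


def build_ring(node_ids: Sequence[str]) -> Topology:
    """Build a single-cluster ring over ``node_ids`` in the given order."""
    ids = list(node_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate node ids")
    return Topology(node_ids=ids, clusters=[ids.copy()])


def build_clustered(cluster_spec: Iterable[Sequence[str]]) -> Topology:
    """Build ``m`` within-cluster rings plus a ring over the clusters."""
    clusters = [list(group) for group in cluster_spec]
    for group in clusters:
        if not group:
            raise ValueError("empty cluster group")
    flat = [n for c in clusters for n in c]
    if len(set(flat)) != len(flat):
        raise ValueError("cluster groups must be disjoint")
    return Topology(node_ids=flat, clusters=clusters)


def transfers_per_circuit(topology: Topology) -> int:
    """Closed-form model-transfer count for one full circuit of the topology.

    ``sum(s_i**2) + m**2`` for ``m > 1`` clusters; the inter-cluster term is
    omitted for a single cluster, giving ``n**2`` for a flat ring.
    """
    sizes = topology.cluster_sizes
    m = len(sizes)
    intra = sum(s * s for s in sizes)
    return intra + (m * m if m > 1 else 0)


def simulate_circuit(topology: Topology) -> TransferLedger:
    """Brute-force one circuit, recording every model movement in a ledger.

    Within each cluster, each member node's model makes a full circuit of the
    cluster ring: ``s`` hops (its final hop returns it home), so ``s**2``
    deliveries per cluster.  With more than one cluster, each cluster's
    representative then circuits the ring of ``m`` clusters the same way.
    A single-node ring is degenerate: its one delivery comes from the
    evaluation host.
    """
    ledger = TransferLedger()

    def _circuit(ring: list[str], model_ids: list[str]) -> None:
        s = len(ring)
        if s == 1:
            for mid in model_ids:
                ledger.record(mid, EVAL_HOST, ring[0], 0, 0)
            return
        for mid, start in zip(model_ids, ring):
            pos = ring.index(start)
            for step in range(s):
                nxt = ring[(pos + 1) % s]
                ledger.record(mid, ring[pos], nxt, 0, step)
                pos = (pos + 1) % s

    for order in topology.traversal_order:
        _circuit(list(order), [f"model@{n}" for n in order])

    if topology.n_clusters > 1:
        rep_ring = [f"cluster{idx}" for idx in topology.inter_cluster_order]
        _circuit(rep_ring, [f"rep@{r}" for r in rep_ring])
    return ledger


def decentralized_transfer_count(n_nodes: int, n_rounds: int, n_teachers: int) -> int:
    """Transfers for a student plus co-traveling teachers over ``n_rounds``.

    Every visit to a node delivers the student and each of the ``n_teachers``
    teacher models, so the count is ``n_nodes * n_rounds * (n_teachers + 1)``.
    """
    if n_nodes < 1:
        raise ValueError("n_nodes must be >= 1")
    if n_rounds < 0 or n_teachers < 0:
        raise ValueError("n_rounds and n_teachers must be >= 0")
    return n_nodes * n_rounds * (n_teachers + 1)


def clientserver_transfer_count(
    images_per_worker: int,
    batch_size: int,
    n_epochs: int,
    n_workers: int,
    rounding: str = "paper_one_decimal",
) -> float:
    """Weight transfers for synchronous client–server distributed training.

    Each batch moves the weights to and from every worker (``2 * n_workers``
    per-batch transfers).  ``rounding="paper_one_decimal"`` rounds the batch
    count to one decimal place before multiplying, the convention used in
    published cost worksheets; ``"exact"`` keeps the exact fraction.
    """
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    if images_per_worker < 0 or n_epochs < 0 or n_workers < 0:
        raise ValueError("counts must be >= 0")
    if rounding not in ("paper_one_decimal", "exact"):
        raise ValueError(f"unknown rounding mode {rounding!r}")
    batches = images_per_worker / batch_size
    if rounding == "paper_one_decimal":
        batches = round(batches, 1)
    return batches * (2 * n_workers) * n_epochs


def reduction_factor(baseline_count: float, decentralized_count: float) -> float:
    """Baseline-to-decentralized transfer ratio, rounded to one decimal."""
    if decentralized_count <= 0:
        raise ValueError("decentralized_count must be > 0")
    return round(baseline_count / decentralized_count, 1)
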