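"""Desk-scale two-class datasets with asymmetric label noise and node partitions.

Emulates the study conditions of a binary image-classification benchmark
without any download: balanced two-class data (class 0 = cat/non-viable,
class 1 = dog/viable), an 80/20 train/validation split, deterministic
asymmetric label flipping (a fixed fraction of each true class is relabelled
as the other class), and partitioning of the training set across data-silo
nodes — either evenly with class stratification, or with the unequal
per-clinic sizes of a five-clinic embryology consortium
(587, 414, 789, 236, 167 of 2193).

Flip counts are exact (``round(rate * N_class)`` items per true class, chosen
by seeded permutation) rather than i.i.d. draws, so the per-node label
compositions are deterministic: balanced nodes of 360+360 under 50%/10%
flipping hold exactly 216 cat-labelled and 504 dog-labelled items.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np

__all__ = [
    "LabeledDataset",
    "NodeDataset",
    "make_synthetic_dataset",
    "split_train_validation",
    "inject_asymmetric_noise",
    "partition_nodes",
    "clinic_profile_sizes",
    "CLINIC_NODE_TOTALS",
]

#: Per-clinic training-set sizes of the five-node medical consortium.
CLINIC_NODE_TOTALS = (587, 414, 789, 236, 167)


@dataclass
class LabeledDataset:
    """Samples with current labels, pre-noise labels, and provenance tags.

    ``labels`` may differ from ``true_labels`` only for items flipped by
    noise injection; ``provenance`` carries the owning node/clinic tag (empty
    string before partitioning).
    """

    samples: np.ndarray
    labels: np.ndarray
    true_labels: np.ndarray
    provenance: np.ndarray = field(default=None)  # type: ignore[assignment]
    image_shape: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.true_labels = np.asarray(self.true_labels, dtype=int)
        if self.provenance is None:
            self.provenance = np.array([""] * len(self.labels), dtype=object)
        else:
            self.provenance = np.asarray(self.provenance, dtype=object)
        n = self.samples.shape[0]
        if not (len(self.labels) == len(self.true_labels) == len(self.provenance) == n):
            raise ValueError("samples, labels, true_labels, provenance must align")

    def __len__(self) -> int:
        return self.samples.shape[0]

    @property
    def n_classes(self) -> int:
        return int(max(self.labels.max(initial=0), self.true_labels.max(initial=0))) + 1

    def subset(self, idx: np.ndarray) -> "LabeledDataset":
        return LabeledDataset(
            self.samples[idx],
            self.labels[idx],
            self.true_labels[idx],
            self.provenance[idx],
            self.image_shape,
        )

    def label_counts(self, n_classes: int = 2) -> np.ndarray:
        return np.bincount(self.labels, minlength=n_classes)

    def noise_fraction_by_labelled_class(self, n_classes: int = 2) -> np.ndarray:
        """Fraction of items in each *labelled* class whose label is wrong."""
        out = np.zeros(n_classes)
        for c in range(n_classes):
            mask = self.labels == c
            if mask.any():
                out[c] = np.mean(self.true_labels[mask] != c)
        return out

    # -- persistence ---------------------------------------------------------

    def to_npz(self, path: Union[str, Path]) -> None:
        np.savez_compressed(
            path,
            samples=self.samples,
            labels=self.labels,
            true_labels=self.true_labels,
            provenance=self.provenance.astype(str),
            image_shape=np.array(self.image_shape or (0, 0)),
        )

    @classmethod
    def from_npz(cls, path: Union[str, Path]) -> "LabeledDataset":
        with np.load(path, allow_pickle=False) as z:
            shape = tuple(int(v) for v in z["image_shape"])
            return cls(
                z["samples"],
                z["labels"],
                z["true_labels"],
                z["provenance"].astype(object),
                None if shape == (0, 0) else shape,  # type: ignore[arg-type]
            )

    def to_png_directory(self, directory: Union[str, Path]) -> None:
        """Write one grayscale PNG per sample plus a ``manifest.csv``.

        Requires ``image_shape``; feature-vector datasets use :meth:`to_npz`.
        """
        from PIL import Image

        if self.image_shape is None:
            raise ValueError("PNG export requires an image-shaped dataset")
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        h, w = self.image_shape
        with open(directory / "manifest.csv", "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["path", "label", "true_label", "node_id"])
            for i in range(len(self)):
                img = self.samples[i].reshape(h, w)
                arr = np.clip(img * 255.0, 0, 255).astype(np.uint8)
                name = f"sample_{i:06d}.png"
                Image.fromarray(arr, mode="L").save(directory / name)
                writer.writerow(
                    [name, int(self.labels[i]), int(self.true_labels[i]), self.provenance[i]]
                )

    @classmethod
    def from_png_directory(cls, directory: Union[str, Path]) -> "LabeledDataset":
        from PIL import Image

        directory = Path(directory)
        samples, labels, true_labels, prov = [], [], [], []
        shape = None
        with open(directory / "manifest.csv", newline="") as fh:
            for row in csv.DictReader(fh):
                arr = np.asarray(Image.open(directory / row["path"]), dtype=float) / 255.0
                shape = arr.shape
                samples.append(arr.ravel())
                labels.append(int(row["label"]))
                true_labels.append(int(row["true_label"]))
                prov.append(row["node_id"])
        return cls(np.stack(samples), labels, true_labels, np.array(prov, dtype=object), shape)


@dataclass
class NodeDataset:
    """One silo's local view of the training data, plus its role."""

    node_id: str
    data: LabeledDataset
    role: str = "train"  # train | validation | transfer | test

    def __len__(self) -> int:
        return len(self.data)


def make_synthetic_dataset(
    n_per_class: int,
    kind: str = "gaussian_blobs",
    class_separation: float = 3.0,
    seed: int = 0,
) -> LabeledDataset:
    """Balanced two-class dataset, deterministic given the seed.

    ``gaussian_blobs`` draws 2-D unit-variance Gaussians whose means are
    ``class_separation`` apart — at separation 3 a linear model reaches well
    over 95% balanced accuracy, at separation 0 the classes are
    indistinguishable.  ``toy_images`` emits 16×16 grayscale
    class-conditioned textures (vertical vs horizontal stripes in noise) so
    image-pipeline code paths are exercised without any download.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if class_separation < 0:
        raise ValueError("class_separation must be >= 0")
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    labels = np.repeat([0, 1], n_per_class)
    image_shape = None

    if kind == "gaussian_blobs":
        offset = class_separation / 2.0
        means = np.where(labels[:, None] == 0, -offset, offset)
        samples = rng.normal(0.0, 1.0, size=(n, 2)) + means
    elif kind == "toy_images":
        h = w = 16
        image_shape = (h, w)
        yy, xx = np.mgrid[0:h, 0:w]
        stripes0 = 0.5 + 0.5 * np.sin(2 * np.pi * xx / 4.0)  # vertical stripes
        stripes1 = 0.5 + 0.5 * np.sin(2 * np.pi * yy / 4.0)  # horizontal stripes
        base = np.where(labels[:, None, None] == 0, stripes0, stripes1)
        # separation scales signal-to-noise; noise sd fixed at 1 like the blobs
        noise = rng.normal(0.0, 1.0, size=(n, h, w))
        samples = (class_separation / 3.0) * (base - 0.5) + 0.3 * noise + 0.5
        samples = samples.reshape(n, h * w)
    else:
        raise ValueError(f"unknown dataset kind {kind!r}")

    perm = rng.permutation(n)
    return LabeledDataset(samples[perm], labels[perm], labels[perm].copy(), None, image_shape)


def split_train_validation(
    dataset: LabeledDataset, fraction_validation: float, seed: int = 0
) -> tuple[LabeledDataset, LabeledDataset]:
    """Seeded shuffle then disjoint, exhaustive, class-stratified split.

    Validation takes ``round(fraction * N_c)`` items of each true class, so a
    balanced pool stays balanced on both sides (2250+2250 at 20% gives a
    3600-item training set of exactly 1800 per class and 900 validation).
    """
    if not 0.0 < fraction_validation < 1.0:
        raise ValueError("fraction_validation must lie strictly in (0, 1)")
    rng = np.random.default_rng(seed)
    classes = np.unique(dataset.true_labels)
    sizes = np.array([(dataset.true_labels == c).sum() for c in classes])
    # total validation size rounds to nearest; split over classes by largest remainder
    n_val_total = int(np.floor(fraction_validation * len(dataset) + 0.5))
    exact = fraction_validation * sizes
    per_class = np.floor(exact).astype(int)
    short = n_val_total - per_class.sum()
    order = np.argsort(-(exact - per_class))
    per_class[order[:short]] += 1
    val_idx: list[int] = []
    train_idx: list[int] = []
    for cls, n_val in zip(classes, per_class):
        members = rng.permutation(np.flatnonzero(dataset.true_labels == cls))
        val_idx.extend(members[:n_val].tolist())
        train_idx.extend(members[n_val:].tolist())
    return (
        dataset.subset(np.sort(np.asarray(train_idx, dtype=int))),
        dataset.subset(np.sort(np.asarray(val_idx, dtype=int))),
    )


def inject_asymmetric_noise(
    dataset: LabeledDataset,
    flip_rate_per_true_class: Mapping[int, float],
    seed: int = 0,
) -> LabeledDataset:
    """Flip exactly ``round(rate * N_class)`` labels per true class.

    Binary flipping: an item of true class ``c`` is relabelled ``1 - c``.
    The flipped items are chosen by seeded permutation; the labelled-class
    counts after flipping depend only on the rates, not on the seed.
    ``true_labels`` are preserved for bookkeeping.
    """
    for rate in flip_rate_per_true_class.values():
        if not 0.0 <= rate <= 1.0:
            raise ValueError("flip rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    new_labels = dataset.true_labels.copy()
    for cls in sorted(flip_rate_per_true_class):
        rate = flip_rate_per_true_class[cls]
        members = np.flatnonzero(dataset.true_labels == cls)
        n_flip = int(round(rate * members.size))
        flip_idx = rng.permutation(members)[:n_flip]
        new_labels[flip_idx] = 1 - cls
    return replace(dataset, labels=new_labels)


def partition_nodes(
    train_set: LabeledDataset,
    sizes: Union[str, Sequence[int]],
    n_nodes: Optional[int] = None,
    seed: int = 0,
) -> list[NodeDataset]:
    """Split the training set into disjoint, exhaustive per-node views.

    ``sizes="even"`` stratifies by true class so every node receives equal
    class counts before any noise injection (remainders round-robin);
    an explicit size list assigns a seeded shuffle of the items in order.
    """
    n = len(train_set)
    rng = np.random.default_rng(seed)
    if isinstance(sizes, str):
        if sizes != "even":
            raise ValueError(f"unknown sizes mode {sizes!r}")
        if n_nodes is None or n_nodes < 1:
            raise ValueError("even partition requires n_nodes >= 1")
        per_node_idx: list[list[int]] = [[] for _ in range(n_nodes)]
        for rank, cls in enumerate(np.unique(train_set.true_labels)):
            members = rng.permutation(np.flatnonzero(train_set.true_labels == cls))
            # round-robin with a per-class offset so remainders spread evenly
            assign = (np.arange(members.size) + rank) % n_nodes
            for k in range(n_nodes):
                per_node_idx[k].extend(members[assign == k].tolist())
        chunks = [np.asarray(sorted(ix), dtype=int) for ix in per_node_idx]
    else:
        sizes = [int(s) for s in sizes]
        if any(s < 0 for s in sizes):
            raise ValueError("sizes must be nonnegative")
        if sum(sizes) != n:
            raise ValueError(f"sizes sum to {sum(sizes)}, dataset has {n} items")
        perm = rng.permutation(n)
        bounds = np.cumsum([0] + sizes)
        chunks = [np.sort(perm[bounds[i] : bounds[i + 1]]) for i in range(len(sizes))]

    nodes = []
    for k, idx in enumerate(chunks):
        node_id = f"node{k + 1}"
        view = train_set.subset(idx)
        view.provenance = np.array([node_id] * len(view), dtype=object)
        nodes.append(NodeDataset(node_id=node_id, data=view, role="train"))
    return nodes


def clinic_profile_sizes(total: int) -> list[int]:
    """Node sizes proportional to the five-clinic profile, largest-remainder.

    ``total == 2193`` reproduces the consortium's exact per-clinic totals
    (587, 414, 789, 236, 167).
    """
    if total < len(CLINIC_NODE_TOTALS):
        raise ValueError("total must be at least the number of clinics")
    props = np.asarray(CLINIC_NODE_TOTALS, dtype=float)
    props = props / props.sum()
    exact = props * total
    base = np.floor(exact).astype(int)
    remainder = total - base.sum()
    order = np.argsort(-(exact - base))
    base[order[:remainder]] += 1
    while (base == 0).any():  # tiny totals: every clinic keeps at least one item
        base[np.argmax(base)] -= 1
        base[np.argmin(base)] += 1
    return base.tolist()
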