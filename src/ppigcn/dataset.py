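"""Interface labels, protein-level splits and composite dataset assembly.

A residue of the query protein is an *interface residue* (label 1) when at
least one of its heavy (non-hydrogen) atoms lies within 5 A of any heavy
atom of the partner protein; "within" is inclusive, so a closest pair at
exactly 5.0 A is labeled positive. Labeling uses a KD-tree over partner
heavy atoms but is required (and tested) to equal the all-pairs brute
force.

Datasets are transductive: every protein's graph becomes one block of a
block-diagonal composite adjacency, features are stacked and standardized
with training-node statistics, and three disjoint node masks record which
proteins are train / validation / test. Splits are always by whole protein.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.spatial import cKDTree

from .features import FeatureMatrix, FeatureStandardizer
from .graphs import CompositeGraph, ProteinGraph, block_diagonal
from .structures import ProteinStructure

logger = logging.getLogger(__name__)

DEFAULT_INTERFACE_CUTOFF = 5.0

SPLIT_NAMES = ("train", "val", "test")


class DatasetError(ValueError):
    """Raised on misaligned inputs or invalid split requests."""


@dataclass
class LabelVector:
    """Per-residue binary interface labels for one protein."""

    protein_id: str
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if not np.isin(self.labels, (0, 1)).all():
            raise DatasetError(f"{self.protein_id}: labels must be 0/1")

    @property
    def n(self) -> int:
        return self.labels.shape[0]


@dataclass
class MaskedDataset:
    """Block-diagonal composite with stacked features, labels and masks."""

    composite: CompositeGraph
    features: np.ndarray
    labels: np.ndarray
    train_mask: np.ndarray
    val_mask: np.ndarray
    test_mask: np.ndarray
    scaler: FeatureStandardizer | None = None

    def __post_init__(self) -> None:
        n = self.composite.n
        if self.features.shape[0] != n or self.labels.shape[0] != n:
            raise DatasetError("features/labels are not aligned with the composite graph")
        masks = np.stack([self.train_mask, self.val_mask, self.test_mask])
        if masks.sum(axis=0).max() > 1:
            raise DatasetError("masks must be pairwise disjoint")

    @property
    def n(self) -> int:
        return self.composite.n

    @property
    def offsets(self) -> dict[str, tuple[int, int]]:
        return self.composite.offsets

    def mask(self, name: str) -> np.ndarray:
        return {"train": self.train_mask, "val": self.val_mask, "test": self.test_mask}[name]


def label_interfaces(
    query: ProteinStructure,
    partner: ProteinStructure,
    cutoff: float = DEFAULT_INTERFACE_CUTOFF,
) -> LabelVector:
    """Label query residues with a heavy atom within ``cutoff`` of the partner."""
    partner_coords = np.concatenate(
        [res.heavy_coords() for res in partner.residues]
    ) if partner.n else np.empty((0, 3))
    labels = np.zeros(query.n, dtype=int)
    if partner_coords.shape[0] == 0:
        logger.warning("%s: partner %s has no heavy atoms; all labels 0",
                       query.id, partner.id)
        return LabelVector(protein_id=query.id, labels=labels)
    tree = cKDTree(partner_coords)
    for i, res in enumerate(query.residues):
        coords = res.heavy_coords()
        if coords.shape[0] == 0:
            continue
        dist, _ = tree.query(coords, k=1)
        if np.min(dist) <= cutoff:
            labels[i] = 1
    return LabelVector(protein_id=query.id, labels=labels)


def label_interfaces_bruteforce(
    query: ProteinStructure,
    partner: ProteinStructure,
    cutoff: float = DEFAULT_INTERFACE_CUTOFF,
) -> LabelVector:
    """All-pairs reference labeler; the KD-tree route must reproduce this."""
    partner_coords = np.concatenate(
        [res.heavy_coords() for res in partner.residues]
    ) if partner.n else np.empty((0, 3))
    labels = np.zeros(query.n, dtype=int)
    for i, res in enumerate(query.residues):
        for c in res.heavy_coords():
            if partner_coords.shape[0] and np.any(
                np.linalg.norm(partner_coords - c, axis=1) <= cutoff
            ):
                labels[i] = 1
                break
    return LabelVector(protein_id=query.id, labels=labels)


def transfer_labels(
    labels: LabelVector,
    source: ProteinStructure,
    target: ProteinStructure,
) -> LabelVector:
    """Carry labels computed on one structure onto another conformation.

    Correspondence is by chain id + author residue number (+ insertion
    code); target residues without a match get label 0. This is how labels
    derived from a bound complex are applied to the unbound structure.
    """
    by_key = {
        (res.chain_id, res.author_number, res.insertion_code): int(labels.labels[i])
        for i, res in enumerate(source.residues)
    }
    out = np.array([
        by_key.get((res.chain_id, res.author_number, res.insertion_code), 0)
        for res in target.residues
    ])
    return LabelVector(protein_id=target.id, labels=out)


def random_split(
    protein_ids: Sequence[str],
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> dict[str, str]:
    """Deterministically assign whole proteins to train/val/test."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise DatasetError(f"fractions must sum to 1, got {fractions}")
    n = len(protein_ids)
    n_nonzero = sum(1 for f in fractions if f > 0)
    if n < n_nonzero:
        raise DatasetError(f"{n} proteins cannot fill {n_nonzero} nonempty splits")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    # keep every nonzero split nonempty after rounding
    if fractions[0] > 0:
        n_train = max(n_train, 1)
    if fractions[1] > 0:
        n_val = max(n_val, 1)
    if fractions[2] > 0:
        n_train = min(n_train, n - n_val - 1)
    split: dict[str, str] = {}
    for rank, idx in enumerate(order):
        if rank < n_train:
            part = "train"
        elif rank < n_train + n_val:
            part = "val"
        else:
            part = "test"
        split[protein_ids[idx]] = part
    return split


def assemble(
    proteins: Sequence[tuple[ProteinGraph, FeatureMatrix, LabelVector]],
    split: Mapping[str, str],
    standardize_features: bool = True,
) -> MaskedDataset:
    """Stack per-protein graphs/features/labels into one masked dataset.

    Feature columns 0-12 are z-scored with training-node statistics (unless
    ``standardize_features`` is disabled); the one-hot block is untouched.
    """
    for graph, feats, labels in proteins:
        if not (graph.n == feats.n == labels.n):
            raise DatasetError(
                f"{graph.protein_id}: graph n={graph.n}, features n={feats.n}, "
                f"labels n={labels.n} are inconsistent"
            )
        if graph.protein_id not in split:
            raise DatasetError(f"split does not cover protein {graph.protein_id}")
        if split[graph.protein_id] not in SPLIT_NAMES:
            raise DatasetError(
                f"{graph.protein_id}: unknown split {split[graph.protein_id]!r}"
            )

    composite = block_diagonal([g for g, _, _ in proteins])
    features = np.vstack([f.values for _, f, _ in proteins])
    labels = np.concatenate([l.labels for _, _, l in proteins])

    n = composite.n
    masks = {name: np.zeros(n, dtype=bool) for name in SPLIT_NAMES}
    for (pid, _), (start, stop) in zip(composite.blocks, composite.offsets.values()):
        masks[split[pid]][start:stop] = True

    scaler = None
    if standardize_features:
        if masks["train"].sum() >= 2:
            scaler = FeatureStandardizer().fit(features[masks["train"]])
            features = scaler.transform(features)
        else:
            logger.warning("fewer than 2 training nodes; skipping standardization")

    return MaskedDataset(
        composite=composite,
        features=features,
        labels=labels,
        train_mask=masks["train"],
        val_mask=masks["val"],
        test_mask=masks["test"],
        scaler=scaler,
    )


def export_labels(
    labels: LabelVector, structure: ProteinStructure, path: str | Path
) -> Path:
    """Write labels as TSV: protein_id, chain, author_number, label."""
    if labels.n != structure.n:
        raise DatasetError("labels are not aligned with the structure")
    lines = ["protein_id\tchain\tauthor_number\tlabel"]
    for i, res in enumerate(structure.residues):
        num = f"{res.author_number}{res.insertion_code}"
        lines.append(f"{labels.protein_id}\t{res.chain_id}\t{num}\t{labels.labels[i]}")
    path = Path(path)
    path.write_text("\n".join(lines) + "\n")
    return path


def import_labels(path: str | Path) -> LabelVector:
    """Read a label TSV written by :func:`export_labels`."""
    lines = Path(path).read_text().splitlines()
    values, pid = [], None
    for line in lines[1:]:
        pid_i, _chain, _num, label = line.split("\t")
        pid = pid or pid_i
        values.append(int(label))
    if pid is None:
        raise DatasetError(f"empty label file: {path}")
    return LabelVector(protein_id=pid, labels=np.array(values))
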