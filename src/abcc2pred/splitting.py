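"""PCC-threshold labeling and train/test splitting.

Three split strategies are provided, mirroring common practice for
imbalanced QSAR sets:

* ``maccs_diverse`` — greedy MaxMin diversity selection in structural-key
  space (distance = 1 - Tanimoto),
* ``descriptor_diverse`` — the same greedy MaxMin in normalized descriptor
  space (continuous Tanimoto dissimilarity by default),
* ``random_stratified`` — per-class random sampling.

Diverse splits are fully deterministic (ties broken by input order); the
random split is reproducible from its seed.  Diverse selection ignores the
class labels, so diverse training sets have uncontrolled class ratios —
that is a property of the method, not a bug.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .descriptors import DescriptorMatrix, StructuralKeyFingerprint
from .records import Dataset


@dataclass
class LabelRule:
    """Classify as substrate iff PCC <= threshold (boundary inclusive)."""

    threshold: float = -0.25

    def __post_init__(self) -> None:
        if not (-1.0 <= self.threshold <= 0.0):
            raise ValueError(f"threshold {self.threshold} outside [-1, 0]")


@dataclass
class SplitResult:
    strategy: str
    train_ids: list[str]
    test_ids: list[str]
    fraction: float
    seed: int | None = None

    def __post_init__(self) -> None:
        train, test = set(self.train_ids), set(self.test_ids)
        if train & test:
            raise ValueError("train and test sets overlap")

    def to_dict(self) -> dict:
        return {
            "strategy": self.strategy,
            "fraction": self.fraction,
            "seed": self.seed,
            "train_ids": list(self.train_ids),
            "test_ids": list(self.test_ids),
        }


def label_by_pcc(ds: Dataset, rule: LabelRule) -> Dataset:
    """Label every record: substrate iff pcc <= threshold.

    A PCC exactly at the threshold is a substrate (the cutoff is "lower or
    equal").  Records without a PCC raise, listing the offending ids.
    """
    missing = [r.id for r in ds.records if r.pcc is None]
    if missing:
        raise ValueError(f"records without PCC cannot be labeled: {missing}")
    labels = [1 if r.pcc <= rule.threshold else 0 for r in ds.records]
    return Dataset(
        records=ds.records, label_threshold=rule.threshold, labels=labels
    )


def split_random_stratified(
    ds: Dataset, fraction: float = 0.8, seed: int | None = 0
) -> SplitResult:
    """Random split keeping floor(fraction * class size) of each class in
    training.

    With 154 substrates at 80% this puts 123 substrates in training.
    Raises if either class is empty or the test set would be empty.
    """
    if ds.labels is None:
        raise ValueError("dataset must be labeled before splitting")
    ids = np.asarray(ds.ids, dtype=object)
    labels = np.asarray(ds.labels)
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    for cls in (0, 1):
        members = np.flatnonzero(labels == cls)
        if members.size == 0:
            raise ValueError(f"class {cls} has no members; cannot stratify")
        n_train = math.floor(fraction * members.size)
        chosen = rng.choice(members, size=n_train, replace=False)
        train_idx.extend(int(i) for i in chosen)
    train_set = set(train_idx)
    test_idx = [i for i in range(len(ids)) if i not in train_set]
    if not test_idx:
        raise ValueError("empty test set; lower the training fraction")
    if not train_idx:
        raise ValueError("empty training set; raise the training fraction")
    train_idx = sorted(train_set)
    return SplitResult(
        strategy="random_stratified",
        train_ids=[str(i) for i in ids[train_idx]],
        test_ids=[str(i) for i in ids[test_idx]],
        fraction=fraction,
        seed=seed,
    )


# --- diverse (MaxMin) splitting --------------------------------------------


def fingerprint_distance_matrix(fps: list[StructuralKeyFingerprint]) -> np.ndarray:
    """Pairwise 1 - Tanimoto over structural-key fingerprints."""
    n = len(fps)
    bits = np.zeros((n, fps[0].n_keys + 1), dtype=bool)
    for i, fp in enumerate(fps):
        if fp.n_keys != fps[0].n_keys:
            raise ValueError("fingerprint length mismatch")
        bits[i, list(fp.bits)] = True
    counts = bits.sum(axis=1).astype(float)
    inter = (bits.astype(np.float64) @ bits.T.astype(np.float64))
    union = counts[:, None] + counts[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 1.0)
    np.fill_diagonal(sim, 1.0)
    return 1.0 - sim


def descriptor_distance_matrix(
    matrix: DescriptorMatrix, metric: str = "tanimoto"
) -> np.ndarray:
    """Continuous dissimilarity on z-scored descriptors.

    Columns are first min-max rescaled to [0, 1] (constant columns to 0) so
    the continuous Tanimoto coefficient
    ``x.y / (|x|^2 + |y|^2 - x.y)`` is well defined; ``metric="euclidean"``
    is the config alternative.
    """
    X = matrix.values.to_numpy(dtype=float)
    lo, hi = X.min(axis=0), X.max(axis=0)
    span = np.where(hi - lo > 1e-12, hi - lo, 1.0)
    X = (X - lo) / span
    if metric == "euclidean":
        sq = (X**2).sum(axis=1)
        d2 = sq[:, None] + sq[None, :] - 2 * X @ X.T
        return np.sqrt(np.clip(d2, 0.0, None))
    if metric != "tanimoto":
        raise ValueError(f"unknown descriptor metric {metric!r}")
    dot = X @ X.T
    sq = np.diag(dot)
    denom = sq[:, None] + sq[None, :] - dot
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(denom > 1e-12, dot / np.where(denom > 1e-12, denom, 1.0), 1.0)
    np.fill_diagonal(sim, 1.0)
    return 1.0 - np.clip(sim, 0.0, 1.0)


def maxmin_pick(dist: np.ndarray, n_pick: int) -> list[int]:
    """Greedy MaxMin selection on a precomputed distance matrix.

    The first pick is the first member (in input order) of the most distant
    pair; every later pick maximizes the minimum distance to the picked
    set.  All ties break toward the lowest index, so the selection is
    deterministic.
    """
    n = dist.shape[0]
    if n_pick < 1 or n_pick > n:
        raise ValueError(f"cannot pick {n_pick} of {n}")
    # first member of the most distant pair, scanning row-major
    best = np.unravel_index(np.argmax(dist), dist.shape)
    first = int(min(best))
    picked = [first]
    mindist = dist[first].copy()
    mindist[first] = -np.inf
    for _ in range(n_pick - 1):
        nxt = int(np.argmax(mindist))  # argmax takes the lowest index on ties
        picked.append(nxt)
        mindist = np.minimum(mindist, dist[nxt])
        mindist[nxt] = -np.inf
    return picked


def split_diverse_maxmin(
    ds: Dataset,
    fraction: float = 0.8,
    space: str = "fingerprint",
    fingerprints: list[StructuralKeyFingerprint] | None = None,
    matrix: DescriptorMatrix | None = None,
    metric: str = "tanimoto",
) -> SplitResult:
    """Diversity split: training = ceil(fraction * N) MaxMin picks.

    ``space="fingerprint"`` needs ``fingerprints`` aligned with the
    dataset; ``space="descriptor"`` needs a z-scored ``matrix``.  With
    N=1204 at 80% the training set holds 964 compounds.
    """
    n = len(ds)
    if n < 2:
        raise ValueError("need at least 2 compounds to split")
    n_train = math.ceil(fraction * n)
    if n_train >= n:
        raise ValueError("empty test set; lower the training fraction")
    if space == "fingerprint":
        if fingerprints is None or len(fingerprints) != n:
            raise ValueError("fingerprints must align with the dataset")
        dist = fingerprint_distance_matrix(fingerprints)
        strategy = "maccs_diverse"
    elif space == "descriptor":
        if matrix is None or len(matrix) != n:
            raise ValueError("descriptor matrix must align with the dataset")
        if matrix.ids != ds.ids:
            raise ValueError("descriptor matrix ids do not match the dataset")
        dist = descriptor_distance_matrix(matrix, metric=metric)
        strategy = "descriptor_diverse"
    else:
        raise ValueError(f"unknown space {space!r}")
    picked = maxmin_pick(dist, n_train)
    picked_set = set(picked)
    ids = ds.ids
    return SplitResult(
        strategy=strategy,
        train_ids=[ids[i] for i in sorted(picked_set)],
        test_ids=[ids[i] for i in range(n) if i not in picked_set],
        fraction=fraction,
    )
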