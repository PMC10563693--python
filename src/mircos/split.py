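"""Kennard-Stone maxmin sample selection and the stratified 70/30 split.

Kennard-Stone picks a representative calibration subset deterministically:
the first two picks are the pair at maximum Euclidean distance, and every
later pick maximizes its minimum distance to the already-selected set.
Ties are broken toward the lowest canonical index (records sorted by
sample_id), so selection is invariant to record shuffling.

The stratified split runs Kennard-Stone independently within each class
with a per-class training size of floor(fraction * class size) —
109 cultivated / 63 wild at 0.7 gives the 76/44 train and 33/19 test
counts the pipeline's reports are built around.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .preprocess import ChainTransformer, PreprocessSpec
from .spectra import SpectraSet

__all__ = [
    "SplitResult",
    "SplitError",
    "kennard_stone_select",
    "stratified_split",
    "write_split_manifest",
    "read_split_manifest",
]


class SplitError(ValueError):
    """Invalid split parameters or class structure."""


@dataclass(frozen=True)
class SplitResult:
    """Disjoint train/test sample-id sets with per-class bookkeeping."""

    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    per_class_counts: dict[str, tuple[int, int]]  # class -> (n_train, n_test)
    method: str = "kennard_stone"
    seed: int | None = None

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise SplitError("train and test sets overlap")
        n_train = sum(c[0] for c in self.per_class_counts.values())
        n_test = sum(c[1] for c in self.per_class_counts.values())
        if (n_train, n_test) != (len(self.train_ids), len(self.test_ids)):
            raise SplitError("per_class_counts inconsistent with id sets")


def kennard_stone_select(X: np.ndarray, n_select: int) -> list[int]:
    """Greedy maxmin (Kennard-Stone) selection of ``n_select`` row indices.

    The returned list is in selection order. Deterministic: the seed pair
    is the lexicographically smallest of the maximum-distance pairs, and
    subsequent maxmin ties resolve to the lowest row index.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if not (2 <= n_select <= n):
        raise SplitError(f"n_select must be in [2, {n}], got {n_select}")
    d = cdist(X, X)
    # seed pair: maximum pairwise distance, lowest (i, j) on ties
    iu = np.triu_indices(n, k=1)
    flat = d[iu]
    best = np.flatnonzero(flat == flat.max())[0]
    i0, j0 = iu[0][best], iu[1][best]
    selected = [int(i0), int(j0)]
    min_dist = np.minimum(d[i0], d[j0])
    min_dist[selected] = -np.inf
    while len(selected) < n_select:
        nxt = int(np.argmax(min_dist))  # argmax returns the first (lowest) index on ties
        selected.append(nxt)
        min_dist = np.minimum(min_dist, d[nxt])
        min_dist[nxt] = -np.inf
    return selected


def stratified_split(
    spectra: SpectraSet,
    fraction: float = 0.7,
    space: PreprocessSpec | str | None = None,
) -> SplitResult:
    """Per-class Kennard-Stone train/test partition.

    ``space`` names the representation distances are computed in: ``None``
    (raw spectra, the default), a chain name, or a PreprocessSpec.
    Replicated records are averaged per sample first, so replicates of one
    sample always land on the same side of the split. Training size per
    class is floor(fraction * class size); every class must keep at least
    one test sample.
    """
    if not (0 < fraction < 1):
        raise SplitError("fraction must lie in (0, 1)")
    work = spectra.mean_by_sample()
    if space is not None:
        work = ChainTransformer.from_name(space).fit_transform(work) if isinstance(
            space, str
        ) else ChainTransformer(space).fit_transform(work)

    # canonical ordering by sample_id for deterministic tie-breaking
    order = np.argsort(np.asarray(work.sample_ids))
    ids = [work.sample_ids[i] for i in order]
    labels = [work.labels[i] for i in order]
    X = work.absorbance[order]

    train_ids: list[str] = []
    test_ids: list[str] = []
    counts: dict[str, tuple[int, int]] = {}
    for class_name in sorted(set(labels)):
        cls_idx = [i for i, lab in enumerate(labels) if lab == class_name]
        n_cls = len(cls_idx)
        if n_cls < 3:
            raise SplitError(f"class {class_name!r} has {n_cls} samples; need >= 3")
        if fraction * n_cls > n_cls - 0.5:
            raise SplitError(
                f"fraction {fraction} would leave class {class_name!r} with an "
                f"empty test set at conventional rounding"
            )
        n_train = int(np.floor(fraction * n_cls))
        if n_train < 2 or n_train >= n_cls:
            raise SplitError(
                f"fraction {fraction} leaves class {class_name!r} with an "
                f"empty or undersized train/test side"
            )
        picked = kennard_stone_select(X[cls_idx], n_train)
        chosen = {cls_idx[p] for p in picked}
        train_ids += [ids[i] for i in sorted(chosen)]
        test_ids += [ids[i] for i in cls_idx if i not in chosen]
        counts[class_name] = (n_train, n_cls - n_train)
    return SplitResult(tuple(train_ids), tuple(test_ids), counts)


def write_split_manifest(split: SplitResult, path: str | Path) -> None:
    rows = [(sid, "train") for sid in split.train_ids] + [
        (sid, "test") for sid in split.test_ids
    ]
    pd.DataFrame(rows, columns=["sample_id", "role"]).to_csv(path, index=False)


def read_split_manifest(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, dtype=str)
    return dict(zip(df["sample_id"], df["role"]))
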