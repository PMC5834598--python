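"""Kennard-Stone sample splitting.

The study design holds out two small sets from a single cohort: 70 % of
the samples for training, 15 % for internal validation (GA fitness, KNN
k selection, SVM hyper-parameter grids) and 15 % for final prediction.
Selection is by the classical Kennard-Stone maximin algorithm, which is
fully deterministic: the most design-spanning samples are picked first
and go to training, so the held-out sets sit inside the calibration
domain.

On the 76-sample cohort (42 + 34) the stratified 70/15/15 rule yields
exactly 54 training, 11 validation and 11 prediction samples, with a
prediction set of 6 NILM + 5 SIL.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import InputError
from .preprocess import FLAG_NORMALIZED, FLAG_ROI, FeatureMatrix

FRACTIONS = (0.70, 0.15, 0.15)


@dataclass
class SplitIndices:
    """Disjoint, exhaustive train/validation/prediction row-index sets."""

    train: np.ndarray
    validation: np.ndarray
    prediction: np.ndarray
    fractions: tuple[float, float, float] = FRACTIONS

    def validate(self, n: int) -> None:
        parts = [self.train, self.validation, self.prediction]
        allidx = np.concatenate(parts)
        if allidx.size != n or np.unique(allidx).size != n:
            raise InputError("split is not a disjoint exhaustive partition")


def kennard_stone_order(X: np.ndarray) -> np.ndarray:
    """Kennard-Stone maximin ordering of the rows of ``X``.

    The first two elements are the pair at maximum pairwise Euclidean
    distance (lowest indices on ties); each later element maximizes its
    minimum distance to everything already selected (lowest index on
    ties).  Deterministic; no randomness.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise InputError("kennard_stone_order requires at least 2 samples")

    sq = np.sum(X * X, axis=1)
    D = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.maximum(D, 0.0, out=D)

    # Farthest pair; row-major argmax on the upper triangle gives the
    # lexicographically smallest (i, j) among ties.
    iu = np.triu_indices(n, k=1)
    k = int(np.argmax(D[iu]))
    i, j = int(iu[0][k]), int(iu[1][k])

    order = [i, j]
    selected = np.zeros(n, dtype=bool)
    selected[[i, j]] = True
    mind = np.minimum(D[:, i], D[:, j])
    for _ in range(n - 2):
        cand = np.where(~selected, mind, -np.inf)
        nxt = int(np.argmax(cand))  # first occurrence -> lowest index on ties
        order.append(nxt)
        selected[nxt] = True
        np.minimum(mind, D[:, nxt], out=mind)
    return np.array(order, dtype=int)


def _split_sizes(n: int) -> tuple[int, int, int]:
    n_val = int(np.floor(FRACTIONS[1] * n))
    n_pred = int(np.floor(FRACTIONS[2] * n))
    return n - n_val - n_pred, n_val, n_pred


def split_70_15_15(fm: FeatureMatrix, stratified: bool = True) -> SplitIndices:
    """Partition the cohort 70/15/15 by Kennard-Stone ordering.

    When ``stratified`` (default) the KS order is computed within each
    class; validation takes ``floor(0.15 n_c)`` samples per class, then
    prediction the next ``floor(0.15 n_c)``, and training the remainder
    — the KS-earliest (most design-spanning) samples.  Distances are
    computed on the matrix the models will see, so the input must be
    normalized and ROI-compressed.
    """
    missing = {FLAG_NORMALIZED, FLAG_ROI} - fm.flags
    if missing:
        raise InputError(f"split requires a matrix with flags {sorted(missing)}")

    groups: list[np.ndarray]
    if stratified:
        groups = []
        for level in fm.class_levels():
            idx = np.where(fm.labels == level)[0]
            if idx.size < 3:
                raise InputError(
                    f"class {level!r} has only {idx.size} samples (need >= 3)"
                )
            groups.append(idx)
    else:
        if fm.n_samples < 3:
            raise InputError("need at least 3 samples to split")
        groups = [np.arange(fm.n_samples)]

    train, val, pred = [], [], []
    for idx in groups:
        order = idx[kennard_stone_order(fm.X[idx])]
        n_tr, n_val, n_pred = _split_sizes(idx.size)
        train.append(order[:n_tr])
        val.append(order[n_tr : n_tr + n_val])
        pred.append(order[n_tr + n_val :])
    out = SplitIndices(
        train=np.sort(np.concatenate(train)),
        validation=np.sort(np.concatenate(val)),
        prediction=np.sort(np.concatenate(pred)),
    )
    out.validate(fm.n_samples)
    return out


def split_to_csv(split: SplitIndices, fm: FeatureMatrix, path: str | Path) -> None:
    """Audit table: one row per sample, ``sample_id,set``."""
    assignment = {}
    for name, idx in (
        ("train", split.train),
        ("validation", split.validation),
        ("prediction", split.prediction),
    ):
        for i in idx:
            assignment[int(i)] = name
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_id", "set"])
        for i, sid in enumerate(fm.sample_ids):
            writer.writerow([sid, assignment[i]])


def split_from_csv(path: str | Path, fm: FeatureMatrix) -> SplitIndices:
    sets: dict[str, list[int]] = {"train": [], "validation": [], "prediction": []}
    pos = {sid: i for i, sid in enumerate(fm.sample_ids)}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            sets[row["set"]].append(pos[row["sample_id"]])
    out = SplitIndices(
        train=np.sort(np.array(sets["train"], dtype=int)),
        validation=np.sort(np.array(sets["validation"], dtype=int)),
        prediction=np.sort(np.array(sets["prediction"], dtype=int)),
    )
    out.validate(fm.n_samples)
    return out
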