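"""Peak-list I/O and spectral pre-processing.

Direct-infusion spectra come off the instrument with per-sample m/z axes:
the same lipid appears at slightly different measured masses in different
samples.  Before any multivariate modelling the cohort must be bunched
into one rectangular matrix (samples x m/z features).  The steps, in the
order the pipeline enforces them, are:

1. :func:`build_common_axis` — agglomerative ppm merging of all observed
   m/z values into one common axis; each sample's intensities land in
   their merged column, zeros elsewhere.
2. :func:`normalize_rows` — scale every sample so its sum of squared
   intensities equals 1 (removes total-ion-current variation).
3. :func:`roi_select` — regions-of-interest compression: keep only the
   columns whose intensity rises above a fraction (default 3 %) of the
   maximum intensity of the normalized matrix.

:func:`difference_spectrum` then gives the classic two-class contrast
(mean control spectrum minus mean case spectrum) used to pick out the
discriminating lipids.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError, StateError
from .synthetic import MANIFEST_NAME, NILM, SIL, RawSpectrum

FLAG_NORMALIZED = "normalized"
FLAG_ROI = "roi_compressed"


@dataclass
class FeatureMatrix:
    """Samples x common-m/z-axis intensity table with labels.

    ``flags`` records which pre-processing stages have been applied
    (:data:`FLAG_NORMALIZED`, :data:`FLAG_ROI`); downstream stages check
    them so the pipeline cannot silently run out of order.
    """

    axis: np.ndarray                 # ascending m/z values, length p
    X: np.ndarray                    # (n, p) non-negative intensities
    labels: np.ndarray               # (n,) class labels
    sample_ids: np.ndarray           # (n,) identifiers
    flags: set[str] = field(default_factory=set)

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def validate(self) -> None:
        if self.axis.ndim != 1 or self.X.ndim != 2:
            raise InputError("axis must be 1-D and X 2-D")
        if self.X.shape[1] != self.axis.size:
            raise InputError("X column count != axis length")
        if not (self.X.shape[0] == self.labels.size == self.sample_ids.size):
            raise InputError("row count, labels and sample_ids disagree")
        if self.axis.size > 1 and not np.all(np.diff(self.axis) > 0):
            raise InputError("axis is not strictly increasing")

    def select_columns(self, idx: np.ndarray) -> "FeatureMatrix":
        return replace(
            self,
            axis=self.axis[idx],
            X=self.X[:, idx],
            flags=set(self.flags),
        )

    def class_levels(self) -> list[str]:
        return sorted(set(self.labels.tolist()))


@dataclass
class RoiReport:
    """Outcome of ROI compression: which columns survived and why."""

    kept_indices: np.ndarray
    threshold_value: float
    threshold_fraction: float


# ---------------------------------------------------------------------------
# Peak-list I/O


def read_peaklists(directory: str | Path) -> list[RawSpectrum]:
    """Read the manifest + per-sample CSV layout written by
    :func:`lipoclass.synthetic.write_peaklists`."""
    directory = Path(directory)
    manifest = directory / MANIFEST_NAME
    if not manifest.exists():
        raise InputError(f"no {MANIFEST_NAME} in {directory}")
    spectra: list[RawSpectrum] = []
    with open(manifest, newline="") as fh:
        for row in csv.DictReader(fh):
            data = np.loadtxt(
                directory / row["filename"], delimiter=",", ndmin=2, dtype=float
            )
            if data.size == 0:
                mz = np.empty(0)
                inten = np.empty(0)
            else:
                mz, inten = data[:, 0], data[:, 1]
            spec = RawSpectrum(
                sample_id=row["sample_id"], label=row["label"], mz=mz, intensity=inten
            )
            spec.validate()
            spectra.append(spec)
    return spectra


def read_msp(path: str | Path, label: str) -> list[RawSpectrum]:
    """Minimal MSP-style reader: ``Name:`` starts a record, ``Num Peaks:``
    is followed by whitespace- or semicolon-separated ``mz intensity``
    pairs.  All records receive the given class label."""
    spectra = []
    name = None
    peaks: list[tuple[float, float]] = []

    def flush():
        if name is not None:
            arr = np.array(sorted(peaks)) if peaks else np.empty((0, 2))
            spectra.append(
                RawSpectrum(
                    sample_id=name,
                    label=label,
                    mz=arr[:, 0] if arr.size else np.empty(0),
                    intensity=arr[:, 1] if arr.size else np.empty(0),
                )
            )

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            low = line.lower()
            if low.startswith("name:"):
                flush()
                name = line.split(":", 1)[1].strip()
                peaks = []
            elif ":" in line and not line[0].isdigit():
                continue
            else:
                vals = line.replace(";", " ").split()
                if len(vals) >= 2:
                    peaks.append((float(vals[0]), float(vals[1])))
    flush()
    return spectra


# ---------------------------------------------------------------------------
# Common axis


def build_common_axis(
    spectra: Sequence[RawSpectrum], merge_tol_ppm: float = 5.0
) -> FeatureMatrix:
    """Build the single m/z vector common to all samples.

    All observed m/z values are pooled, sorted, and agglomerated: a value
    joins the current cluster when its ppm gap to the cluster's running
    intensity-weighted mean is at most ``merge_tol_ppm``; the merged
    column position is the final intensity-weighted mean.  Each sample's
    intensity is placed at its merged column (summed if two of its own
    peaks merge), zero elsewhere.
    """
    if len(spectra) == 0:
        raise InputError("build_common_axis requires at least one spectrum")
    if merge_tol_ppm < 0:
        raise ConfigurationError("merge_tol_ppm must be >= 0")

    for s in spectra:
        s.validate()

    mz_all = np.concatenate([s.mz for s in spectra])
    int_all = np.concatenate([s.intensity for s in spectra])
    sample_idx = np.concatenate(
        [np.full(s.mz.size, i, dtype=int) for i, s in enumerate(spectra)]
    )
    order = np.argsort(mz_all, kind="stable")
    mz_all, int_all, sample_idx = mz_all[order], int_all[order], sample_idx[order]

    cluster_id = np.empty(mz_all.size, dtype=int)
    centers: list[float] = []
    cur_wsum = 0.0   # sum of weights (intensities) in current cluster
    cur_msum = 0.0   # weighted sum of m/z
    cur_cnt = 0
    cur_plain = 0.0  # unweighted sum, fallback when all intensities are 0
    cid = -1

    def center() -> float:
        return cur_msum / cur_wsum if cur_wsum > 0 else cur_plain / cur_cnt

    for k in range(mz_all.size):
        m, w = mz_all[k], int_all[k]
        if cid >= 0:
            c = center()
            if (m - c) <= c * merge_tol_ppm * 1e-6:
                cur_wsum += w
                cur_msum += w * m
                cur_cnt += 1
                cur_plain += m
                cluster_id[k] = cid
                continue
            centers.append(center())
        cid += 1
        cur_wsum, cur_msum, cur_cnt, cur_plain = w, w * m, 1, m
        cluster_id[k] = cid
    if cur_cnt:
        centers.append(center())

    axis = np.array(centers)
    n, p = len(spectra), axis.size
    X = np.zeros((n, p))
    np.add.at(X, (sample_idx, cluster_id), int_all)

    fm = FeatureMatrix(
        axis=axis,
        X=X,
        labels=np.array([s.label for s in spectra]),
        sample_ids=np.array([s.sample_id for s in spectra]),
        flags=set(),
    )
    fm.validate()
    return fm


# ---------------------------------------------------------------------------
# Normalization and ROI compression


def normalize_rows(fm: FeatureMatrix) -> FeatureMatrix:
    """Scale every row so its sum of squares equals 1 (idempotent)."""
    norms = np.linalg.norm(fm.X, axis=1)
    zero = np.where(norms == 0)[0]
    if zero.size:
        raise InputError(
            f"cannot normalize all-zero sample(s): {', '.join(fm.sample_ids[zero])}"
        )
    out = replace(fm, X=fm.X / norms[:, None], flags=fm.flags | {FLAG_NORMALIZED})
    return out


def roi_select(
    fm: FeatureMatrix,
    threshold_fraction: float = 0.03,
    per_sample: bool = False,
    allow_unnormalized: bool = False,
) -> tuple[FeatureMatrix, RoiReport]:
    """Regions-of-interest compression.

    Keeps exactly the columns whose maximum over samples is strictly
    higher than ``threshold_fraction`` times the global maximum intensity
    of the matrix (a column exactly at the threshold is dropped).  With
    ``per_sample=True`` the threshold is applied per row instead, and a
    column is kept when any sample exceeds its own row threshold.

    The matrix must be normalized first (the pipeline's fixed order);
    pass ``allow_unnormalized=True`` to override explicitly.
    """
    if not 0 < threshold_fraction < 1:
        raise ConfigurationError("threshold_fraction must be in (0, 1)")
    if FLAG_NORMALIZED not in fm.flags and not allow_unnormalized:
        raise StateError(
            "roi_select requires a normalized matrix (normalize_rows first); "
            "pass allow_unnormalized=True to override"
        )
    if per_sample:
        row_thr = threshold_fraction * fm.X.max(axis=1, keepdims=True)
        keep_mask = np.any(fm.X > row_thr, axis=0)
        threshold_value = float(threshold_fraction * fm.X.max())
    else:
        threshold_value = float(threshold_fraction * fm.X.max())
        keep_mask = fm.X.max(axis=0) > threshold_value
    kept = np.where(keep_mask)[0]
    out = fm.select_columns(kept)
    out.flags.add(FLAG_ROI)
    return out, RoiReport(
        kept_indices=kept,
        threshold_value=threshold_value,
        threshold_fraction=threshold_fraction,
    )


def difference_spectrum(
    fm: FeatureMatrix, minuend: str | None = None, subtrahend: str | None = None
) -> np.ndarray:
    """Mean spectrum contrast between the two classes.

    By default returns mean(NILM rows) - mean(SIL rows) per column, so a
    negative entry marks an m/z more intense in the SIL (positive) class.
    Requires a normalized, ROI-compressed matrix with exactly two label
    levels.
    """
    missing = {FLAG_NORMALIZED, FLAG_ROI} - fm.flags
    if missing:
        raise InputError(
            f"difference_spectrum requires flags {sorted(missing)} to be set"
        )
    levels = fm.class_levels()
    if len(levels) != 2:
        raise InputError(f"expected exactly 2 classes, found {len(levels)}")
    if minuend is None or subtrahend is None:
        if set(levels) == {NILM, SIL}:
            minuend, subtrahend = NILM, SIL
        else:
            minuend, subtrahend = levels
    if sorted([minuend, subtrahend]) != levels:
        raise InputError("minuend/subtrahend do not match the matrix labels")
    a = fm.X[fm.labels == minuend].mean(axis=0)
    b = fm.X[fm.labels == subtrahend].mean(axis=0)
    return a - b


# ---------------------------------------------------------------------------
# Tabular serialization


def feature_matrix_to_csv(fm: FeatureMatrix, path: str | Path) -> None:
    """Write the matrix as one CSV: sample_id, label, then one column per
    m/z value (header holds the m/z with 17 significant digits)."""
    df = pd.DataFrame(fm.X, columns=[f"{m:.17g}" for m in fm.axis])
    df.insert(0, "label", fm.labels)
    df.insert(0, "sample_id", fm.sample_ids)
    df.to_csv(path, index=False, float_format="%.17g")


def feature_matrix_from_csv(
    path: str | Path, flags: Iterable[str] = ()
) -> FeatureMatrix:
    df = pd.read_csv(path)
    axis = np.array([float(c) for c in df.columns[2:]])
    fm = FeatureMatrix(
        axis=axis,
        X=df.iloc[:, 2:].to_numpy(dtype=float),
        labels=df["label"].to_numpy(dtype=str),
        sample_ids=df["sample_id"].to_numpy(dtype=str),
        flags=set(flags),
    )
    fm.validate()
    return fm


def roi_report_to_csv(report: RoiReport, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["kept_index"])
        for i in report.kept_indices:
            writer.writerow([int(i)])
        writer.writerow([])
        writer.writerow(["threshold_value", f"{report.threshold_value:.17g}"])
        writer.writerow(["threshold_fraction", f"{report.threshold_fraction:.17g}"])
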