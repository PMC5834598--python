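"""Model evaluation: confusion counts, sensitivity/specificity, F-score,
ROC/AUC, and the per-model report table.

SIL (the lesion class) is the positive class throughout:

    Sensitivity(%) = TP / (TP + FN) * 100
    Specificity(%) = TN / (TN + FP) * 100
    F-score        = 2 * SENS * SPEC / (SENS + SPEC)   (on the percent
                     scale, reported divided by 100)

Note this F-score is the harmonic mean of sensitivity and specificity —
the convention of the clinical chemometrics literature — not the
precision-recall F1.  AUC is the trapezoidal area under the empirical
ROC curve, which (with ties counted 1/2) equals the Mann-Whitney
probability that a random positive scores above a random negative.

Metrics with a zero denominator raise
:class:`~lipoclass.errors.UndefinedMetricError` rather than silently
returning 0; the report writer turns those into annotated NA cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import ConvergenceError, InputError, UndefinedMetricError
from .synthetic import NILM, SIL


@dataclass
class ConfusionCounts:
    """Two-class confusion counts with SIL as the positive class."""

    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def confusion(
    y_true: Sequence[str],
    y_pred: Sequence[str],
    positive: str = SIL,
    negative: str = NILM,
) -> ConfusionCounts:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise InputError("y_true and y_pred differ in length")
    valid = {positive, negative}
    unknown = (set(y_true.tolist()) | set(y_pred.tolist())) - valid
    if unknown:
        raise InputError(f"unknown label(s): {sorted(unknown)}")
    tp = int(np.sum((y_true == positive) & (y_pred == positive)))
    tn = int(np.sum((y_true == negative) & (y_pred == negative)))
    fp = int(np.sum((y_true == negative) & (y_pred == positive)))
    fn = int(np.sum((y_true == positive) & (y_pred == negative)))
    return ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn)


def sensitivity(cc: ConfusionCounts) -> float:
    """TP / (TP + FN) as a percentage."""
    if cc.TP + cc.FN == 0:
        raise UndefinedMetricError("sensitivity undefined: no positive samples")
    return 100.0 * cc.TP / (cc.TP + cc.FN)


def specificity(cc: ConfusionCounts) -> float:
    """TN / (TN + FP) as a percentage."""
    if cc.TN + cc.FP == 0:
        raise UndefinedMetricError("specificity undefined: no negative samples")
    return 100.0 * cc.TN / (cc.TN + cc.FP)


def f_score(sens_percent: float, spec_percent: float) -> float:
    """Harmonic mean of sensitivity and specificity, on the 0-1 scale.

    Evaluated on the percent scale then divided by 100; (0, 0) is 0 by
    continuity.
    """
    if sens_percent < 0 or spec_percent < 0:
        raise InputError("sensitivity/specificity must be non-negative")
    if sens_percent + spec_percent == 0:
        return 0.0
    return (2.0 * sens_percent * spec_percent / (sens_percent + spec_percent)) / 100.0


def roc_curve(
    scores: np.ndarray, y_true: Sequence[str], positive: str = SIL
) -> tuple[np.ndarray, np.ndarray]:
    """Empirical ROC (FPR, TPR), thresholds descending, ties grouped."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y_true) == positive
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("ROC undefined: only one class present")
    order = np.argsort(-scores, kind="stable")
    y_sorted = y[order]
    s_sorted = scores[order]
    tps = np.cumsum(y_sorted)
    fps = np.cumsum(~y_sorted)
    # Keep only the last point of each tied-score block.
    last = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    tpr = np.r_[0.0, tps[last] / n_pos]
    fpr = np.r_[0.0, fps[last] / n_neg]
    return fpr, tpr


def roc_auc(scores: np.ndarray, y_true: Sequence[str], positive: str = SIL) -> float:
    """Trapezoidal area under the empirical ROC curve.

    Larger scores must mean "more positive-like".  Equals the
    Mann-Whitney estimate P(score+ > score-) with ties counted 1/2.
    """
    fpr, tpr = roc_curve(scores, y_true, positive)
    return float(np.trapezoid(tpr, fpr))


# ---------------------------------------------------------------------------
# Report


@dataclass
class ModelEvaluation:
    """One report row; None marks a metric that could not be computed."""

    name: str
    sensitivity: float | None
    specificity: float | None
    auc: float | None
    f_score: float | None
    note: str = ""


@dataclass
class EvaluationReport:
    """Machine twin of the published evaluation tables: one row per
    model with prediction-set sensitivity, specificity, AUC, F-score."""

    rows: list[ModelEvaluation]
    dataset: str = ""
    split: str = "prediction"

    def to_frame(self) -> pd.DataFrame:
        def fmt_pct(v):
            return round(v, 1) if v is not None else None

        def fmt3(v):
            return round(v, 3) if v is not None else None

        return pd.DataFrame(
            {
                "model": [r.name for r in self.rows],
                "sensitivity_pct": [fmt_pct(r.sensitivity) for r in self.rows],
                "specificity_pct": [fmt_pct(r.specificity) for r in self.rows],
                "auc": [fmt3(r.auc) for r in self.rows],
                "f_score": [fmt3(r.f_score) for r in self.rows],
                "note": [r.note for r in self.rows],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, na_rep="NA")


def evaluate_model(
    name: str,
    y_true: Sequence[str],
    y_pred: Sequence[str],
    scores: np.ndarray | None,
    positive: str = SIL,
    negative: str = NILM,
) -> ModelEvaluation:
    """Evaluate one model's hard predictions plus (optional) raw scores;
    undefined metrics become None cells with a note."""
    notes = []
    cc = confusion(y_true, y_pred, positive, negative)
    try:
        sens: float | None = sensitivity(cc)
    except UndefinedMetricError as exc:
        sens, notes = None, notes + [str(exc)]
    try:
        spec: float | None = specificity(cc)
    except UndefinedMetricError as exc:
        spec, notes = None, notes + [str(exc)]
    auc: float | None = None
    if scores is not None:
        try:
            auc = roc_auc(scores, y_true, positive)
        except UndefinedMetricError as exc:
            notes.append(str(exc))
    fs = f_score(sens, spec) if sens is not None and spec is not None else None
    return ModelEvaluation(
        name=name,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        f_score=fs,
        note="; ".join(notes),
    )


def build_report(
    models: Sequence[
        tuple[str, Callable[[np.ndarray], np.ndarray], Callable[[np.ndarray], np.ndarray] | None]
    ],
    X_pred: np.ndarray,
    y_pred_true: Sequence[str],
    dataset: str = "",
) -> EvaluationReport:
    """Evaluate every (name, predict_fn, score_fn) triple on the held-out
    prediction samples.

    ``predict_fn`` maps a feature matrix to class labels; ``score_fn``
    (may be None) maps it to raw scores oriented so larger = more
    SIL-like (discriminant score differences, SVM pre-sign f, KNN vote
    fraction).  A model whose training or scoring failed to converge is
    reported as an NA row rather than aborting the report.
    """
    rows = []
    for name, predict_fn, score_fn in models:
        try:
            y_hat = predict_fn(X_pred)
            s = score_fn(X_pred) if score_fn is not None else None
            rows.append(evaluate_model(name, y_pred_true, y_hat, s))
        except ConvergenceError as exc:
            rows.append(
                ModelEvaluation(
                    name=name,
                    sensitivity=None,
                    specificity=None,
                    auc=None,
                    f_score=None,
                    note=f"did not converge: {exc}",
                )
            )
    return EvaluationReport(rows=rows, dataset=dataset)
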