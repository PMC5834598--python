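"""End-to-end orchestration: simulate -> preprocess -> split -> reduce ->
train -> evaluate -> annotate.

Every stage is a plain function over a *run directory*: it reads the
artifacts earlier stages wrote and writes its own as plain text (CSV /
JSON), so a run can be resumed stage by stage and the monolithic
:func:`run` is literally the composition of the stage functions.  All
randomness (synthetic cohort, GA restarts) flows from one root seed via
named substreams recorded in the run log; identical config + seed gives
byte-identical artifacts.

Stage order is fixed: common axis -> normalize -> ROI -> split ->
reduce (PCA and/or GA on training data) -> train -> evaluate on the
held-out prediction set -> annotate the difference spectrum.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import annotation as anno
from .classifiers import (
    DiscriminantModel,
    KernelSpec,
    SvmModel,
    discriminant_classify,
    discriminant_from_dict,
    discriminant_roc_score,
    discriminant_to_dict,
    fit_discriminant,
    knn_classify,
    knn_select_k,
    svm_classify,
    svm_decision,
    svm_from_dict,
    svm_to_dict,
    svm_train,
)
from .errors import ConfigurationError, ConvergenceError, LipoclassError
from .evaluation import EvaluationReport, ModelEvaluation, evaluate_model
from .preprocess import (
    FLAG_NORMALIZED,
    FLAG_ROI,
    FeatureMatrix,
    build_common_axis,
    difference_spectrum,
    feature_matrix_from_csv,
    feature_matrix_to_csv,
    normalize_rows,
    read_peaklists,
    roi_report_to_csv,
    roi_select,
)
from .reduction import (
    GAConfig,
    ga_result_to_csv,
    ga_select,
    pca_fit,
    pca_model_from_json,
    pca_model_to_json,
    pca_scores,
)
from .split import split_70_15_15, split_from_csv, split_to_csv
from .synthetic import NILM, SIL, CohortConfig, generate_cohort, write_peaklists

#: The model grid of the study: discriminant and KNN rows, the five-kernel
#: SVM rows on PCA scores and GA variables, and SVM-RBF on the full matrix.
DEFAULT_MODELS: tuple[str, ...] = (
    "PCA-LDA",
    "GA-LDA",
    "PCA-QDA",
    "GA-QDA",
    "KNN",
    "PCA-SVM-L",
    "PCA-SVM-Q",
    "PCA-SVM-P",
    "PCA-SVM-RBF",
    "PCA-SVM-MLP",
    "GA-SVM-L",
    "GA-SVM-Q",
    "GA-SVM-P",
    "GA-SVM-RBF",
    "GA-SVM-MLP",
    "SVM-RBF",
)

_KERNEL_BY_LETTER = {
    "L": "linear",
    "Q": "quadratic",
    "P": "poly3",
    "RBF": "rbf",
    "MLP": "mlp",
}

SPLIT_FRACTIONS = (0.70, 0.15, 0.15)


@dataclass
class RunConfig:
    """Configuration of one end-to-end run.

    Exactly one input source: a synthetic :class:`CohortConfig` (its seed
    is overridden by the run's root seed substream) or a directory of
    peak-list CSVs with a manifest.
    """

    cohort: CohortConfig | None = field(default_factory=CohortConfig)
    peaklist_dir: str | None = None
    merge_tol_ppm: float = 5.0
    roi_fraction: float = 0.03
    stratified: bool = True
    pca_k: int = 10
    ga: GAConfig = field(default_factory=GAConfig)
    models: tuple[str, ...] = DEFAULT_MODELS
    svm_C: float | None = None          # None -> validation grid
    svm_gamma: float | None = None      # None -> validation grid (RBF)
    svm_C_grid: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0)
    svm_gamma_grid: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0, 100.0)
    knn_k_grid: tuple[int, ...] = (1, 3, 5, 7, 9)
    annotation_top_n: int = 5
    annotation_tol_ppm: float = 10.0
    reference_table: str | None = None  # None -> packaged table
    equal_priors: bool = False
    seed: int = 0

    def validate(self) -> None:
        if (self.cohort is None) == (self.peaklist_dir is None):
            raise ConfigurationError(
                "exactly one input source: cohort or peaklist_dir"
            )
        if abs(sum(SPLIT_FRACTIONS) - 1.0) > 1e-9:
            raise ConfigurationError("split fractions must sum to 1")
        for name in self.models:
            _parse_model_name(name)


def _parse_model_name(name: str) -> tuple[str | None, str, str | None]:
    """Model name -> (feature mode, classifier, kernel name)."""
    parts = name.split("-")
    if name == "KNN":
        return None, "KNN", None
    if parts[0] in ("PCA", "GA"):
        mode, rest = parts[0], parts[1:]
    else:
        mode, rest = None, parts
    if rest and rest[0] in ("LDA", "QDA") and len(rest) == 1:
        return mode, rest[0], None
    if rest and rest[0] == "SVM" and len(rest) == 2 and rest[1] in _KERNEL_BY_LETTER:
        return mode, "SVM", _KERNEL_BY_LETTER[rest[1]]
    raise ConfigurationError(f"cannot parse model name {name!r}")


def derive_seeds(root_seed: int) -> dict[str, int]:
    """Named substream seeds (all below 2**31) from the root seed."""
    ss = np.random.SeedSequence(root_seed)
    children = ss.spawn(2)
    return {
        "synthetic": int(children[0].generate_state(1)[0] % (2**31)),
        "ga": int(children[1].generate_state(1)[0] % (2**31)),
    }


class PipelineStageError(LipoclassError):
    """Wraps any stage failure with the stage name, so a failed run halts
    with a machine-readable record of where."""

    def __init__(self, stage: str, error: Exception):
        super().__init__(f"stage {stage!r} failed: {error}")
        self.stage = stage
        self.error = error


def _log(rundir: Path, record: dict) -> None:
    with open(rundir / "run_log.jsonl", "a") as fh:
        fh.write(json.dumps(record) + "\n")


# ---------------------------------------------------------------------------
# Stages


def stage_simulate(config: RunConfig, rundir: Path) -> None:
    seeds = derive_seeds(config.seed)
    cohort = dataclasses.replace(config.cohort, seed=seeds["synthetic"])
    spectra = generate_cohort(cohort)
    write_peaklists(spectra, rundir / "peaklists")
    _log(
        rundir,
        {
            "stage": "simulate",
            "root_seed": config.seed,
            "synthetic_seed": seeds["synthetic"],
            "n_samples": len(spectra),
        },
    )


def stage_preprocess(config: RunConfig, rundir: Path) -> None:
    src = Path(config.peaklist_dir) if config.peaklist_dir else rundir / "peaklists"
    spectra = read_peaklists(src)
    fm = build_common_axis(spectra, merge_tol_ppm=config.merge_tol_ppm)
    n_full = fm.n_features
    fm = normalize_rows(fm)
    fm, report = roi_select(fm, threshold_fraction=config.roi_fraction)
    feature_matrix_to_csv(fm, rundir / "features.csv")
    (rundir / "features_flags.json").write_text(json.dumps(sorted(fm.flags)))
    roi_report_to_csv(report, rundir / "roi_report.csv")
    _log(
        rundir,
        {
            "stage": "preprocess",
            "n_samples": fm.n_samples,
            "n_features_full": n_full,
            "n_features_roi": fm.n_features,
            "roi_threshold": report.threshold_value,
        },
    )


def _load_features(rundir: Path) -> FeatureMatrix:
    flags = set(json.loads((rundir / "features_flags.json").read_text()))
    return feature_matrix_from_csv(rundir / "features.csv", flags=flags)


def stage_split(config: RunConfig, rundir: Path) -> None:
    fm = _load_features(rundir)
    split = split_70_15_15(fm, stratified=config.stratified)
    split_to_csv(split, fm, rundir / "split.csv")
    _log(
        rundir,
        {
            "stage": "split",
            "stratified": config.stratified,
            "sizes": [
                int(split.train.size),
                int(split.validation.size),
                int(split.prediction.size),
            ],
        },
    )


def stage_reduce(config: RunConfig, rundir: Path) -> None:
    fm = _load_features(rundir)
    split = split_from_csv(rundir / "split.csv", fm)
    modes = {_parse_model_name(m)[0] for m in config.models}
    record: dict = {"stage": "reduce"}
    if "PCA" in modes:
        model = pca_fit(fm.X[split.train], k=config.pca_k)
        pca_model_to_json(model, rundir / "pca_model.json")
        record["pca_k"] = config.pca_k
        record["pca_explained_variance_fraction"] = [
            round(float(v), 6) for v in model.explained_variance_fraction
        ]
    if "GA" in modes:
        seeds = derive_seeds(config.seed)
        ga_cfg = dataclasses.replace(config.ga, seed=seeds["ga"])
        result = ga_select(
            fm.X[split.train],
            fm.labels[split.train],
            fm.X[split.validation],
            fm.labels[split.validation],
            ga_cfg,
        )
        ga_result_to_csv(result, fm.axis, rundir / "ga_selected.csv")
        record["ga_seed"] = seeds["ga"]
        record["ga_n_selected"] = int(result.selected.size)
        record["ga_best_fitness"] = float(result.best_fitness)
    _log(rundir, record)


def _load_ga_selected(rundir: Path) -> np.ndarray:
    idx = []
    for line in (rundir / "ga_selected.csv").read_text().splitlines()[1:]:
        if line.startswith("#") or not line.strip():
            continue
        idx.append(int(line.split(",")[0]))
    return np.array(idx, dtype=int)


def _positive_negative(fm: FeatureMatrix) -> tuple[str, str]:
    levels = fm.class_levels()
    if set(levels) == {NILM, SIL}:
        return SIL, NILM
    return levels[-1], levels[0]


def _transform(mode, fm, rundir):
    if mode == "PCA":
        model = pca_model_from_json(rundir / "pca_model.json")
        return lambda X: pca_scores(model, X)
    if mode == "GA":
        sel = _load_ga_selected(rundir)
        return lambda X: X[:, sel]
    return lambda X: X


def _balanced_accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    levels = sorted(set(y_true.tolist()))
    return float(
        np.mean([np.mean(y_pred[y_true == c] == c) for c in levels])
    )


def _fit_svm_with_grid(
    config: RunConfig,
    kernel_name: str,
    Xt: np.ndarray,
    yt_signed: np.ndarray,
    Xv: np.ndarray,
    yv_signed: np.ndarray,
) -> tuple[SvmModel, float, float | None]:
    """Fit an SVM, choosing C (and gamma for RBF) on the validation set by
    balanced accuracy when not pinned in the config.  Grid order is fixed,
    ties keep the first (smallest) values."""
    C_grid = [config.svm_C] if config.svm_C is not None else list(config.svm_C_grid)
    if kernel_name == "rbf":
        g_grid = (
            [config.svm_gamma]
            if config.svm_gamma is not None
            else list(config.svm_gamma_grid)
        )
    else:
        g_grid = [None]
    best = None
    for C in C_grid:
        for gamma in g_grid:
            spec = KernelSpec(name=kernel_name, gamma=gamma)
            try:
                model = svm_train(Xt, yt_signed, spec, C=C)
            except ConvergenceError:
                continue
            pred = svm_classify(model, Xv)
            acc = _balanced_accuracy(yv_signed, pred)
            if best is None or acc > best[0]:
                best = (acc, model, C, gamma)
    if best is None:
        # Every grid point failed; retrain once at defaults to surface the
        # ConvergenceError to the caller.
        spec = KernelSpec(name=kernel_name, gamma=g_grid[0])
        model = svm_train(Xt, yt_signed, spec, C=C_grid[0])
        return model, C_grid[0], g_grid[0]
    return best[1], best[2], best[3]


def stage_train(config: RunConfig, rundir: Path) -> None:
    fm = _load_features(rundir)
    split = split_from_csv(rundir / "split.csv", fm)
    positive, negative = _positive_negative(fm)

    models_out: dict[str, dict] = {}
    for name in config.models:
        mode, clf, kernel_name = _parse_model_name(name)
        tf = _transform(mode, fm, rundir)
        Xt = tf(fm.X[split.train])
        yt = fm.labels[split.train]
        entry: dict = {"features": mode or "none", "classifier": clf}
        if clf in ("LDA", "QDA"):
            model = fit_discriminant(clf, Xt, yt, equal_priors=config.equal_priors)
            entry["type"] = "discriminant"
            entry["model"] = discriminant_to_dict(model)
        elif clf == "SVM":
            Xv = tf(fm.X[split.validation])
            yv = fm.labels[split.validation]
            yt_signed = np.where(yt == positive, 1.0, -1.0)
            yv_signed = np.where(yv == positive, 1.0, -1.0)
            try:
                model, C, gamma = _fit_svm_with_grid(
                    config, kernel_name, Xt, yt_signed, Xv, yv_signed
                )
                entry["type"] = "svm"
                entry["model"] = svm_to_dict(model)
                entry["selected_C"] = C
                entry["selected_gamma"] = gamma
            except ConvergenceError as exc:
                entry["type"] = "svm"
                entry["error"] = str(exc)
        else:  # KNN on the whole ROI matrix
            Xv = tf(fm.X[split.validation])
            k = knn_select_k(
                Xt, yt, Xv, fm.labels[split.validation], config.knn_k_grid
            )
            entry["type"] = "knn"
            entry["k"] = k
        models_out[name] = entry
    (rundir / "models.json").write_text(json.dumps(models_out))
    _log(
        rundir,
        {
            "stage": "train",
            "models": list(config.models),
            "knn_k": models_out.get("KNN", {}).get("k"),
        },
    )


def stage_evaluate(config: RunConfig, rundir: Path) -> EvaluationReport:
    fm = _load_features(rundir)
    split = split_from_csv(rundir / "split.csv", fm)
    positive, negative = _positive_negative(fm)
    models = json.loads((rundir / "models.json").read_text())

    X_pred_full = fm.X[split.prediction]
    y_true = fm.labels[split.prediction]
    rows = []
    for name, entry in models.items():
        mode = None if entry["features"] == "none" else entry["features"]
        tf = _transform(mode, fm, rundir)
        Xp = tf(X_pred_full)
        if "error" in entry:
            rows.append(
                ModelEvaluation(
                    name=name,
                    sensitivity=None,
                    specificity=None,
                    auc=None,
                    f_score=None,
                    note=f"did not converge: {entry['error']}",
                )
            )
            continue
        if entry["type"] == "discriminant":
            model = discriminant_from_dict(entry["model"])
            y_hat = discriminant_classify(model, Xp)
            scores = discriminant_roc_score(model, Xp, positive)
        elif entry["type"] == "svm":
            model = svm_from_dict(entry["model"])
            signed = svm_classify(model, Xp)
            y_hat = np.where(signed > 0, positive, negative)
            scores = svm_decision(model, Xp)
        else:
            Xt = tf(fm.X[split.train])
            y_hat, frac = knn_classify(
                Xt, fm.labels[split.train], Xp, entry["k"], positive=positive
            )
            scores = frac
        rows.append(
            evaluate_model(name, y_true, y_hat, scores, positive, negative)
        )
    report = EvaluationReport(rows=rows, dataset=str(rundir))
    report.to_csv(rundir / "report.csv")
    _log(rundir, {"stage": "evaluate", "n_models": len(rows)})
    return report


def stage_annotate(config: RunConfig, rundir: Path) -> None:
    fm = _load_features(rundir)
    diff = difference_spectrum(fm)
    ranked = anno.rank_discriminant_features(
        fm.axis, diff, top_n=config.annotation_top_n
    )
    reference = anno.load_reference_table(config.reference_table)
    records, unmatched = anno.match_reference(
        ranked, reference, tol_ppm=config.annotation_tol_ppm
    )
    anno.annotation_to_csv(records, unmatched, rundir / "annotation.csv")
    _log(
        rundir,
        {
            "stage": "annotate",
            "n_ranked": len(ranked),
            "n_matched": len(records),
            "n_unmatched": len(unmatched),
        },
    )


# ---------------------------------------------------------------------------
# Monolithic run


def run(config: RunConfig, outdir: str | Path) -> Path:
    """Execute the whole pipeline into ``outdir`` and return it.

    Any stage failure halts the run with :class:`PipelineStageError`
    (stage name + original error) after writing an error record to the
    run log.
    """
    config.validate()
    rundir = Path(outdir)
    rundir.mkdir(parents=True, exist_ok=True)
    log = rundir / "run_log.jsonl"
    if log.exists():
        log.unlink()

    stages = []
    if config.cohort is not None:
        stages.append(("simulate", stage_simulate))
    stages += [
        ("preprocess", stage_preprocess),
        ("split", stage_split),
        ("reduce", stage_reduce),
        ("train", stage_train),
        ("evaluate", stage_evaluate),
        ("annotate", stage_annotate),
    ]
    for stage_name, fn in stages:
        try:
            fn(config, rundir)
        except Exception as exc:
            _log(rundir, {"stage": stage_name, "error": str(exc)})
            raise PipelineStageError(stage_name, exc) from exc
    return rundir
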