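"""Shared fixtures: small synthetic cohorts and preprocessed matrices.

Everything is generated programmatically at test time; session scope
keeps the default 76-sample cohort to a single build.
"""

import numpy as np
import pytest

from lipoclass.preprocess import build_common_axis, normalize_rows, roi_select
from lipoclass.split import split_70_15_15
from lipoclass.synthetic import CohortConfig, Marker, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The study-sized cohort: 42 NILM + 34 SIL, five markers at fold 5."""
    return generate_cohort(CohortConfig(seed=7))


@pytest.fixture(scope="session")
def roi_matrix(default_cohort):
    """Default cohort after common axis, normalization and ROI compression."""
    fm = normalize_rows(build_common_axis(default_cohort))
    fm, _ = roi_select(fm)
    return fm


@pytest.fixture(scope="session")
def default_split(roi_matrix):
    return split_70_15_15(roi_matrix)


@pytest.fixture(scope="session")
def planted_cohort_matrix():
    """Cohort where 2 of ~50 variables carry all class separation (fold 10):
    48 shared background peaks plus two markers, no decoy noise."""
    cfg = CohortConfig(
        n_background_peaks=48,
        n_noise_peaks=0,
        marker_table=[Marker(331.177, "SIL", 10.0), Marker(369.227, "NILM", 10.0)],
        seed=11,
    )
    fm = normalize_rows(build_common_axis(generate_cohort(cfg)))
    fm, _ = roi_select(fm)
    split = split_70_15_15(fm)
    marker_cols = (
        int(np.argmin(np.abs(fm.axis - 331.177))),
        int(np.argmin(np.abs(fm.axis - 369.227))),
    )
    return fm, split, marker_cols


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def run_pca_svm_rbf(seed: int, effect_size: float, tmpdir) -> tuple[float, float, float]:
    """Full-pipeline helper: default cohort at the given marker fold-change,
    PCA-SVM-RBF only; returns prediction-set (sensitivity%, specificity%, AUC)."""
    import pandas as pd

    from lipoclass.pipeline import RunConfig, run
    from lipoclass.synthetic import DEFAULT_MARKERS

    markers = [Marker(mz, up, effect_size) for mz, up, _ in DEFAULT_MARKERS]
    cfg = RunConfig(
        cohort=CohortConfig(marker_table=markers),
        models=("PCA-SVM-RBF",),
        seed=seed,
    )
    rundir = run(cfg, tmpdir)
    row = pd.read_csv(rundir / "report.csv").iloc[0]
    return (
        float(row["sensitivity_pct"]),
        float(row["specificity_pct"]),
        float(row["auc"]),
    )
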