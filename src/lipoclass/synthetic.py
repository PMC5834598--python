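"""Synthetic direct-infusion ESI-like centroid spectra.

The study system is a cohort of blood-plasma lipid extracts measured by
direct infusion on a high-resolution instrument in positive mode over
m/z 200-1200: one centroided spectrum per sample, each with its own
irregular m/z axis.  This module simulates such cohorts with a known
ground truth so that the downstream chemometric pipeline (common-axis
construction, normalization, ROI compression, splitting, feature
reduction, classification) can be exercised and validated end to end.

Model
-----
* A set of *background* lipid peaks shared by both classes.  Positions are
  drawn once per cohort, uniformly over the m/z range (optionally with a
  configurable density weighting toward low m/z, where real plasma lipid
  spectra concentrate most of their signal); mean intensities are drawn
  from a heavy-tailed log-uniform distribution.
* A small table of *marker* peaks whose mean intensity differs between the
  two classes by a fold-change (``effect_size``); the default markers sit
  at the five m/z positions that discriminate NILM from SIL plasma
  (331.177 and 397.258 up in SIL; 369.227, 680.450 and 780.526 up in NILM).
* Per sample, every peak position is jittered by Gaussian ppm noise (no
  two samples share an axis) and every intensity is multiplied by a
  log-normal factor with unit mean and configurable CV.
* A *noise floor* of low-intensity decoy peaks at random positions, below
  the eventual ROI threshold, exercises the compression step.

Everything is driven by one integer seed and is bit-reproducible.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, InputError

NILM = "NILM"
SIL = "SIL"

#: Discriminant marker positions (Th), their up-regulated class and the
#: default fold-change between class-conditional mean intensities.
DEFAULT_MARKERS: tuple[tuple[float, str, float], ...] = (
    (331.177, SIL, 5.0),
    (369.227, NILM, 5.0),
    (397.258, SIL, 5.0),
    (680.450, NILM, 5.0),
    (780.526, NILM, 5.0),
)

#: Mean intensity of a marker peak in its *down* class, on the arbitrary
#: intensity scale where background peak means are log-uniform in
#: [0.005, 1].  Mid-scale, so markers are neither the base peak nor lost
#: in the noise floor.
MARKER_BASE_INTENSITY = 0.3


@dataclass(frozen=True)
class Marker:
    """One class-differential peak: position, favoured class, fold-change."""

    mz: float
    up_class: str
    effect_size: float


@dataclass
class CohortConfig:
    """Parameters of a simulated two-class cohort.

    Defaults reproduce the study design: 42 NILM (control) and 34 SIL
    (lesion) plasma samples, positive-mode spectra over m/z 200-1200,
    five marker lipids at fold-change 5, ~2 ppm mass jitter (consistent
    with sub-2-ppm accuracy at 140k resolving power), 30 % multiplicative
    intensity CV, and a 2 % decoy noise floor.
    """

    n_class_a: int = 42                      # NILM samples
    n_class_b: int = 34                      # SIL samples
    mz_range: tuple[float, float] = (200.0, 1200.0)
    n_background_peaks: int = 300
    marker_table: Sequence[Marker] = field(
        default_factory=lambda: [Marker(*m) for m in DEFAULT_MARKERS]
    )
    mz_jitter_ppm: float = 2.0
    intensity_cv: float = 0.3
    noise_floor: float = 0.02                # fraction of the max mean peak
    n_noise_peaks: int = 200                 # decoy peaks per sample
    low_mz_weight: float = 0.0               # 0 = uniform positions;
    # > 0 biases background positions toward low m/z with density
    # proportional to exp(-w * (mz - lo)/(hi - lo)).
    seed: int = 0
    label_a: str = NILM
    label_b: str = SIL

    def validate(self) -> None:
        if self.n_class_a < 1:
            raise ConfigurationError("n_class_a must be >= 1")
        if self.n_class_b < 1:
            raise ConfigurationError("n_class_b must be >= 1")
        lo, hi = self.mz_range
        if not lo < hi:
            raise ConfigurationError("mz_range lower bound must be < upper bound")
        if self.n_background_peaks < 0:
            raise ConfigurationError("n_background_peaks must be >= 0")
        if self.mz_jitter_ppm < 0:
            raise ConfigurationError("mz_jitter_ppm must be >= 0")
        if self.intensity_cv < 0:
            raise ConfigurationError("intensity_cv must be >= 0")
        if not 0 <= self.noise_floor < 1:
            raise ConfigurationError("noise_floor must be in [0, 1)")
        if self.n_noise_peaks < 0:
            raise ConfigurationError("n_noise_peaks must be >= 0")
        for m in self.marker_table:
            if m.effect_size <= 0:
                raise ConfigurationError(
                    f"effect_size must be > 0 (marker at m/z {m.mz})"
                )
            if m.up_class not in (self.label_a, self.label_b):
                raise ConfigurationError(
                    f"up_class {m.up_class!r} is not a cohort label"
                )
            if not lo <= m.mz <= hi:
                raise ConfigurationError(
                    f"marker m/z {m.mz} outside mz_range"
                )


@dataclass
class RawSpectrum:
    """One sample's centroid peak list with its class label.

    ``mz`` is strictly increasing; ``intensity`` is non-negative and of
    the same length.
    """

    sample_id: str
    label: str
    mz: np.ndarray
    intensity: np.ndarray

    def validate(self) -> None:
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise InputError(f"{self.sample_id}: mz/intensity shape mismatch")
        if self.mz.size and not np.all(np.diff(self.mz) > 0):
            raise InputError(f"{self.sample_id}: mz not strictly increasing")
        if np.any(self.intensity < 0):
            raise InputError(f"{self.sample_id}: negative intensity")


def _lognormal_factors(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Multiplicative log-normal noise with unit mean and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma2 = math.log(1.0 + cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=size)


def _background_positions(
    rng: np.random.Generator, cfg: CohortConfig
) -> np.ndarray:
    lo, hi = cfg.mz_range
    if cfg.low_mz_weight <= 0:
        return rng.uniform(lo, hi, cfg.n_background_peaks)
    # Inverse-CDF sampling of density exp(-w u) on u in [0, 1].
    w = cfg.low_mz_weight
    u = rng.uniform(0.0, 1.0, cfg.n_background_peaks)
    x = -np.log1p(-u * (1.0 - math.exp(-w))) / w
    return lo + x * (hi - lo)


def generate_cohort(config: CohortConfig) -> list[RawSpectrum]:
    """Simulate one cohort of centroid spectra.

    Returns ``n_class_a + n_class_b`` spectra, class-A samples first.
    Each sample's axis is independently jittered so no two samples share
    an identical axis; a marker's mean intensity in its up-class is
    ``effect_size`` times its mean in the other class.  Fully
    reproducible from ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    lo, hi = config.mz_range

    bg_mz = np.sort(_background_positions(rng, config))
    # Heavy-tailed mean intensities: log-uniform over [0.005, 1].
    bg_mean = 10.0 ** rng.uniform(math.log10(0.005), 0.0, config.n_background_peaks)

    marker_mz = np.array([m.mz for m in config.marker_table])
    n_markers = marker_mz.size

    all_means = np.concatenate([bg_mean, np.full(n_markers, MARKER_BASE_INTENSITY)])
    ref_max = float(all_means.max()) if all_means.size else 1.0

    labels = [config.label_a] * config.n_class_a + [config.label_b] * config.n_class_b
    n_total = len(labels)
    width = max(3, len(str(n_total)))

    spectra: list[RawSpectrum] = []
    for i, label in enumerate(labels):
        marker_mean = np.array(
            [
                MARKER_BASE_INTENSITY
                * (m.effect_size if m.up_class == label else 1.0)
                for m in config.marker_table
            ]
        )
        mz = np.concatenate([bg_mz, marker_mz])
        mean = np.concatenate([bg_mean, marker_mean])
        inten = mean * _lognormal_factors(rng, config.intensity_cv, mz.size)

        if config.n_noise_peaks:
            noise_mz = rng.uniform(lo, hi, config.n_noise_peaks)
            noise_int = rng.uniform(
                0.0, config.noise_floor * ref_max, config.n_noise_peaks
            )
            mz = np.concatenate([mz, noise_mz])
            inten = np.concatenate([inten, noise_int])

        if config.mz_jitter_ppm > 0:
            mz = mz * (
                1.0 + rng.normal(0.0, config.mz_jitter_ppm * 1e-6, mz.size)
            )
        np.clip(mz, lo, hi, out=mz)

        order = np.argsort(mz, kind="stable")
        mz, inten = mz[order], inten[order]
        # Exact duplicate positions (vanishingly rare) are summed so the
        # axis stays strictly increasing.
        if mz.size and np.any(np.diff(mz) == 0):
            uniq, inv = np.unique(mz, return_inverse=True)
            summed = np.zeros_like(uniq)
            np.add.at(summed, inv, inten)
            mz, inten = uniq, summed

        spec = RawSpectrum(
            sample_id=f"S{i + 1:0{width}d}", label=label, mz=mz, intensity=inten
        )
        spec.validate()
        spectra.append(spec)
    return spectra


MANIFEST_NAME = "manifest.csv"


def write_peaklists(spectra: Sequence[RawSpectrum], directory: str | Path) -> list[Path]:
    """Write one two-column CSV (mz, intensity; no header) per sample plus
    a ``manifest.csv`` (``sample_id,label,filename``; with header).

    Values are written with 17 significant digits, so reading back through
    :func:`lipoclass.preprocess.read_peaklists` round-trips exactly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    manifest_rows = []
    for spec in spectra:
        spec.validate()
        fname = f"{spec.sample_id}.csv"
        path = directory / fname
        with open(path, "w", newline="") as fh:
            for m, v in zip(spec.mz, spec.intensity):
                fh.write(f"{m:.17g},{v:.17g}\n")
        manifest_rows.append((spec.sample_id, spec.label, fname))
        paths.append(path)
    with open(directory / MANIFEST_NAME, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_id", "label", "filename"])
        writer.writerows(manifest_rows)
    return paths
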