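"""Discriminant-feature ranking and lipid annotation.

After the two-class difference spectrum (mean NILM minus mean SIL) is
computed, the m/z features with the largest absolute difference are the
candidate discriminating lipids: positive entries favour NILM, negative
entries favour SIL.  Each candidate is then matched against a local
lipid reference table (formula, name, lipid class, associated sample
class) by monoisotopic mass within a ppm tolerance, and the signed ppm
mass error of every match is recorded.

The packaged reference table carries the five plasma lipids known to
separate NILM from SIL in this assay (Tetranor-PGFM, a prostaglandin,
HEFAD, a glycerophosphoserine and a sulfatide); users can extend it with
their own CSV in the same format.  Formulas are treated as the intact
detected-ion composition; an optional adduct mode ([M+H]+ / [M+Na]+,
with electron-mass correction) is available but off by default.
"""

from __future__ import annotations

import csv
import re
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .errors import FormulaError, InputError
from .synthetic import NILM, SIL

#: Monoisotopic masses (Da) of the most abundant isotope, IUPAC/CODATA.
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
    "Na": 22.9897692809,
    "K": 38.96370668,
    "Cl": 34.96885268,
    "F": 18.99840322,
}

ELECTRON_MASS = 0.000548579909
PROTON_MASS = MONOISOTOPIC_MASS["H"] - ELECTRON_MASS

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Elemental composition of a Hill-style formula string."""
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise FormulaError(f"cannot parse formula {formula!r} at {pos}")
        pos = match.end()
        elem, num = match.group(1), match.group(2)
        if elem not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unknown element {elem!r} in {formula!r}")
        counts[elem] = counts.get(elem, 0) + (int(num) if num else 1)
    if pos != len(formula):
        raise FormulaError(f"cannot parse formula {formula!r} at {pos}")
    return counts


def formula_mass(formula: str, adduct: str | None = None) -> float:
    """Monoisotopic mass (Da) of a formula; empty string is 0.

    ``adduct`` may be ``"M+H"`` or ``"M+Na"`` to compute the cation m/z
    (adds the adduct atom and removes one electron mass).
    """
    mass = sum(MONOISOTOPIC_MASS[e] * n for e, n in parse_formula(formula).items())
    if adduct is None:
        return mass
    if adduct == "M+H":
        return mass + MONOISOTOPIC_MASS["H"] - ELECTRON_MASS
    if adduct == "M+Na":
        return mass + MONOISOTOPIC_MASS["Na"] - ELECTRON_MASS
    raise InputError(f"unsupported adduct {adduct!r}")


def ppm_error(theoretical: float, observed: float) -> float:
    """Signed mass error, 1e6 * (observed - theoretical) / theoretical."""
    if theoretical <= 0:
        raise InputError("theoretical mass must be > 0")
    return 1e6 * (observed - theoretical) / theoretical


# ---------------------------------------------------------------------------
# Feature ranking


@dataclass
class RankedFeature:
    """A difference-spectrum extreme: m/z, signed magnitude, favoured class."""

    mz: float
    difference: float
    favored_class: str   # NILM if the difference is positive, SIL if negative


def rank_discriminant_features(
    axis: np.ndarray, diff: np.ndarray, top_n: int = 5
) -> list[RankedFeature]:
    """Top ``top_n`` features of a difference spectrum by |difference|.

    The sign convention follows the NILM-minus-SIL contrast: positive
    entries are tagged NILM, negative SIL.  Zero entries never rank; if
    fewer than ``top_n`` nonzero entries exist the list is clipped with a
    warning.
    """
    axis = np.asarray(axis, dtype=float)
    diff = np.asarray(diff, dtype=float)
    if axis.shape != diff.shape:
        raise InputError("axis and difference spectrum differ in length")
    nonzero = np.where(diff != 0)[0]
    if top_n > nonzero.size:
        if top_n > axis.size or nonzero.size < min(top_n, axis.size):
            warnings.warn(
                f"only {nonzero.size} nonzero features available "
                f"(requested {top_n}); clipping",
                stacklevel=2,
            )
        top_n = nonzero.size
    order = nonzero[np.argsort(-np.abs(diff[nonzero]), kind="stable")][:top_n]
    return [
        RankedFeature(
            mz=float(axis[i]),
            difference=float(diff[i]),
            favored_class=NILM if diff[i] > 0 else SIL,
        )
        for i in order
    ]


# ---------------------------------------------------------------------------
# Reference matching


@dataclass
class ReferenceEntry:
    formula: str
    name: str
    lipid_class: str       # FA | GPL | SPL (free-text for extensions)
    assigned_class: str    # NILM | SIL
    theoretical_mass: float


@dataclass
class LipidRecord:
    """One annotated feature, mirroring the published assignment table."""

    mz_observed: float
    formula: str
    name: str
    lipid_class: str
    assigned_class: str
    error_ppm: float
    favored_class: str = ""


def load_reference_table(
    path: str | Path | None = None, adduct: str | None = None
) -> list[ReferenceEntry]:
    """Load a reference CSV (``formula,name,lipid_class,assigned_class``);
    defaults to the packaged five-lipid table.  Theoretical masses are
    computed from the formulas at load time."""
    if path is None:
        ref = resources.files("lipoclass.data").joinpath("lipid_reference.csv")
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    entries = []
    for row in csv.DictReader(text.splitlines()):
        entries.append(
            ReferenceEntry(
                formula=row["formula"],
                name=row["name"],
                lipid_class=row["lipid_class"],
                assigned_class=row["assigned_class"],
                theoretical_mass=formula_mass(row["formula"], adduct=adduct),
            )
        )
    return entries


def match_reference(
    features: list[RankedFeature],
    reference: list[ReferenceEntry],
    tol_ppm: float = 10.0,
) -> tuple[list[LipidRecord], list[RankedFeature]]:
    """Match ranked features to reference entries within ``tol_ppm``.

    Every reference entry within tolerance of a feature produces a
    :class:`LipidRecord` (closest first); features with no match are
    returned separately.  No record ever carries |error_ppm| > tol_ppm.
    """
    if tol_ppm < 0:
        raise InputError("tol_ppm must be >= 0")
    records: list[LipidRecord] = []
    unmatched: list[RankedFeature] = []
    for feat in features:
        hits = []
        for entry in reference:
            err = ppm_error(entry.theoretical_mass, feat.mz)
            if abs(err) <= tol_ppm:
                hits.append((abs(err), err, entry))
        if not hits:
            unmatched.append(feat)
            continue
        hits.sort(key=lambda t: t[0])
        for _, err, entry in hits:
            records.append(
                LipidRecord(
                    mz_observed=feat.mz,
                    formula=entry.formula,
                    name=entry.name,
                    lipid_class=entry.lipid_class,
                    assigned_class=entry.assigned_class,
                    error_ppm=err,
                    favored_class=feat.favored_class,
                )
            )
    return records, unmatched


def annotation_to_csv(
    records: list[LipidRecord],
    unmatched: list[RankedFeature],
    path: str | Path,
) -> None:
    """Write the annotation table (columns mirroring the published
    assignment table, plus the data-driven favoured class)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["mz", "error_ppm", "formula", "name", "lipid_class",
             "assigned_class", "favored_class"]
        )
        for r in records:
            writer.writerow(
                [
                    f"{r.mz_observed:.6f}",
                    f"{r.error_ppm:.3f}",
                    r.formula,
                    r.name,
                    r.lipid_class,
                    r.assigned_class,
                    r.favored_class,
                ]
            )
        for f in unmatched:
            writer.writerow([f"{f.mz:.6f}", "", "", "unmatched", "", "", f.favored_class])
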