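# Methods

`lipoclass` implements a complete chemometric classification pipeline for
untargeted, direct-infusion ESI lipidomic spectra of blood plasma, with a
two-class endpoint: NILM (negative for intraepithelial lesion or
malignancy — the control class) versus SIL (squamous intraepithelial
lesion — the positive class throughout). This note documents the models,
the parameters that matter, the synthetic-data model, and the numerical
and design choices that were genuinely open.

## Pre-processing

**Common m/z axis.** Direct-infusion centroid spectra carry per-sample
axes. All observed m/z values are pooled, sorted, and agglomerated: a
value joins the current cluster when its ppm gap to the cluster's running
intensity-weighted mean is at most `merge_tol_ppm`; the merged column
position is the final intensity-weighted mean. The default tolerance is
5 ppm, chosen to comfortably exceed the ~2 ppm mass accuracy of a modern
Orbitrap at 140k resolving power while keeping distinct lipids apart; on
the default synthetic cohort the union axis has ~15,000 columns for 76
samples of ~500 peaks each, i.e. the axis is a near-union, which matches
the regime reported for real cohorts of this kind. The tolerance is
configurable because the correct value depends on instrument and
acquisition.

**Normalization.** Each row (sample) is divided by its Euclidean norm, so
its sum of squared intensities equals 1. This removes total-ion-current
variation. All-zero rows are rejected by name rather than silently kept.

**ROI compression.** A column survives when its maximum over samples is
*strictly higher than* `threshold_fraction` (default 0.03) times the
single global maximum of the normalized matrix. Keeping a column on the
strength of any one sample preserves class-specific peaks present in only
one class. A per-sample-threshold variant is available behind a flag. The
order is fixed — normalize, then compress — and enforced through
provenance flags on the matrix; compressing an un-normalized matrix
requires an explicit override.

## Splitting

Samples are partitioned 70/15/15 into training / validation / prediction
by the Kennard–Stone maximin algorithm on the normalized, ROI-compressed
features (the matrix the models see). KS is deterministic: the farthest
pair first (lowest indices on ties), then each sample maximizing its
minimum distance to the selected set. The KS-earliest, most
design-spanning samples go to training; validation and prediction take
`floor(0.15 n)` each and training absorbs the remainder, which yields
exactly 54/11/11 on 76 samples. Splitting is stratified by class by
default: the prediction-set granularity of per-class rates (multiples of
1/6 and 1/5 on a 6 NILM + 5 SIL set) matches what per-class flooring
produces on a 42+34 cohort. A global (unstratified) KS is available via
flag.

## Feature reduction

**PCA.** Column-mean-centred SVD fitted on training rows only; the
classifiers consume the scores of the first k = 10 components (no
variance scaling — rows are already unit-norm). Sign convention: the
largest-magnitude entry of each loading is positive, which makes runs
reproducible to the byte.

**GA variable selection.** Binary chromosomes (one bit per m/z column)
are evolved to minimize the average risk of misclassification on the
validation set,

    G = (1/N_V) Σ_n g_n,
    g_n = r²(x_n, m_own) / min_{wrong k} r²(x_n, m_k),

where r² is the squared Mahalanobis distance to a class mean under the
pooled training covariance of the selected variables (a per-class
covariance mode exists for the QDA pairing; the pooled form is the
default because the single-covariance distance matches the LDA context
the fitness was designed for). Degenerate cases are defined explicitly:
a validation sample at zero distance from both means is equidistant
(g = 1); zero wrong-class distance with nonzero own distance is the worst
case (g = ∞).

GA settings follow the study protocol: 40 generations × 80 chromosomes,
crossover probability 0.60 (single-point), per-bit mutation 0.10, three
restarts from independent seeded populations with the best chromosome
overall returned. Where the protocol is silent the package uses
tournament selection of size 2 and elitism of one (which is what makes
the best-fitness trace monotone), initial bit probability 0.05, and a
hard cap of 30 active variables (chromosomes above the cap get infinite
fitness). The cap keeps subset covariances well-posed against 54 training
samples and reproduces the 14–27-variable regime the method is known
for. Fitness values are cached by chromosome, which makes the triple
restart cheap.

A property worth knowing: because g_n's numerator grows with subset
dimension, the ratio fitness favours the single most-discriminating
variable when markers are individually strong. On synthetic cohorts with
one dominant marker the GA will (correctly) converge to very small
subsets; broad subsets emerge only when separation is genuinely
distributed across variables, as in real spectra.

## Classifiers

All classifiers are strictly two-class.

**LDA / QDA.** Scores per class k (classify by argmin):

    L_ik = (x_i − x̄_k)ᵀ Σ_pooled⁻¹ (x_i − x̄_k) − 2 ln π_k
    Q_ik = (x_i − x̄_k)ᵀ Σ_k⁻¹ (x_i − x̄_k) + ln|Σ_k| − 2 ln π_k

Priors default to training class proportions; an equal-priors switch
exists. Any covariance with condition number above 1e10 receives a ridge
λI with λ = 1e-6·trace(Σ)/p — small enough to be numerically invisible on
well-posed problems, large enough to keep GA-subset and per-class QDA
covariances invertible.

**SVM.** Soft-margin dual solved by deterministic SMO: sweeps in index
order, partner chosen to maximize |E_i − E_j| with an ordered-scan
fallback, Platt's b1/b2 bias update, and bias recomputed from margin
support vectors at the end. Kernels: linear, quadratic (τ + xᵀz)²,
cubic (τ + xᵀz)³, RBF exp(−γ‖x−z‖²), MLP tanh(k1 xᵀz + k2). Defaults:
τ = 1, γ = 1/p, k1 = 1, k2 = −1. The MLP kernel is indefinite; for
non-positive pair curvature the pair objective is evaluated at the box
ends, which makes termination the norm, but training carries a sweep cap
and a documented may-raise-`ConvergenceError` contract, and the report
builder turns such models into annotated NA rows.

The box constraint C and RBF width γ are not part of the published
protocol. The pipeline therefore selects them on the validation set by
balanced accuracy over fixed grids (C ∈ {0.1, 1, 10, 100},
γ ∈ {0.01, 0.1, 1, 10, 100}), with ties resolved toward the smallest
values (strongest regularization). Both can be pinned in the run
configuration, which disables the grid. This matters in practice: PCA
scores of unit-norm spectra live on a small scale, where γ = 1/p alone
badly underfits.

**KNN.** Euclidean majority vote on the whole ROI matrix; k restricted
to odd values (no vote ties in a two-class problem) and chosen on the
validation set by balanced accuracy over {1, 3, 5, 7, 9}, smallest k on
ties. The positive-class vote fraction serves as the ROC score.

## Evaluation

With SIL positive: Sensitivity(%) = TP/(TP+FN)·100, Specificity(%) =
TN/(TN+FP)·100, and the F-score is the harmonic mean of the two on the
percent scale, reported divided by 100 — the clinical-chemometrics
convention, *not* the precision–recall F1. Zero-denominator metrics raise
an error rather than silently reporting 0; the report writer renders them
as annotated NA cells. F(0, 0) is defined as 0 by continuity.

AUC is the trapezoidal area under the empirical ROC with tied scores
grouped, which equals the Mann–Whitney probability with ties counted ½
(asserted to 1e-12 in tests). Score orientation per family is fixed and
documented: discriminant models use L(NILM) − L(SIL) (larger = more
SIL-like), SVMs the raw pre-sign decision value, KNN the SIL vote
fraction — a convention the source protocol leaves unstated for
hard-label classifiers. Reported tables round percentages to 1 decimal
and AUC/F-score to 3, matching the published precision.

## Annotation

The two-class difference spectrum (mean NILM row minus mean SIL row of
the compressed matrix) tags its extremes: positive entries favour NILM,
negative SIL. The top-|difference| features are matched against a local
reference table by monoisotopic mass (IUPAC most-abundant-isotope masses
embedded as data) within a ppm tolerance (default 10 ppm), recording the
signed error 1e6·(observed − theoretical)/theoretical per match. The
packaged table carries the five discriminating plasma lipids of this
assay: Tetranor-PGFM (C16H27O7) and a hydroperoxide-epidioxide fatty-acid
derivative (C22H37O6) for SIL; a prostaglandin (C20H33O6), a
glycerophosphoserine (C34H67O10NP) and the sulfatide (3′-sulfo)Galβ-Cer
(C40H78O11NS) for NILM. Formulas are treated as the intact detected-ion
composition; an optional [M+H]+/[M+Na]+ adduct mode with electron-mass
correction exists but is off by default, because no single convention
reproduces vendor-software error values in general.

## Synthetic cohorts

The generator emulates the study design: 42 NILM + 34 SIL positive-mode
spectra over m/z 200–1200, each with its own jittered axis.

* **Background**: 300 peaks shared by both classes, positions drawn once
  per cohort (uniform by default; a density weighting toward low m/z is
  available, mimicking the low-mass concentration of real plasma lipid
  signal), mean intensities log-uniform over [0.005, 1] (heavy-tailed).
* **Markers**: the five discriminating m/z positions, fold-change 5
  between class means by default (`effect_size`; the up-class mean is
  exactly effect_size × the down-class mean), base intensity 0.3.
* **Noise**: every intensity is multiplied by a unit-mean log-normal
  factor with CV 0.3; every position is jittered by Gaussian noise with
  σ = 2 ppm; 200 decoy peaks per sample sit below the eventual ROI
  threshold (noise-floor fraction 0.02).

The CV, jitter and intensity scales are stand-ins chosen to be
instrument-plausible, not fitted to any real cohort. What the generator
deliberately omits: isotope patterns, adduct chemistry, profile-mode peak
shapes, ionization suppression, between-subject covariance of the lipid
background, and the LSIL/HSIL substructure of the SIL class. Passing
recovery tests on these cohorts therefore demonstrates that the pipeline
machinery extracts planted class structure of realistic magnitude — not
that real plasma cohorts will classify at any particular rate.

Two behaviours of the honest pipeline on synthetic nulls deserve note.
First, with no class effect, an unweighted soft-margin SVM trained on a
30-vs-24 imbalanced training set leans toward the majority class, so
null sensitivity sits below 50% and specificity above — balanced
accuracy, not each rate separately, is the chance-level quantity (the
degenerate sensitivity-0/specificity-100 behaviour of SVM on full
spectra is a known real-data outcome of this method family). Second, as
discussed above, the ratio fitness makes the GA prefer the single
strongest marker over a redundant pair.

## Problem sizes and determinism

Default runs use the 76-sample cohort (~15,000-column union axis,
~220-column ROI matrix); recovery properties are averaged over 10–20
seeded cohorts, and GA checks use ~50-variable cohorts — sizes chosen so
the whole test suite and the acceptance script each complete in well
under a coffee break on one CPU. Every source of randomness (cohort
simulation, GA restarts) flows from one root seed through named
substreams recorded in the run log; identical configuration and seed
reproduce every artifact byte for byte, and a run resumed stage by stage
from serialized intermediates equals the monolithic run exactly.

## Known limitations

* Two-class only; no multiclass coupling, probability calibration,
  cross-validation, or confidence intervals (single KS split by design).
* The ROI rule is the threshold form appropriate to chromatography-free
  spectra, not the full chromatography-aware ROI algorithm.
* The SMO implementation is compact and exact for the ≤100-sample regime
  this pipeline targets; it is not tuned for large n.
* Reference matching is mass-only (no MS/MS, no isotope-fine-structure
  scoring); identifications are "possible lipids" in the usual
  annotation sense.
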