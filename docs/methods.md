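# Methods

`irscreen` implements a blood-based infrared screening analysis: FTIR
absorption spectra of two blood fractions (dried PBMC films and dried
plasma) are preprocessed into second-derivative fingerprints, compared
per wavenumber between a cancer and a control group, reduced to a small
feature set, classified with quadratic discriminant analysis (QDA), and
validated by Monte Carlo cross-validation (MC-CV). Because clinical
cohorts of this kind are rarely shareable, the package carries a
synthetic-cohort generator with plantable class effects, so every stage
can be validated by parameter recovery rather than by eyeballing.

## Data model

All spectra live on a canonical axis of 6845 points spanning
700–4000 cm⁻¹ inclusive. The axis is *defined* by its endpoints and
point count; the spacing, 3300/6844 ≈ 0.48218 cm⁻¹, is derived. (A
nominal spacing of 0.482 and a count of 6845 are mutually inconsistent
at full precision; defining the grid by count and endpoints makes both
the full count and the 2282-point fingerprint subset exact.) The
fingerprint region is the subset with wavenumber ≤ 1800 cm⁻¹ — 2282
points — where most biochemical information of biofluids lies.
Wavenumbers are stored ascending everywhere; descending order in files
is a presentation concern handled at I/O boundaries.

## Synthetic cohorts

The generator emulates the *statistical* structure of a two-arm
screening study, not the physics of the measurement:

* **Design.** 29 cancer subjects and 30 controls (15 benign, 15
  healthy), 5 replicate measurements per subject per blood component.
  Clinical covariates (histology, stage, size bin, receptor status) are
  drawn independently from the reference marginal frequencies; their
  joint distribution is not modelled because it is not reported
  anywhere. A 15 % hemolysis rate removes those subjects' plasma
  spectra, reproducing component-missing subjects (the reference fused
  cohort kept 26 + 24 of 30 + 29 subjects).
* **Spectra.** Each component has a fixed sum-of-Gaussians band model at
  the canonical assignment positions (amide I 1655, amide II 1545,
  COO⁻/CH₃ 1400, PO₂⁻ 1240/1080, C–O 1160/1140, nucleic-acid conformers
  920/860/800 cm⁻¹, plus the C–H/N–H stretch region above 2800).
  Gaussians were chosen over Lorentzian/Voigt shapes: biological films
  yield broad, heavily overlapped bands for which the distinction is
  immaterial, and Gaussians admit closed-form derivative checks.
* **Variation.** Subject-level biology is a per-band multiplicative
  perturbation (σ = 2 %); replicate-level noise is white with
  σ = 2·10⁻⁴ absorbance, representative of a well-averaged (≈128-scan)
  measurement; each replicate adds a small linear + broad-Gaussian
  baseline drift. Each subject's noiseless spectrum is rescaled so its
  amide I maximum falls inside 0.55–0.90 absorbance, i.e. inside the QC
  acceptance window — measurement artifacts are opt-in, injected
  explicitly (`inject_artifact`: over-/under-exposure, narrow
  water-vapor lines).
* **Effects.** Class effects perturb one band's amplitude and/or width
  by a few percent for one diagnosis group. The default malignancy
  signature (PBMC: −5 % at 1140, +4 % width at 1545, −3 % at 1080;
  plasma: +5 % at 1160, −3 % width at 1655) follows the reported
  discriminative band positions; the *magnitudes* are calibration
  choices — no effect sizes are published — set to 2–3× the
  subject-level scatter, which is the regime where the pipeline lands
  in the published performance range rather than saturating.
* **Determinism.** A master seed spawns one substream per subject
  (`numpy` `SeedSequence.spawn`), so a subject's spectra do not change
  when the cohort grows. The amide-target and baseline jitters scale
  with the configured noise levels, so a zero-noise configuration is
  exactly deterministic (pure band sum + fixed baseline).

What the generator does **not** emulate: Mie scattering, film-thickness
variation, instrument line shape, detector nonlinearity, or correlated
(pink) noise. Passing tests therefore show that the *algorithms* behave
correctly on data with the assumed band-plus-noise structure; they do
not certify performance on real films, where scattering artifacts are
the dominant nuisance.

## Preprocessing

Stage order is fixed: QC → fingerprint restriction → vector
normalization → moving average → second derivative → replicate
averaging.

* **QC.** A spectrum passes if its amide I maximum (1600–1700 cm⁻¹)
  lies in [0.5, 1.0] absorbance and its water-vapor metric — RMS of the
  second difference of raw absorbance over 1400–1800 cm⁻¹, divided by
  the amide I maximum — is at most 9·10⁻⁴. The threshold is the 99th
  percentile of the metric over clean simulated replicates at default
  noise settings (2710 spectra, 5 seeds); the metric itself is a
  construction of this package (the problem, not the test, is standard).
* **Normalization.** "Unity total energy" is implemented as unit
  Euclidean norm, computed over the fingerprint region only (the
  restriction precedes normalization in the chain).
* **Smoothing.** Centered moving average, default 5 points, truncating
  at the edges. The width is not published; it is exposed and logged.
  Smoothing runs along the wavenumber axis (scans are co-added by the
  instrument before export).
* **Second derivative.** Savitzky–Golay, window 9, polynomial order 2 —
  the de facto standard in FTIR chemometrics. It is exact on quadratics
  (a frozen test invariant) and places a Gaussian band's minimum at the
  band center to within one grid step. Edge values come from one-sided
  polynomial fits.
* **Averaging.** Replicates are averaged *after* all per-spectrum
  transforms, matching the convention that displayed spectra are
  averages of processed measurements. Subjects whose replicates all
  fail QC are dropped and logged.

No baseline correction, EMSC, or atmospheric compensation is applied
beyond the QC reject rule; the second derivative suppresses smooth
baselines by construction.

## Feature selection

At every fingerprint wavenumber a two-sample t-test compares the cancer
and control rows of the second-derivative dataset. Welch's
unequal-variance form is the default — equal group variances are an
assumption, not a given — with a `pooled` flag for the classical
Student statistic. Significance threshold α = 0.005, uncorrected: the
per-wavenumber traces are reported as raw p-values with the α line
drawn, in keeping with how such traces are conventionally displayed;
family-wise discovery control is explicitly out of scope.

Each significant candidate is then screened by the overlapping
coefficient OVL = ∫ min(f̂₁, f̂₂) of the two classes' Gaussian KDEs
(Silverman bandwidth, numerical integration over the pooled range ± 3
bandwidths). Candidates with OVL above 0.8 are discarded, the rest are
ranked by ascending OVL (ties: ascending p, then ascending wavenumber)
and capped at k = 10 per component.

Two knobs deserve justification:

* **overlap_max = 0.8.** At the study's n (≈25–30 per class) a feature
  at exactly p = 0.005 has a standardized mean difference around 0.8,
  which corresponds to a theoretical normal OVL near 0.67. A threshold
  of 0.5 would reject essentially every feature the t-criterion admits,
  making the two criteria contradictory; 0.8 keeps OVL as a meaningful
  secondary filter (it removes heavy-tailed and outlier-driven
  candidates) without emptying the candidate set.
* **min_sep = 8 cm⁻¹.** Adjacent grid points inside one absorption band
  are nearly collinear after smoothing; feeding several of them to QDA
  produces ill-conditioned covariances. A greedy minimum-separation
  rule (skip a candidate within 8 cm⁻¹ ≈ one band half-width of an
  already-kept one) keeps one representative per band region. This is
  redundancy control, not interval merging — features remain single
  wavenumbers.

Clinical subgroup traces (`subgroup_trace`) run the same pointwise test
between two strata of the cancer group (mass size ≤/> 20 mm, single vs
multiple masses, stage I vs II, IDC vs ILC, vascular invasion, node
involvement), dropping subjects with missing values pairwise.

## Classification

QDA models each class as a multivariate normal with its own covariance;
the subject score is the log-density difference (cancer minus control),
so positive scores are cancer-like. Sample covariances are shrunk
toward a scaled identity, Σ + λ·tr(Σ)/p·I with λ = 10⁻⁶ by default —
enough to guarantee positive-definiteness at small n without materially
moving well-conditioned fits. Priors are empirical class frequencies
(an `equal` option exists). Fitting refuses n ≤ p per class rather than
fitting silently; the MC-CV driver additionally caps the fused feature
count at (smallest training class − 1), dropping the weakest-ranked
features across both components.

The ROC enumerates thresholds at +∞, the midpoints between consecutive
distinct scores, and −∞, predicting cancer when score ≥ threshold. AUC
is the trapezoidal integral, which equals pairwise concordance with
half-credit for ties (verified exhaustively against a brute-force
oracle on small integer score vectors). The operating cut-off maximizes
Youden's J = sensitivity + specificity − 1; ties break toward higher
sensitivity (a screening test prefers catching cases), then toward the
lower threshold. A closest-to-top-left criterion is available.

## Monte Carlo cross-validation

Each of 500 (default) repetitions draws a stratified subject-level
70/30 split — subject-level, so replicates and components of one
subject never straddle the split. Feature selection runs on the
training subjects only, inside the loop, by default: the alternative
(selecting once on all data) leaks validation information, and the
package keeps it available (`selection_in_loop=False`) purely so the
inflation is demonstrable — on null data it raises mean validation AUC
from ≈0.5 to ≈0.8. Validation sensitivity/specificity are evaluated at
the training-chosen cut-off, never re-optimized. Per-repetition seeds
are independent substreams of the MC-CV seed, so doubling the
repetition count leaves earlier repetitions' results unchanged.
Repetitions with an empty fused feature set are skipped and counted; a
run with more than half its repetitions skipped fails loudly.

Aggregate ROC curves are vertical averages (mean sensitivity on a fixed
false-positive-rate grid); summary statistics report mean, SD, and
2.5/97.5 percentiles separately rather than guessing at any particular
interval construction.

## Problem sizes used in validation

The test suite and the acceptance script run the analysis at the study
design size (29 + 30 subjects, 5 replicates), with 200 MC-CV
repetitions per run, 50 seeded runs for recovery rates, and 20 seeds
for null calibration of the t-test — sizes at which the Monte Carlo
error of each reported aggregate is comfortably below the margin the
corresponding check allows.

## Known limitations

* The generator's band-plus-white-noise model is optimistic about real
  dried-film spectra (no scattering, no correlated noise); absolute
  performance numbers on synthetic cohorts should be read as
  "achievable under the assumed structure", not as clinical estimates.
* OVL estimation by KDE is biased upward for small samples (identical
  distributions estimate ≈0.98–1.0); thresholds are calibrated with
  that bias in mind.
* The JCAMP-DX support is deliberately a subset: `(X++(Y..Y))` tables
  with AFFN numerics only, no ASDF/DIFDUP compression and no vendor
  formats.
* No FDR control, no interval merging of adjacent features, no
  alternative classifiers, no nested hyperparameter tuning.
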