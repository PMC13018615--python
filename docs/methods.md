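# Methods

## SPD geometry

The package works on the manifold of symmetric positive-definite (SPD)
matrices under the affine-invariant Riemannian metric (AIRM),

d(A, B) = ‖logm(A^{−1/2} B A^{−1/2})‖_F = √Σₖ log²λₖ,

where λₖ are the generalised eigenvalues of (A, B). AIRM is the metric whose
tangent chart matches the whitening C̄^{−1/2} · Log_C̄(·) · C̄^{−1/2} used in
the tangent projection, and it is invariant under congruence by any
invertible matrix — re-referencing or linearly remixing the ECG leads moves
every covariance the same way. The log-Euclidean metric would be the main
alternative; it agrees with AIRM for commuting matrices (which the test
suite exploits as a closed-form oracle) but lacks full affine invariance.

Matrix functions are computed by symmetric eigendecomposition. Eigenvalues
at or below 1e−12 times the largest are treated as numerically singular and
the input is rejected rather than repaired — repair (shrinkage) belongs to
covariance estimation, where it is explicit and configurable. Every result
of a matrix function is re-symmetrised as (M + Mᵀ)/2 to suppress
floating-point drift.

### Fréchet (Karcher) mean

The weighted Fréchet mean argmin_C Σᵢ wᵢ d(C, Cᵢ)² is found by the standard
fixed-point iteration C ← Exp_C(step · Σᵢ wᵢ Log_C(Cᵢ)), initialised at the
log-Euclidean mean expm(Σ wᵢ logm Cᵢ), with step 1.0, tolerance 1e−8 on the
Frobenius norm of the tangent update, and at most 100 iterations.
Non-convergence is reported as a warning, not an exception, because a
slightly unconverged mean is still a valid reference point. The two-point
weighted mean has the closed form of the geodesic point
A^{1/2}(A^{−1/2} B A^{−1/2})^α A^{1/2}, which both the augmentation code
(directly) and the test suite (as an oracle for the iterative solver) use.

### Tangent vectorisation

Tangent matrices are vectorised by their upper triangle with off-diagonal
entries scaled by √2, so the Euclidean norm of the vector equals the
Riemannian distance to the reference. For 12 leads this yields 78 features.
The inverse (`tangent_lift`) is exact and round-trips to 1e−8.

## ECG ingestion

ECGs are 12×T matrices (mV) at 500 Hz in the standard lead order
DI, DII, DIII, AVR, AVL, AVF, V1–V6, read from columnar CSV (header
optional; a permuted header is remapped). R peaks are detected with a
Pan–Tompkins-style chain on lead DII: zero-phase 5–15 Hz band-pass, squared
derivative, 150 ms moving integration, threshold at 0.5× a 2 s rolling
maximum, 200 ms refractory period, and refinement to the band-passed
extremum. Beats are cut to 1 s windows with the R peak at 40% of the window
(covering P–QRS–T); beats that would overrun an edge are dropped.

The per-recording covariance is the pooled sample covariance of the
mean-centred, concatenated beat windows, shrunk toward a scaled identity:
C ← (1−γ)C + γ(tr C/12)I with γ = 0.01 by default. Pooling maximises sample
support for a 12×12 estimate; the shrinkage floor keeps the estimate SPD
even with degenerate leads. A configuration switch (`use_aligned=False`)
feeds the raw unaligned signal instead of the aligned beat stream, since
either could plausibly drive the covariance in practice.

## Clinical text

Each patient's history is the concatenation of diagnosis, intervention and
medication term lists from the structured letter table; demographics are
never featurised. Documents become raw term-frequency vectors (no TF-IDF,
no normalisation) over a lowercased, alphanumeric-token (length ≥ 2)
vocabulary in lexicographic order. The vocabulary is always built from
training-fold documents only; fitting it on all data would leak test terms.
Each ECG is paired with the patient's letter nearest in date; ties break to
the earlier letter (information already available before the ECG). Patients
with no letter are flagged text-missing: excluded from every arm of a
fusion comparison (to keep arms paired) but retained for ECG-only runs.

## Augmentation

An augmented sample draws one α ~ Beta(a, b) (default a = b = 0.4,
concentrating mass near the endpoints so most mixes stay close to a real
sample), mixes the two covariances along the geodesic, re-projects at the
training-fold reference mean, and mixes the text vectors linearly with the
*same* α. The reference mean is computed from original samples only and is
not recomputed after augmentation, so original tangent features are
untouched by augmentation. Classification mixes within class and keeps the
label (the stated purpose is class balancing); regression mixes arbitrary
pairs and interpolates labels linearly. Balancing appends mixes until every
outcome group matches the largest; a single-member group cannot be paired
and is left unbalanced with a warning.

The conventional comparator (`upsample` arms) duplicates instead of mixing:
`upsample_baseline` appends exact copies, and the hybrid ablation arm mixes
the covariance but copies one parent's letter verbatim, breaking the
cross-modal α-consistency.

## Evaluation protocol

CPET labels are used directly for regression and discretised for
classification: VE/VCO₂ at 30 (top of its 20–30 normal range), VO₂ %pred at
(45, 60, 85)% (the central pair being its normal range), VO₂ peak at the
training-fold median — no printed clinical threshold in L/min exists, so
the cut is data-driven per fold. Boundary values go to the upper group.
These defaults exist so the synthetic benchmark runs; for real use the cuts
are configuration the user must own.

Splits are stratified patient leave-out: each of 100 repeats holds out one
uniformly chosen patient per lesion class, and all of a held-out patient's
records leave the training fold. The same plan object is reused across all
arms of a comparison, so arms are paired repeat by repeat; the augmentation
RNG stream is also shared across arms within a repeat, so paired
augmentation arms see identical pairs and α draws and differ only in their
stated policy.

Models are RBF-kernel SVMs (C = 1, ε = 0.1 for regression) with per-fold
standardisation; the baseline is ordinary least squares for continuous
labels and logistic regression for groups. The standardiser is fit on the
original training samples only — not on augmented ones — extending the
originals-only rule from the tangent reference to the scaler (convex text
mixes have shrunken column variance, and a scaler fit on them distorts test
documents). Test predictions are aggregated per patient (mean for
regression; mean decision score, then majority class, for classification).
Metrics are R², adjusted R² (p = number of feature columns; undefined when
n ≤ p+1), RMSE, Pearson r, accuracy, macro F1, and macro one-vs-rest ROC
AUC on decision scores; repeats whose test fold contains a single class are
excluded from AUC aggregation with their count reported. Because each test
fold holds only one patient per class, per-repeat correlations are
unstable; regression recovery is therefore also reported as the pooled
correlation over all held-out (patient, prediction) pairs across the plan
(`pooled_regression_metrics`).

## Synthetic cohort generator

The generator emulates the statistical structure of a small imbalanced CHD
cohort, not cardiology: no P/T waves, no lesion-specific morphology.

* **Classes.** Five lesion classes sized (12, 8, 8, 7, 5) — 40 patients,
  mirroring the imbalance ratios of a real CHD service at desk scale. Class
  prototypes sit at Riemannian distance `separation` (default 2.0) from a
  fixed AR(1)-correlated base covariance (lead variance 0.04 mV², ρ = 0.3),
  in random symmetric directions of exactly unit Frobenius norm, resampled
  until pairwise distances reach 0.5·separation. Patients scatter around
  their prototype with tangent perturbations of expected unit norm scaled
  by `dispersion` (default 0.3). Normalising directions makes `separation`
  and `dispersion` interpretable Riemannian radii; with raw unit-variance
  entries the perturbation norm would grow with the matrix dimension and
  the stated identifiability regime would be unreachable.
* **ECG.** 30 s records at 500 Hz: baseline noise coloured by the patient
  covariance (population covariance exactly C) plus Gaussian-bump QRS
  deflections (0.8 mV, ~80 ms, fixed per-lead polarities, heart rate
  uniform in 60–90 bpm) at known indices, so the detector can be validated
  in closed loop.
* **Letters.** A 60-token vocabulary with a fixed power-law base
  distribution; class distributions are Dirichlet perturbations with
  concentration `class_topic_concentration` (→∞ collapses all classes onto
  the base, i.e. text becomes uninformative). Optionally a severity topic
  (the last quarter of the vocabulary) is blended in with weight
  `severity_weight · sigmoid(z)`, tying term usage to the patient's
  continuous disease burden the way medication and intervention lists do;
  and optionally each patient draws an idiosyncratic spiky distribution
  around their class distribution. Both extensions default to off.
* **Outcomes.** z is the cohort-standardised projection of the patient's
  true tangent coordinates onto a unit direction — random by default, or
  the leading principal direction of the class prototypes
  (`direction="between_class"`, severity tracking lesion anatomy). Each
  label is intercept + signal_sd·z + noise, with intercepts/scales in
  clinically plausible ranges (VE/VCO₂ 30 ± 8, VO₂ %pred 65 ± 9%, VO₂ peak
  1.5 ± 0.35 L/min) and noise set so the true linear model explains
  `target_r2` (default 0.6) of the variance. Physiological clamps exist but
  never trigger at default scales (audited).

One letter and one CPET document per patient, dated within ±90 days of the
ECG; `distractor_docs` adds a second, farther letter to exercise
nearest-date linkage.

### What passing the synthetic benchmarks does and does not show

Two benchmark conditions are frozen in `riemecg.benchmarks`:

* the **recovery benchmark** (generator defaults) checks identifiability —
  the full pipeline recovers the five classes (accuracy ≥ 0.9) and the
  regression signal (pooled r ≈ √0.6 ceiling) — and hosts the
  mixing-vs-duplication ablation;
* the **fusion benchmark** (dispersion 4.5, native 2.5 s segments, class
  topic concentration 0.3, severity weight 0.6, between-class outcome
  direction, true R² 0.9) realises the regime where letters carry signal
  the degraded ECG channel lacks; there, fusing modalities beats ECG alone.
  At the default conditions ECG alone is nearly perfectly class-informative
  and fusion has nothing to add, so the fusion comparison is only
  meaningful in this regime.

Directional arm comparisons aggregate mean macro F1 over the two fixed-cut
labels and three cohort sub-seeds with 100 paired repeats each; the
median-cut VO₂ peak label is excluded from directions because its per-fold
median cut re-balances the groups by construction.

A known negative result, reproduced deliberately rather than hidden: with
letters that carry only class- and severity-level signal, duplicating real
minority letters (which re-weights genuine documents and preserves the
empirical text spread) is as good as or slightly better than convex
mixing (which shrinks within-class text variance). The advantage of
α-consistent mixing over upsampling reported on real clinical data is not
reproduced by this multinomial text model — real letters' patient-specific
term reuse across documents is a plausible missing ingredient. The
corresponding acceptance check is left asserting the claimed direction and
currently fails on the frozen benchmark seeds.

## Numerical and degenerate-input policy

Dimension mismatches, asymmetric inputs and non-SPD matrices raise
structured errors naming the offending quantity; near-singular covariances
are rejected at the geometry layer and repaired only by explicit shrinkage
at estimation. Flat ECGs yield an empty peak list plus a warning; empty
corpora yield an empty vocabulary plus a warning; zero-variance regression
targets yield NaN metrics plus a warning. Everything downstream of a seed
is deterministic: regenerating a cohort or re-running an ablation with the
same configuration reproduces files and reports byte for byte.

## Known limitations

* The generator's waveforms are statistically faithful (covariance,
  R-peak timing) but morphologically naive; detector performance on real
  ECGs is not established by these tests.
* Text is multinomial bag-of-words; it cannot express negation, multi-word
  clinical entities, or cross-document consistency of a patient's history.
* The clinical grouping cuts for VO₂ %pred and VE/VCO₂ are normal-range
  defaults, not validated thresholds; VO₂ peak grouping depends on the
  training fold.
* SVM hyperparameters are fixed defaults; no tuning is performed, so
  absolute metric levels are conservative.
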