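# Methods

This note documents the models, estimators and design choices behind
`beatselect`, in the spirit of a package reference: what is computed, under
which assumptions, and where the genuinely open decisions were made.

## Problem setting

Long-term ambulatory ECG produces tens of thousands of beats per patient;
the clinically relevant task is *interpatient* classification: a model
trained on a reference population must label the beats of a previously
unseen patient.  Two properties dominate the design: severe class
imbalance (roughly 90 % N, 2 % S, 7 % V, 1 % F) and strong interpatient
variability of beat morphology, against which only patient-normalized
features are stable.  Plain accuracy is uninformative here; we evaluate
with the balanced classification rate (BCR).

## Balanced classification rate

BCR is implemented as the **arithmetic mean of per-class recalls**.  A
majority-class-only predictor in a K-class problem then scores exactly
1/K (25 % for K = 4), and missing a single class degrades the score
gracefully instead of collapsing it to zero.  The phrase "geometric mean"
sometimes attaches to this quantity in the literature, but the standard
worked example (one class of four correct → 25 %) and published score
tables are only consistent with the arithmetic mean — a true geometric
mean would be 0 whenever any recall is 0.  A `kind="geometric"` switch
exists for comparison.

## Feature extraction (249 columns)

Windows are half-open `[on, off)` over 0-based sample indices; all
durations are in seconds, amplitudes in millivolts.

* **Segmentation (24/lead).**  From the delineated P, QRS and T waves:
  flags (wave present), signed/positive/negative areas (amplitude sum ×
  sampling period), extrema, standard deviation, skewness and kurtosis of
  the QRS amplitudes, and the QRS/P/T, Q→R, R→S, QRS-on→T-off (QT) and
  QRS-off→T-on (ST) durations.  Skewness and kurtosis of a zero-variance
  window are undefined and therefore *missing*, not NaN.
* **R-R intervals (4 + 4×2).**  Previous and next interval, the mean of
  the ≤10 intervals spanned by the 5 beats before and after (truncated at
  record edges), and the record mean.  First/last beats fall back to the
  record mean for the missing neighbor.  The same four are computed from
  the automatically detected R spikes; the reference four are shared by
  both leads.
* **Morphology (19/lead).**  The amplitude linearly interpolated at 10
  uniform points across [QRS_on, QRS_off] and 9 across [QRS_off, T_off],
  endpoints included.  Endpoint inclusion is a convention choice; it is
  fixed here and encoded in the column definitions.
* **Hermite basis functions (20/lead).**  The ±300 ms R-centered window is
  least-squares projected on discretely orthonormalized Hermite functions
  of orders 0–19.  The width σ is selected per beat from a 30-point
  geometric grid spanning 5–100 ms (covering physiological QRS widths) by
  minimizing the RMS reconstruction error; ties take the smaller σ.  The
  stable two-term recurrence with the Gaussian envelope folded in avoids
  overflow at large arguments.  An all-zero window returns zero
  coefficients and the grid-midpoint σ.
* **Higher-order statistics (30/lead).**  Diagonal slices of the 2nd, 3rd
  and 4th-order cumulant functions of the mean-removed ±250 ms window,
  with biased (1/N) estimators: c2(τ) = E[x(n)x(n+τ)] (the
  autocorrelation), c3(τ) = E[x(n)x(n+τ)²], and
  c4(τ) = E[x(n)x(n+τ)³] − 3c2(τ)c2(0), evaluated at 10 equally spaced
  lags in [−250, +250] ms (±250, ±194, ±139, ±83, ±28 ms at 360 Hz).
* **Normalized groups (3 + 3×2 and 21/lead).**  R-R features and non-flag
  segmentation features divided by their per-patient mean.  The
  patient-mean R-R feature is dropped from the normalized group — it
  normalizes to the constant 1 — which is the only accounting consistent
  with a 249-column total.

**Missingness and imputation.**  Absent fiducial points make the features
that need them *missing* (data, never an error).  Missing entries are
imputed with the patient's own mean of that feature (global column mean,
then 0, as fallbacks), so no information flows between patients; the
pre-imputation mask is preserved for audit.  Beats labeled outside the
four AAMI classes (paced, unclassifiable, unknown codes) are carried
through annotation handling and dropped only at matrix assembly.

## Classifiers

**Weighted LDA.**  Homoscedastic Gaussian classes fitted in closed form;
the pooled covariance weights each class's scatter by its cost,
Σ = Σ_k c_k S_k / Σ_k c_k N_k, so equal weights recover ordinary LDA
exactly.  If Σ is singular (zero within-class scatter, collinear
features) a ridge ε·I with ε = 10⁻⁸·tr(Σ)/d is added.  Prediction
maximizes the linear discriminant; ties go to the lowest class index
(classes kept sorted).

**Weighted SVM.**  One-against-one: K(K−1)/2 pairwise soft-margin SVMs
with the polynomial kernel (xᵀz + 1)^d, each penalizing class k's slack
by C·c_k; prediction by majority vote, ties to the lowest class index.
The pairwise quadratic programs are solved by scikit-learn's `SVC`
(libsvm); the weighting contract, pairing and tie-breaking live in this
package.  Inverse-prior weights are normalized to sum to K (for LDA this
scale cancels; for the SVM it would fold into C), but an explicit weight
dict is applied *unnormalized* so that weighting a class by m is
equivalent to duplicating its samples m times.  An optional
standardization switch (off by default) z-scores features on the training
split.

## Feature selection

**Histogram MI filter.**  I(x; y) = H(y) − Σ_b p(b) H(y | b) from the
empirical joint of y with x binned into round(√N) equal-width bins over
the observed training range; natural log (nats); clipped at 0.  A constant
feature has one effective bin and scores exactly 0.  The estimator is
invariant under monotone affine transforms of x, and ranking ties keep
column order, making the ranking fully deterministic.  The default top-k
is 6; the cut-off between "informative" and "noise" MI values is a
judgment call (MI is unbounded), so `k` is exposed rather than inferred
from an elbow heuristic.

**Forward-backward wrapper.**  Starting from the empty set, each step adds
the feature with the best criterion value; from the third step a backward
pass removes a feature if that strictly improves the criterion; the search
stops when no addition strictly improves or 10 features are reached.
Strict improvement on both moves guarantees termination; the trace records
every candidate evaluation as well as the accepted steps.

The criterion is the mean BCR over 4 patient-grouped internal folds of the
*training* patients.  A single held-out split was considered and rejected:
with a few dozen held-out beats the criterion's granularity (1 recall step
per class) stalls the strict-improvement rule after one or two features,
whereas fold-averaging keeps it fine-grained while still never touching
the test patients.  Model selection on test-side performance would
overstate generalization and is structurally impossible here (the leakage
test asserts that corrupting every test-patient value changes neither the
selected features nor the fitted model).

**Hyperparameter search.**  The SVM grid — degree 1–4 × C ∈ 10⁻⁵…10⁵
(11 log-spaced values) — is scored by leave-one-patient-out
cross-validation on the training patients; folds missing a class are
scored over their present classes and flagged.  Ties prefer the smaller
degree, then the smaller C.

## Synthetic data generator

Each beat is a sum of five Gaussian waves (P, Q, R, S, T).  The generator
emulates the features of real ambulatory data the pipeline must be
sensitive to:

* **class structure** — N: the patient template; S: normal morphology with
  the preceding R-R shortened ×U(0.5, 0.8) and a compensatory pause;
  V: QRS widths ×U(1.8, 2.5), absent P, inverted T, and a premature
  coupling interval ×U(0.65, 0.90) of the sinus cycle (ventricular
  ectopy is early by definition); F: a convex mix λ ∈ U(0.3, 0.7) of the
  N and V wave parameters.  Coupling intervals reference the sinus cycle
  and the compensatory pause restores the sinus schedule, so prematurity
  is crisp rather than compounded across consecutive ectopics.
* **class prevalences** — default 89.9 / 1.9 / 7.4 / 0.8 %, the customary
  interpatient training distribution of ambulatory recordings.
* **interpatient variability** — every patient draws its own heart rate
  (mean R-R U(0.70, 0.95) s), amplitude and width scales, and a morphology
  template (per-wave amplitude factors U(0.7, 1.3), width factors
  U(0.9, 1.15), P/T positions).  This matters: with a single shared
  template the Gaussian beats are textbook-crisp and pooled morphology
  features dominate every rhythm feature, the opposite of what real
  interpatient data show.  With realistic diversity, the patient-normalized
  previous R-R emerges as the top-ranked MI feature — the hallmark
  finding the generator is designed to reproduce structurally.
* **beat-to-beat variability** — ~10 % amplitude and ~8 % width jitter
  (respiratory modulation), plus a per-beat amplitude factor for ectopics
  (multiform ectopy).
* **nuisance processes** — white noise (default 0.02 mV, "low noise"),
  a 0.3 Hz baseline sinusoid (0.1 mV), detected annotations jittered ±1
  sample with a 1 % miss rate, and fiducials dropped at 0.6 % (the order
  of delineation failure rates reported for real delineators).

Fiducial ground truth sits at μ ± 3w of the generative waves, clamped
outward from R so overlapping waves (wide QRS, fusion) never violate the
physiological point order.  Everything is driven by one integer seed and
is bit-reproducible.

**What passing tests do and do not show.**  The generator provides clean
separability at low noise and exact fiducials, so end-to-end scores (BCR
≈ 0.94–0.99 on held-out synthetic patients) demonstrate that the pipeline
is correctly wired and leakage-free — not that comparable accuracy would
be reached on clinical data, where delineation error, artifact, rhythm
context and pathology diversity are far richer.  Structural findings
(normalized R-R ranking first; weighting rescuing minority recall under
noise) are reproduced directionally, not numerically.

## Evaluation protocol and problem sizes

Training and test beats come from disjoint patients; per-patient
statistics (normalization means, imputation means, and the MI histogram
ranges, which are computed on the training split) never cross the split.
The bundled demonstrations use cohorts of 6–9 simulated patients with
150–250 beats each and a reduced SVM grid (degrees 1–3, C ∈ 0.1…100) —
sizes chosen so the full suite runs in well under a minute of extraction
time while every minority class still appears on both sides of the split.
The full degree 1–4 × 11-point C grid remains the default of
`loo_patient_cv` for real use.

## Numerical and convention choices

* Tie-breaking is deterministic everywhere: lowest class index for
  classifier votes, earlier column for equal MI, smaller σ for equal
  Hermite error, smaller degree then smaller C for equal CV score.
* The filter defaults (two cascaded running medians of 0.2 s and 0.6 s,
  zero-phase 4th-order Butterworth low-pass at 35 Hz) follow the filtering
  lineage customary for this task; medians use centered, edge-truncated
  windows so length is preserved, which makes the cascade only
  approximately idempotent near edges (tested to <5 % energy change).
* WFDB-style I/O quantizes amplitudes at the header gain (default
  200 adu/mV, 12-bit two's complement); the CSV dialect is lossless
  (`%.17g` on write, round-trip float parsing on read).
* Fiducial marks read from annotation streams are attached to the beat
  whose R spike is nearest *after correcting for the point's expected
  offset from R* (a T offset ~0.42 s after its own R can be nearer the
  next premature beat's R); ordering violations are dropped to ABSENT
  with a warning count, never by removing beats.
* Q and S peak marks have no standard code in the delineation vocabulary;
  the WFDB-style dialect carries them with the MEASURE code (num 1/2), a
  documented extension that keeps files readable by standard tools.

## Known limitations

* The synthetic generator has no rhythm context (no bigeminy, AF, or
  rate trends), no notched/biphasic QRS shapes, and no electrode artifact
  bursts; morphology diversity is parametric, not sampled from data.
* The wrapper search is greedy; it is not guaranteed to find the optimal
  subset, only a locally improving path (the standard trade-off that makes
  it O(P·k) instead of O(2^P)).
* MI ranking is univariate: redundant copies of one physical quantity
  (e.g. the reference and detected previous R-R) rank adjacently, and
  complementarity between features is invisible to the filter route.
* The SVM route exposes no probability calibration, and only the
  polynomial kernel is wired (matching the design it implements).
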