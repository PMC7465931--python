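# Methods

This note documents the models, estimators and design choices behind
`rettnet`, what the synthetic-data generator does and does not emulate, and
the numerical conventions that make results reproducible.

## Study structure being emulated

The analysis targets a two-group, two-timepoint observational design:
patients with classic Rett syndrome either treated with IGF1 (n = 9) or
untreated (n = 9), each with a resting-state EEG and an ISS clinical
severity assessment at baseline and at twelve months.  Treated patients are
split into responders and nonresponders by a strict decrease of ISS from
baseline to twelve months (equal scores count as nonresponse).  The
bundled reference table (`rettnet/data/table1.tsv`) carries the published
individual-level demographics; applying the strict-decrease rule to it
yields five responders and four nonresponders.  Demographic summaries use
the median and Tukey-hinge IQR for age and the mean with sample (n−1) SD
for ISS, because those conventions reproduce the published group summaries
from the individual rows.  (One published group figure does not round
consistently with the table: the untreated baseline ISS mean computes to
17.56, printed as 17.5; the summary code reports the computed value.)

## Signal model and synthetic cohorts

A recording is modelled as a linear mixture of shared band-limited
Gaussian sources plus independent channel noise:

x_i(t) = Σ_k w_ik s_k(t) + n_i(t)

* Sources `s_k` have a flat power spectrum inside a declared band and zero
  power outside; they are synthesised in the frequency domain and scaled to
  their target variance.
* Noise `n_i` has PSD ∝ f^(−α) over [0.5 Hz, Nyquist), α = 1 by default —
  a realistic resting-EEG spectral slope.  Because the noise is independent
  across channels it contributes no cross-spectrum, so the expected
  coherence of a pair sharing a single source is available in closed form
  (the `analytic_pair_coherence` oracle); the band-averaged forward model
  `expected_pair_coherence` additionally accounts for the 1/f variation of
  the noise floor across a band.

Cohort designs inject coherence structure with two source types: one
*background* source shared by all electrodes (setting a common baseline
coherence, default 0.2–0.3), and dedicated *pair* sources that raise the
coherence of a named electrode pair in a named design cell.  Source
weights are calibrated by bisection against the band-averaged forward
model, with a short fixed-point pass so that pair sources sharing an
electrode (e.g. O1–O2 together with F3–O1) still hit their targets despite
mutual power dilution.  Calibration is exact for the targeted pairs;
untargeted pairs involving a targeted electrode sit marginally below the
background level.  Only coherence *elevations* are realisable in this
parameterisation; a design requesting a target below background raises a
design error.

Per-subject variability enters as a Gaussian jitter of the background
coherence level (SD 0.03 by default), which produces the correlated
between-subject feature structure the PCA and architecture stages need.
The source band extends slightly past the 0.5–30 Hz analysis range
(default top edge 32 Hz) so that scored bands lie in the source interior:
Hann-window leakage otherwise dilutes coherence in the edge bins of a
source band.

Generator defaults mirror the study conditions: 20-minute recordings
(`duration=1200`), eight channels, two timepoints.  The sampling rate is
not stated for the original recordings; the generator defaults to 128 Hz,
which keeps Nyquist well above the 40 Hz filter edge.  ISS scores are
drawn as Normal(17.4, 4.5) truncated to [0, 40] and rounded; responders
improve by Uniform{1..6} points, nonresponders change by Uniform{0..1},
untreated subjects drift by Uniform{−1..5} (ranges read off the reference
table).  Ages are integers from a truncated Normal(7, 4) on [2, 15].
Responder labels in generated clinical tables are always *recomputed* from
the generated ISS values by the strict-decrease rule, never copied from
the design.

A faster feature-level generator (`generate_coherence_features`) draws the
28 pair features directly as cell target + Gaussian noise (SD 0.05 by
default), for studies of the downstream statistics and classifier where
signal synthesis adds nothing.  The emulated responder-prediction cohort
(`response_study_design`) uses +0.3 at O1–O2 and +0.15 at the four
frontal–occipital pairs at baseline, reflecting the finding that the
occipital interhemispheric pair dominates the responder difference.

What the generator does **not** emulate: epileptiform and movement
artifacts, volume conduction / reference effects (no leadfield forward
model), nonstationarity within a recording, and negative coherence
effects.  Tests passing on synthetic cohorts therefore show that the
estimators and statistics behave correctly under the stated generative
model, not that the pipeline is robust to every pathology of clinical EEG.

## Preprocessing

Recordings are band-pass filtered 0.5–40 Hz (4th-order Butterworth,
zero-phase `sosfiltfilt`), optionally notch-filtered at mains frequency,
and cut into non-overlapping 2-s epochs.  Epochs whose absolute amplitude
exceeds a threshold (default 100, read as µV for clinical data) are
dropped with a reason code; this amplitude criterion is a deliberate,
simple stand-in for manual artifact and epileptiform review, whose exact
protocol for the original recordings is not public.  The montage is
F3, F4, T3, T4, P3, P4, O1, O2 — left/right homologues over frontal,
temporal, parietal and occipital cortex, sufficient to express every
regional claim the analysis makes.  At least one kept epoch is required
downstream; coherence additionally requires two averaging segments, since
single-segment coherence is identically 1.

## Spectral and coherence estimation

Power spectra are Welch averages of Hann-windowed, mean-removed segments
(2 s, 50% overlap within kept epochs; one segment per epoch at the default
epoch length), with one-sided density scaling identical to
`scipy.signal.welch`.  Band power integrates the PSD over half-open
[lo, hi) bands — delta 0.5–4, theta 4–8, alpha 8–13, beta 13–30 Hz — which
tile the 0.5–30 Hz analysis range exactly, so per-channel relative powers
sum to 1.  Overall power is reported in dB re 1 unit²/Hz; only dB
*differences* are ever interpreted, so the reference is immaterial.
Hemispheric asymmetry is left-minus-right dB power per homologous pair,
per region (one pair per region in this montage) and averaged over the
hemisphere, overall and per band; it is exactly antisymmetric under
swapping hemispheres.

Coherence uses the same segments: C(ω) = |S_xy|²/(S_xx S_yy) with
segment-averaged spectra, then the arithmetic mean of per-frequency
coherence across each band ("overall" averages 0.5–30 Hz).  The estimator
has the classical positive bias E[Ĉ] ≈ 1/m for independent signals with m
averaging segments; a 20-minute recording gives m = 600 and a negligible
floor, but short recordings should be interpreted against 1/m.  The 28
unique pairs are flattened in a fixed canonical order (upper triangle of
the montage-ordered matrix, O1–O2 last) shared by every file and module.

## Network loadings and architecture

PCA is fitted once on the stacked subject × timepoint feature rows (all
groups and cells together) so that scores live in a common basis and can
be compared across cells; fitting per cell would make loadings
incomparable.  Features are centred but not variance-standardised — all
are coherences on one [0, 1] scale, and raw covariance preserves the
architecture interpretation.  Loadings are sign-fixed (largest-magnitude
element positive) for reproducible reporting.  The retained component
count is the smallest k reaching 90% cumulative explained variance
(configurable).  Architecture matrices are sample covariances (optionally
correlations) of the 28 features within one group × timepoint cell.

Which quantity the original analysis fed into its ANOVA ("network
loadings") is ambiguous between scores, loading values and several
components jointly; this package analyses the retained component *scores*,
one ANOVA per component, and treats the first component as primary.  That
is a documented package choice, not an attested protocol.

## Statistics

The mixed-design repeated-measures ANOVA uses the classical decomposition:
between-subjects variation splits into group and subject-within-group
error; within-subjects variation into time, group × time, and
time × subject-within-group error; each F tests against its matching
error term.  With every subject observed at every timepoint the
decomposition is exactly orthogonal even for unequal group sizes (5/4,
9/9), and the implementation is verified to 1e-8 against a brute-force
design-matrix least-squares oracle and against an independent
implementation.  Missing timepoints raise an error — listwise deletion is
never silent.

Mann-Whitney U is exact (full enumeration) when the combined sample is
≤ 12 without ties, otherwise a tie-corrected normal approximation with
continuity correction; Wilcoxon signed-rank drops zero differences, is
exact for ≤ 15 effective pairs (sign-assignment enumeration, valid under
tied midranks) and tie-corrected normal beyond.  All tests are two-tailed.
Post hoc per-pair tables report the uncorrected p thresholded at α = 0.05
— matching the exploratory post hoc convention of the original analysis —
with a Bonferroni-adjusted column always emitted alongside rather than
silently substituted.

## Response prediction

The classifier is a linear SVM (C = 1) with per-feature standardisation
fitted on training folds only; with two to five features and nine
subjects, any separating kernel is equivalent and linear is the minimal
choice.  Features enter ranked by the baseline responder-vs-nonresponder
post hoc test: ascending p, ties broken by descending |median group
difference| and then canonical pair order.  The effect-size tie-break is
needed because the exact Mann-Whitney p saturates at its minimum (2/126
for n = 5 + 4) whenever a feature fully separates the groups, so p alone
cannot order two fully separated features.

Cross-validation uses k = 5 seeded folds, sizes as equal as possible
(four folds of two and one of one for n = 9), stratified when both class
counts allow (with 4 nonresponders and k = 5 they do not; plain shuffled
folds are used, and with n = 9 a training fold can never lose a class).
The confusion matrix pools all held-out predictions; accuracy, sensitivity
(responder recall) and specificity are recomputed from it.  Sequential
elimination retrains after dropping the worst-ranked remaining feature
down to a single-feature model.

Faithful to the emulated analysis, feature selection runs once on the full
baseline contrast *before* cross-validation.  This leaks held-out
information into feature choice; every report carries the caveat, and a
`nested` mode reselects features inside each training fold.  Nested
selection at α = 0.05 meets a small-sample wall: a leave-two-out training
fold (4 + 3) cannot reach p < 0.05 on an exact rank test (minimum
2/35 ≈ 0.057), so when nothing passes, the nested mode keeps the single
best-ranked feature rather than refusing to train.

## Numerical conventions and degenerate inputs

* One master seed per cohort; per-subject, per-timepoint streams derive
  from (seed, subject index, timepoint index), so recordings and tables
  are bit-identical across runs and subjects are independently seeded.
* Recordings round-trip bit-exactly through the delimited matrix format
  (17 significant digits; `float_precision="round_trip"` on read).  EDF
  files are read (via MNE, labels normalised and reordered to the
  canonical montage) but not written.
* Weight calibration bisects to a relative tolerance of ~1e-6; coherence
  values are clipped to [0, 1] after estimation.
* Degenerate inputs raise typed errors rather than propagating NaN: zero
  total power, a single averaging segment, all epochs rejected, a missing
  electrode, an unrealisable design target, all-zero paired differences,
  an empty feature selection.

## Problem sizes used in the calibration suite

The test battery runs at sizes chosen to make each check sharp while the
whole suite stays quick: coherence-oracle convergence uses three SNRs at
the full 20-minute study duration (tolerance ±0.02); the estimator-bias
floor uses 1,000 ten-segment simulations (±20% relative); ANOVA null
calibration uses 2,000 simulated datasets (Kolmogorov–Smirnov distance
< 0.05); the post hoc type-I check uses 1,000 null cohorts of 10 + 10
(28 pairs each); parameter recovery uses 10 + 10 subjects at five-minute
durations (±0.05) plus 200 feature-level ranking replicates.

## Known limitations

* The amplitude scale and reference scheme of the original recordings are
  unknown; simulated units are arbitrary, which is harmless for coherence
  (scale-free) but means absolute dB powers are only internally
  comparable.
* Epileptiform-discharge rejection is approximated by the amplitude
  criterion alone.
* The real patient EEGs are not public, so the original per-effect
  p-values and covariance figures are not reproducible; the package
  verifies its statistical machinery by calibration and parameter
  recovery on synthetic cohorts instead.
* With n = 9, cross-validated accuracy has a granularity of 1/9 and the
  selection-before-CV protocol is optimistic; the emulated 100% accuracy
  demonstrates the pipeline on strongly separated synthetic data, not
  clinical performance.
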