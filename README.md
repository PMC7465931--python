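# rettnet

Resting-state EEG coherence-network analysis of treatment response in Rett
syndrome.

Rett syndrome (RTT) is a neurodevelopmental disorder, usually caused by
*MECP2* mutations, in which cortical network formation is disrupted.
Insulin-like growth factor 1 (IGF1) is an investigational treatment whose
clinical effect varies strongly between patients.  `rettnet` implements, as
a tested and reusable pipeline, an electrophysiological analysis of that
variability: from eight-channel resting-state EEG it derives spectral and
network features, tests whether treatment and clinical response are
associated with changes in functional network architecture, and asks
whether the *pretreatment* network state predicts who will respond.

Because clinical EEG recordings of this kind are not publicly available,
the package ships a first-class synthetic-data generator that emulates the
study design — two groups of nine patients assessed at baseline and twelve
months, with responder status defined by a strict decrease of the
International Scoring System (ISS) severity score — and whose cross-channel
coherence structure is known in closed form, so every stage of the pipeline
is testable against an analytic oracle.

## The measures

**Magnitude-squared coherence.**  For channels x and y with cross-spectrum
S_xy and auto-spectra S_xx, S_yy (Welch-averaged over 2-s Hann windows),

    C(ω) = |S_xy(ω)|² / (S_xx(ω) · S_yy(ω))  ∈ [0, 1],

computed for all 28 unique electrode pairs of the F3, F4, T3, T4, P3, P4,
O1, O2 montage, band-averaged over the overall range (0.5–30 Hz) and the
delta/theta/alpha/beta bands.

**Network loadings.**  Principal components of the 28-dimensional coherence
feature vectors, fitted once across all subject × timepoint rows so that
component scores are comparable between design cells; covariance
"architecture" matrices summarise each cell's network structure.

**Statistics.**  Two-way mixed repeated-measures ANOVA (between: group;
within: timepoint) on component scores, with Mann-Whitney U and Wilcoxon
signed-rank post hoc tests per electrode pair (uncorrected p thresholded at
0.05, Bonferroni column reported alongside).

**Prediction.**  A linear SVM on the baseline coherence features that
separate responders from nonresponders, validated by stratified five-fold
cross-validation and pruned by sequential elimination of the least
significant feature.

The synthetic generator mixes band-limited Gaussian sources into channels
over independent 1/f noise; for a source shared by two channels with
weights w_i, w_j, the expected coherence is
(w_i w_j σ_s²)² / ((w_i² σ_s² + σ_n²)(w_j² σ_s² + σ_n²)), which the
generator inverts to inject group-, responder- and timepoint-specific
coherence effects at named electrode pairs.

## Worked example

```python
from rettnet import (FeatureTable, PredictorSpec, ResponsePredictor,
                     classify_responders, generate_coherence_features,
                     load_reference_cohort, response_study_design, summarize)

# demographics of the bundled 18-patient reference table
print(summarize(classify_responders(load_reference_cohort())).summary())

# emulated responder cohort -> cross-validated response prediction
feats, clinical = generate_coherence_features(response_study_design(seed=0),
                                              noise_sd=0.05)
report = ResponsePredictor(FeatureTable(feats),
                           spec=PredictorSpec(seed=0)).fit(k=5)
print(report.summary())
```

This prints

```
Cohort summary (age: median [hinge IQR]; ISS: mean +/- sample SD)
             n  age_median  age_iqr  iss_t1_mean  iss_t1_sd  n_responders  n_nonresponders
treated    9.0         4.0      5.0         17.3        3.7           5.0              4.0
untreated  9.0         8.0      7.0         17.6        5.4           0.0              0.0
overall   18.0         6.0      6.0         17.4        4.5           5.0              4.0

Treatment-response prediction (5-fold cross-validation, mode=standard)
============================================================
features (5): O1-O2, F3-O2, F4-O2, F4-O1, F3-O1
n=9  TP=5  FP=0  TN=4  FN=0
accuracy:    1.000
sensitivity: 1.000
specificity: 1.000
```

The cohort summary reproduces the reference demographics (overall median
age 6 years with hinge IQR 6; baseline ISS 17.4 ± 4.5; five treated
responders and four nonresponders under the strict-decrease rule).  On the
emulated cohort — whose responders carry elevated baseline occipital
interhemispheric (O1–O2, +0.3) and frontal–occipital (+0.15) coherence —
feature selection recovers exactly those pairs, and the pooled five-fold
confusion matrix classifies all nine subjects correctly.  The report also
carries a caveat that feature selection ran before cross-validation; a
`nested` mode performs selection inside each training fold.

## Command line

```bash
rettnet simulate  --design design.yaml --out cohort/ --seed 1
rettnet extract   --recordings cohort/recordings --out features/
rettnet network   --features features/coherence_features.csv \
                  --clinical cohort/clinical.csv --out net/
rettnet stats     --features features/coherence_features.csv \
                  --clinical cohort/clinical.csv --scores net/network_scores.csv --out stats/
rettnet predict   --features features/coherence_features.csv \
                  --clinical cohort/clinical.csv --out pred/ --seed 1
rettnet run-all   --config demo_config.yaml   # bundled in rettnet/data/
```

`run-all` writes a manifest with SHA-256 checksums of every output;
identical configurations and seeds reproduce byte-identical results.
Feature extraction never sees the clinical table (blind processing).

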