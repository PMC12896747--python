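# Methods

## Pipeline model

A sample is a short time series of full-scan (MS1) centroided spectra from
an ambient ion source; there is no chromatographic separation, so the
"retention" axis is just the sampling window (default 5 s). The pipeline
assumes (i) spectra mix linearly in the volume fractions of the
constituent oils, and (ii) the class-discriminative information is
localized in m/z: volatile and semi-volatile ions chiefly in 100–300, and
triglyceride ions in 800–1000. Both assumptions are what the fingerprint
design exploits; neither is enforced on real data, but the binning
configuration concentrates resolution where they hold.

## Dynamic binning and aggregation

Each configured interval (start, end, step) expands into contiguous
half-open sub-bins `[lo, lo + step)`. Half-open is the standard histogram
convention; a peak exactly at an interval's end is excluded. When the
interval width is not an integer multiple of the step, the final sub-bin
is truncated to end exactly at the interval end, so the configured range
is always covered and never exceeded. The packaged default configuration
(92 intervals → 666 sub-bins over m/z 75–1000) consists of the 74.99–75.11
interval at 0.01 Da, 64 narrow ±0.03 Da marker windows at 0.01 Da steps
concentrated in the volatile and triglyceride regions, and 27 coarse
survey intervals at 0.5 Da steps; all widths are exact step multiples.

Temporal aggregation computes max, mean, median, SD and sum per sub-bin
across scans, laid out bin-major (all five statistics of bin 0, then
bin 1, …). The layout is a fixed contract because downstream models are
layout-sensitive. SD uses the population convention (divide by n) so a
single-scan series yields 0 rather than NaN.

The eight TIC descriptors are, in fixed order: trapezoidal area, time of
the TIC maximum (first occurrence on ties — the "main peak" of an ambient
acquisition), SNR = max / (MAD·1.4826) guarded to the scan count when the
MAD is 0, count of local maxima with prominence ≥ 5% of the TIC maximum
(a config knob), intensity-weighted skewness and excess kurtosis of the
time profile (defined as 0 for a constant TIC), main-peak height, and
main-peak FWHM at half prominence (0 when no peak is resolvable). Height
and FWHM complete the descriptor set with cheap, deterministic shape
information. Shape statistics require ≥ 3 scans. The five statistics are
computed over the full acquisition window.

## Feature importance and bin refinement

One-way ANOVA F is computed directly (between-group over within-group mean
square); a feature with zero within-class variance but distinct means gets
a +inf sentinel that ranks above every finite score, with ties broken
toward lower m/z for determinism. Mutual information uses the
k-nearest-neighbour estimator (k = 3, configurable) for continuous
features against discrete labels; constant features are forced to exactly
0. Random Forest importance is the mean impurity decrease of a seeded
100-tree forest, normalized to sum to 1. Pearson r against the
adulteration fraction returns 0 for constant features by convention and
rejects a constant target. Refinement keeps the top-k anchors per score
table (|r| for Pearson), expands each to ±window (default 0.03 Da), and
merges overlapping or touching intervals; the merge is idempotent and the
output is a valid, sorted, disjoint bin configuration with a default
0.01 Da step. The number of score tables and k are free parameters: which
scoring files feed the refinement is a user decision, not something the
pipeline fixes.

## Representations

NON passes features through unchanged. PCA and UMAP operate on
per-feature z-scores; the scaler is fit on the training set and its
statistics are applied to later data, so fitted embedders project unseen
samples consistently. PCA defaults to the smallest number of components
retaining 95% of the variance; UMAP defaults to 2 components, 15
neighbours, min_dist 0.1, and is seeded, which makes it single-threaded
and run-to-run identical. Requesting more PCA components than the data
rank truncates with a warning.

## Networks

The Conv–Attention–MLP is implemented in NumPy with explicit
backpropagation (verified against central finite differences in the test
suite). The convolutional branch applies two same-padded 1D convolutions
(64 filters of width 5, then 256 of width 3, ReLU), a
squeeze-and-excitation channel-attention block (reduction 8), a
convolutional spatial-attention gate (width 7 over channel-mean and
channel-max maps), and global max pooling. The parallel MLP branch is a
64-unit layer with one residual block. Branches are fused by a 64-unit
dense layer into a softmax head: class probabilities for the classifier
(cross-entropy), or the five oil fractions for the quantifier (MSE on the
simplex — the softmax guarantees non-negative fractions summing to 1 for
any input, in- or out-of-distribution). Training uses Adam (initial
learning rate 1e-3, batch 32, ≤ 200 epochs), halving the learning rate
after 10 stagnant epochs, early stopping after 20, and restoring the best
weights; the monitored loss is a held-out validation slice (20% of the
training data for the quantifier). Attention realized as SE gating plus a
single-channel spatial gate, and the training schedule itself, are this
package's concrete design choices.

The other four classifiers delegate to scikit-learn with fixed seeds:
RandomForest(n_estimators=100, random_state=42), SVC(kernel="linear",
class_weight="balanced", random_state=42), LogisticRegression(seeded,
max_iter=2000), GradientBoosting(n_estimators=100, learning_rate=0.1,
max_depth=3, random_state=42). SVM probability calibration is off;
decision values are squashed through a logistic map, which is monotone and
therefore AUC-preserving. Data splits are stratified 8:2 with seed 42,
falling back to unstratified (with a warning) when a class has one sample.

## Evaluation conventions

Multiclass precision/recall/F1 are reported per class plus macro
(unweighted mean) and micro (pooled — equal to accuracy for single-label
problems) aggregates; an empty predicted or true class contributes 0 with
a warning. Multiclass AUC is one-versus-rest; the macro average is the
headline number and micro is also reported. RPD uses the n−1 sample SD of
the prediction-set true values; a perfect prediction reports RPD = +inf.
Repeated-run aggregation spawns per-run seeds from a base seed and
reports mean ± SD (n−1) per metric, retaining per-run values. Blind
evaluation enforces sample-id disjointness from the training set and
emits a per-sample misclassification ledger.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the study's design structure exactly: 132 binary,
198 ternary, 132 quaternary and 33 quinary mixtures (4 adulterants, 11
gradient levels from 3% to 90% v/v, 3 replicates, adulterants premixed in
equal volumes), plus pure-oil controls. Spectra are linear mixtures of
five per-class peak libraries built on the marker-window centres of the
default bin configuration — each class owns 8 strong private ions in
100–300 and 2 in 800–1000 over a shared backbone — with per-scan
unit-mean lognormal intensity noise (CV 5%), an additive baseline (0.1% of
the strongest peak), Gaussian m/z jitter (SD 0.002 Da), and a
rise–plateau–fall acquisition envelope over 25 scans in 5 s. The noise
level was chosen so that classifiers perform strongly without the task
being trivial.

What it does **not** emulate: ionization physics and matrix effects,
nonlinear ion suppression between oils, isotope patterns, real volatile
chemistry beyond region-level structure, batch and instrument drift, and
biological variability between oil brands. Passing tests therefore
demonstrate that the pipeline's machinery is correct and that the models
can recover composition under the stated noise model — not that the
reported performance transfers to real oils.

Problem sizes used in the tests and the acceptance script — ~600 samples
for quantification (495 mixtures + 21 pure replicates per class) and 795
for the qualitative task (495 + 60 pure per class) — were chosen as
desk-scale analogues of the study design. The qualitative set carries more
pure-CAO replicates deliberately: with only a handful of pure samples the
pure-vs-adulterated task degenerates into majority-class prediction, and a
headline accuracy would be meaningless. Performance checks assert both the
threshold and superiority over the majority rate.

## Numerical choices and degenerate inputs

Binning uses `searchsorted` on sorted peak lists with a cumulative-sum
trick, so it is exact (no floating accumulation across peaks) and
permutation-invariant. Interval merging treats touching endpoints (within
1e-12) as overlapping. mzXML writing encodes 64-bit network-byte-order
m/z–intensity pairs; reading converts pyteomics' minute-based retention
times back to seconds and skips MS2 scans. Lognormal noise uses
sigma² = ln(1 + CV²) with mean correction so the expected spectrum is
unbiased. Fractions must sum to 1 within 1e-9. Empty prediction inputs
return empty outputs; dimension mismatches name the expected and actual
sizes.

## Known limitations

- The quantifier's accuracy degrades for oils whose private ions overlap
  heavily in a mixture (RPD for SOO is typically the lowest of the five).
- UMAP's `transform` on unseen data is approximate by construction;
  classifiers trained on UMAP features inherit that variance.
- The NumPy network is single-threaded; it is sized for reduced
  (PCA/UMAP) inputs, and training it on full 3338-length vectors is
  supported but slow.
- The mzXML writer emits the minimal subset of the format the reader
  consumes (no index, no instrument metadata).
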