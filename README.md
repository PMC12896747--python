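# oilauth

Camellia oil (*Camellia oleifera* seed oil, CAO) commands a premium price
and is routinely adulterated with cheaper vegetable oils — corn (COO),
olive (OLO), soybean (SOO) and sunflower (SUO) — singly or in multi-oil
blends. `oilauth` implements an ambient-ionization mass-spectrometry
fingerprinting pipeline for detecting and quantifying such adulteration:
full-scan positive-mode spectra (m/z 75–1000) acquired over a short
sampling window are turned into fixed-length fingerprints, screened by
feature-importance analysis, and fed to a suite of machine-learning models
for qualitative classification and quantitative composition prediction.
It is aimed at food-authenticity and chemometrics researchers who want a
tested, reproducible reference implementation, including a synthetic data
generator so every stage can be exercised without instrument data.

## Method

**Fingerprinting.** Each sample is a time series of MS1 scans. The m/z
axis is partitioned by *dynamic binning*: 92 configured intervals, each
defined by a start, end and step (e.g. 0.01 Da over 74.99–75.11), expand
into 666 half-open sub-bins whose peak intensities are summed per scan.
The scans × 666 matrix is aggregated along time with five statistics per
sub-bin (max, mean, median, SD, sum → 3330 values, bin-major), and eight
descriptors of the total ion chromatogram (area, main-peak time, SNR,
peak count, intensity-weighted skewness and excess kurtosis, main-peak
height and FWHM) are appended, giving a 3338-dimensional feature vector.

**Feature selection.** ANOVA F, mutual information, Random Forest
importance and Pearson correlation rank m/z features; the top-k anchors of
each score table are expanded to ±0.03 Da windows and merged into a
refined bin configuration.

**Models.** Three input representations (NON = raw, PCA, UMAP) feed five
classifiers — a 1D Conv–Attention–MLP network (two conv layers with 64 and
256 filters, kernels 5 and 3, channel + spatial attention, global max
pooling, residual MLP branch), Random Forest, linear SVM, logistic
regression and gradient-boosted trees — for pure-vs-adulterated and
multiclass tasks. The same dual-branch network with a 5-way softmax head,
trained with Adam on an MSE loss with early stopping, predicts the volume
fractions of the five oils. The networks are implemented in NumPy with
explicit backpropagation, verified against finite differences.

**Evaluation.** Classification: accuracy, precision, recall, F1 and ROC
AUC (one-versus-rest for multiclass), confusion matrices and blind-set
misclassification ledgers. Quantification follows chemometric convention:
R²C/RMSEC on the calibration set, R²P/RMSEP on the held-out prediction
set, and RPD = SD/RMSEP (SD of the true values in the prediction set,
n−1 convention), with RPD > 3.0 the accepted threshold for a model fit
for quantitative use.

**Synthetic data.** The generator enumerates the full adulteration design
— binary/ternary/quaternary/quinary blends of CAO with 1–4 adulterants at
3, 5, 10, 20, …, 90% (v/v), three replicates (132/198/132/33 samples) —
and simulates scan series by linear spectral mixing of per-class peak
libraries whose discriminative ions sit in the volatile (m/z 100–300) and
triglyceride (800–1000) regions, with lognormal intensity noise (CV 5%),
additive baseline, m/z jitter and a rise–plateau–fall acquisition
envelope.

## Worked example

```python
import numpy as np
from oilauth import default_bin_config, make_profile_library, synth
from oilauth.featurize import expand_bins, featurize_dataset
from oilauth.embed import EmbedConfig, fit_transform
from oilauth.evaluate import classification_report, regression_report
from oilauth.models import (ClassifierSpec, QuantifierSpec, binary_label,
                            split_data, task_labels, train_classifier,
                            train_quantifier)

config = default_bin_config()
grid = expand_bins(config)
library = make_profile_library(42, bins=config)

# qualitative: pure vs adulterated on raw fingerprints
designs = synth.enumerate_design()                      # 495 mixtures
samples = synth.simulate_dataset(library, designs, synth.NoiseModel(),
                                 pure_replicates=60, seed=7)
records = featurize_dataset(samples, grid)
print(f"{len(records)} samples x {records[0].vector.size} features")
labels = [binary_label(r.label) for r in records]
train, test = split_data(records, 0.2, seed=42, labels=labels)
clf = train_classifier(ClassifierSpec(kind="rf"), train, "binary")
x_test = np.vstack([r.vector for r in test])
rep = classification_report(task_labels(test, "binary"), clf.predict(x_test),
                            clf.predict_proba(x_test), classes=clf.classes_)
print(f"RF binary accuracy {rep.accuracy:.3f}  AUC {rep.auc['roc']:.3f}")

# quantitative: PCA features + Conv-Attention-MLP composition model
samples = synth.simulate_dataset(library, designs, synth.NoiseModel(),
                                 pure_replicates=21, seed=7)
records = featurize_dataset(samples, grid)
train, test = split_data(records, 0.2, seed=42)
z_train, embedder = fit_transform(np.vstack([r.vector for r in train]),
                                  EmbedConfig(method="pca"))
quant = train_quantifier(QuantifierSpec(seed=42), train, features=z_train)
pred = quant.predict(embedder.transform(np.vstack([r.vector for r in test])))
true = np.vstack([r.fractions for r in test])
reg = regression_report(true[:, 0], pred[:, 0])
print(f"CAO fraction: R2P {reg.r2_p:.3f}  RMSEP {reg.rmse_p:.3f}  "
      f"RPD {reg.rpd:.2f}")
```

prints

```
795 samples x 3338 features
RF binary accuracy 1.000  AUC 1.000
CAO fraction: R2P 0.949  RMSEP 0.080  RPD 4.43
```

The Random Forest separates pure from adulterated camellia oil perfectly
on the raw fingerprints (the hardest cases are the 3% adulteration
levels), and the PCA-featured quantifier recovers the camellia-oil volume
fraction on held-out mixtures with an 8% RMSEP and an RPD of 4.4 — above
the 3.0 threshold for quantitative applicability.

The same workflow is available from the shell:

```bash
oilauth simulate  --out raw/ --seed 42
oilauth featurize --in raw/ --out features.csv
oilauth train     --features features.csv --out model/ \
                  --task binary --model rf --embed non
oilauth evaluate  --features features.csv --model-dir model/ --out report.json
```

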