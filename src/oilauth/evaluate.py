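"""Model evaluation: classification reports, chemometric regression
statistics (R2, RMSE, RPD), repeated-run aggregation and blind-set audits.

Binary classification treats "adulterated" as the positive class.
Multiclass precision/recall/F1 are reported per class plus macro
(unweighted mean) and micro (pooled) aggregates; multiclass AUC uses
one-versus-rest binarizations with the macro average as the headline
number. The regression bundle follows chemometric convention: R2C/RMSEC on
the calibration set, R2P/RMSEP on the prediction set, and
RPD = SD(true, prediction set) / RMSEP with the n-1 sample SD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn import metrics as _skm

from .models import BINARY_POSITIVE


@dataclass
class ClassificationReport:
    accuracy: float
    precision: dict[str, float]          # per class + "macro" + "micro"
    recall: dict[str, float]
    f1: dict[str, float]
    auc: dict[str, float] | None         # binary: {"roc"}; multiclass OvR
    confusion: np.ndarray                # true x predicted counts
    classes: np.ndarray
    n_misclassified: int

    def summary(self) -> dict[str, float]:
        """Headline numbers in Table form: accuracy, macro P/R/F1, AUC."""
        out = {"accuracy": self.accuracy,
               "precision": self.precision["macro"],
               "recall": self.recall["macro"],
               "f1": self.f1["macro"]}
        if self.auc is not None:
            out["auc"] = self.auc.get("roc", self.auc.get("macro"))
        return out


@dataclass
class RegressionReport:
    """Chemometric regression metrics for one target variable."""

    r2_c: float | None = None
    rmse_c: float | None = None
    r2_p: float | None = None
    rmse_p: float | None = None
    rpd: float | None = None


def _prf(tp: float, denom: float) -> float:
    if denom == 0:
        warnings.warn("empty class in precision/recall; reporting 0",
                      RuntimeWarning, stacklevel=3)
        return 0.0
    return tp / denom


def classification_report(y_true, y_pred, scores=None,
                          classes=None) -> ClassificationReport:
    """Standard classification metrics with per-class and aggregate views.

    ``scores`` (n x n_classes probabilities, or a 1-D positive-class score
    for binary problems) enables AUC; without it AUC is omitted. ``classes``
    fixes the score-column order; by default it is the sorted union of true
    and predicted labels.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("true/predicted label length mismatch")
    if classes is None:
        classes = np.unique(np.concatenate([y_true, y_pred]))
    classes = np.asarray(classes)
    if not set(np.unique(y_true)) <= set(classes.tolist()):
        raise ValueError("true labels outside the provided class set")
    cm = _skm.confusion_matrix(y_true, y_pred, labels=classes)
    n = cm.sum()
    acc = float(np.trace(cm) / n)
    precision, recall, f1 = {}, {}, {}
    for j, c in enumerate(classes):
        p = _prf(cm[j, j], cm[:, j].sum())
        r = _prf(cm[j, j], cm[j, :].sum())
        precision[str(c)] = float(p)
        recall[str(c)] = float(r)
        f1[str(c)] = float(2 * p * r / (p + r)) if (p + r) else 0.0
    precision["macro"] = float(np.mean([precision[str(c)] for c in classes]))
    recall["macro"] = float(np.mean([recall[str(c)] for c in classes]))
    f1["macro"] = float(np.mean([f1[str(c)] for c in classes]))
    # single-label micro aggregates all equal accuracy
    precision["micro"] = recall["micro"] = f1["micro"] = acc

    auc: dict[str, float] | None = None
    if scores is not None:
        scores = np.asarray(scores, dtype=float)
        auc = {}
        if classes.size == 2:
            # positive class: "adulterated" when present, else the second
            # label; 1-D scores are read as the positive-class score
            pos_label = BINARY_POSITIVE if BINARY_POSITIVE in classes \
                else classes[1]
            j = int(np.where(classes == pos_label)[0][0])
            pos = scores if scores.ndim == 1 else scores[:, j]
            mask = y_true == pos_label
            if mask.any() and not mask.all():
                auc["roc"] = auc_roc(mask, pos)
            else:
                warnings.warn("single class in truth; AUC omitted",
                              RuntimeWarning, stacklevel=2)
        else:
            if scores.ndim != 2 or scores.shape[1] != classes.size:
                raise ValueError("scores must have one column per class")
            per, present = [], []
            for j, c in enumerate(classes):
                mask = y_true == c
                if mask.any() and not mask.all():
                    a = auc_roc(mask, scores[:, j])
                    auc[f"ovr_{c}"] = a
                    per.append(a)
                    present.append(j)
            auc["macro"] = float(np.mean(per))
            # micro: pool all OvR decisions
            ybin = np.zeros((y_true.size, classes.size), dtype=bool)
            for j, c in enumerate(classes):
                ybin[:, j] = y_true == c
            auc["micro"] = auc_roc(ybin.ravel(), scores.ravel())
    return ClassificationReport(
        accuracy=acc, precision=precision, recall=recall, f1=f1, auc=auc,
        confusion=cm, classes=classes,
        n_misclassified=int(n - np.trace(cm)))


def auc_roc(y_true, scores) -> float:
    """ROC AUC — the Mann–Whitney probability that a random positive scores
    above a random negative, ties counted half."""
    y = np.asarray(y_true).astype(bool)
    s = np.asarray(scores, dtype=float)
    if y.all() or not y.any():
        raise ValueError("AUC requires both classes present")
    return float(_skm.roc_auc_score(y, s))


def regression_report(y_true, y_pred, which: str = "prediction",
                      report: RegressionReport | None = None
                      ) -> RegressionReport:
    """Fill the calibration or prediction half of a RegressionReport.

    R2 = 1 − SSres/SStot; RMSE = sqrt(mean squared error); RPD (prediction
    set only) = sample SD (n−1) of the true values / RMSEP, reported as
    +inf for a perfect prediction. Constant true values make R2/RPD
    undefined and raise.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("true/predicted must be aligned 1-D arrays")
    if y_true.size < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(y_true) == 0:
        raise ValueError("constant true values: R2 and RPD undefined")
    ss_res = float(((y_true - y_pred) ** 2).sum())
    ss_tot = float(((y_true - y_true.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot
    rmse = float(np.sqrt(ss_res / y_true.size))
    rep = report or RegressionReport()
    if which == "calibration":
        rep.r2_c, rep.rmse_c = r2, rmse
    elif which == "prediction":
        rep.r2_p, rep.rmse_p = r2, rmse
        sd = float(np.std(y_true, ddof=1))
        rep.rpd = sd / rmse if rmse > 0 else float("inf")
    else:
        raise ValueError("which must be 'calibration' or 'prediction'")
    return rep


def repeated_runs(pipeline, n_runs: int = 10, base_seed: int = 0):
    """Run a seeded pipeline closure n times and aggregate its metrics.

    ``pipeline(seed)`` must return a flat dict of metric name -> value.
    Returns (summary, per_run): summary maps each metric to (mean, sd)
    over runs (sd with the n−1 convention; 0 by convention for a single
    run); any run failure aborts, naming the run index.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if n_runs == 1:
        warnings.warn("single run: SD reported as 0 by convention",
                      RuntimeWarning, stacklevel=2)
    rng = np.random.default_rng(base_seed)
    seeds = rng.integers(0, 2 ** 31 - 1, size=n_runs)
    per_run: list[dict[str, float]] = []
    for i, s in enumerate(seeds):
        try:
            per_run.append(dict(pipeline(int(s))))
        except Exception as exc:
            raise RuntimeError(f"pipeline failed on run {i}: {exc}") from exc
    names = per_run[0].keys()
    summary = {}
    for k in names:
        vals = np.array([r[k] for r in per_run], dtype=float)
        sd = float(np.std(vals, ddof=1)) if n_runs > 1 else 0.0
        summary[k] = (float(vals.mean()), sd)
    return summary, per_run


def blind_evaluation(model, records, train_ids,
                     features: np.ndarray | None = None, task: str = "multiclass"):
    """Evaluate a fitted classifier on blind samples unseen in training.

    Enforces sample_id disjointness against ``train_ids`` and returns
    (ClassificationReport, ledger) where the ledger lists each
    misclassified sample's id, true class and predicted class.
    """
    from .models import task_labels

    records = list(records)
    if not records:
        raise ValueError("empty blind set")
    overlap = {r.sample_id for r in records} & set(train_ids)
    if overlap:
        raise ValueError(f"blind set overlaps training set: "
                         f"{sorted(overlap)[:5]}")
    x = np.vstack([r.vector for r in records]) if features is None \
        else np.asarray(features, dtype=float)
    y = task_labels(records, task)
    scores = model.predict_proba(x)
    pred = model.predict(x)
    # scores usable for AUC only when every observed label has a column
    usable = set(np.unique(y)) <= set(model.classes_.tolist())
    report = classification_report(
        y, pred, scores if usable else None,
        classes=np.unique(np.concatenate([y, model.classes_])) if not usable
        else model.classes_)
    ledger = [
        {"sample_id": r.sample_id, "true": str(t), "predicted": str(p)}
        for r, t, p in zip(records, y, pred) if t != p
    ]
    return report, ledger
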