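"""Feature-importance scoring and importance-driven m/z interval refinement.

Four scorers rank features (or raw fine-grid m/z points) for class
discrimination / composition regression: one-way ANOVA F, mutual
information, Random Forest impurity importance, and Pearson correlation
against a continuous adulteration fraction. The refinement step takes the
top-k anchors of each score table, expands each anchor to a ±window m/z
interval, and merges the pooled intervals into a compact bin configuration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import mutual_info_classif

from .io_msdata import BinConfig

#: scores at least this large are treated as the +inf sentinel when ranking
F_INF_SENTINEL = np.inf


@dataclass(frozen=True)
class ScoreTable:
    """Per-feature importance scores anchored to m/z positions.

    ``mz`` anchors are strictly increasing; semantics of ``score`` depend
    on ``method`` (F statistic, MI in nats, normalized importance, or
    Pearson r).
    """

    method: str
    mz: np.ndarray
    score: np.ndarray

    def __post_init__(self) -> None:
        if self.mz.shape != self.score.shape:
            raise ValueError("mz/score length mismatch")
        if self.mz.size > 1 and not np.all(np.diff(self.mz) > 0):
            raise ValueError("m/z anchors must be strictly increasing")

    def top_anchors(self, k: int) -> np.ndarray:
        """m/z anchors of the k best scores; +inf ranks above all finite
        values and ties break toward lower m/z."""
        # stable sort on (-score) keeps lower m/z first among ties
        order = np.argsort(-self.score, kind="stable")
        return self.mz[order[:k]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"method": self.method, "mz": self.mz,
                             "score": self.score})


def _check_xy(features: np.ndarray, labels: np.ndarray,
              min_per_class: int = 2) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if x.ndim != 2 or x.shape[0] != y.shape[0]:
        raise ValueError("features must be (n_samples, n_features) aligned "
                         "with labels")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    if np.any(counts < min_per_class):
        small = classes[counts < min_per_class]
        raise ValueError(f"class(es) with < {min_per_class} samples: {small}")
    return x, y


def _default_anchors(n: int, mz: np.ndarray | None) -> np.ndarray:
    if mz is not None:
        mz = np.asarray(mz, dtype=float)
        if mz.size != n:
            raise ValueError("mz anchor length mismatch")
        return mz
    return np.arange(n, dtype=float)


def anova_f(features: np.ndarray, labels, mz=None) -> ScoreTable:
    """One-way ANOVA F statistic per feature: between-group mean square
    over within-group mean square.

    A feature with zero within-group variance but distinct group means
    scores +inf (reported as the sentinel and ranked above every finite
    score); a feature with no between-group variance scores 0.
    """
    x, y = _check_xy(features, labels)
    classes = np.unique(y)
    n = x.shape[0]
    grand = x.mean(axis=0)
    ssb = np.zeros(x.shape[1])
    ssw = np.zeros(x.shape[1])
    for c in classes:
        xc = x[y == c]
        ssb += xc.shape[0] * (xc.mean(axis=0) - grand) ** 2
        ssw += ((xc - xc.mean(axis=0)) ** 2).sum(axis=0)
    df_b = classes.size - 1
    df_w = n - classes.size
    msb = ssb / df_b
    msw = ssw / df_w
    with np.errstate(divide="ignore", invalid="ignore"):
        f = msb / msw
    f[(msw == 0) & (msb > 0)] = F_INF_SENTINEL
    f[(msw == 0) & (msb == 0)] = 0.0
    return ScoreTable("anova_f", _default_anchors(x.shape[1], mz), f)


def mutual_info(features: np.ndarray, labels, mz=None, *,
                n_neighbors: int = 3, seed: int = 0) -> ScoreTable:
    """Nonparametric mutual information (nats) between each feature and the
    class label, k-nearest-neighbour estimator (k configurable, default 3).
    Constant features score exactly 0."""
    x, y = _check_xy(features, labels)
    mi = mutual_info_classif(x, y, n_neighbors=n_neighbors,
                             random_state=seed)
    mi = np.maximum(mi, 0.0)
    mi[x.std(axis=0) == 0] = 0.0
    return ScoreTable("mutual_info", _default_anchors(x.shape[1], mz), mi)


def rf_importance(features: np.ndarray, labels, mz=None, *,
                  n_estimators: int = 100, seed: int = 42) -> ScoreTable:
    """Mean impurity-decrease importance from a seeded Random Forest;
    scores are normalized to sum to 1."""
    x, y = _check_xy(features, labels)
    forest = RandomForestClassifier(n_estimators=n_estimators,
                                    random_state=seed)
    forest.fit(x, y)
    imp = forest.feature_importances_
    return ScoreTable("rf_importance", _default_anchors(x.shape[1], mz), imp)


def pearson_scores(features: np.ndarray, target, mz=None) -> ScoreTable:
    """Pearson correlation of each feature against a continuous target
    (e.g. the adulteration fraction). Constant features score r = 0 by
    convention; a constant target is a validation error."""
    x = np.asarray(features, dtype=float)
    t = np.asarray(target, dtype=float)
    if x.shape[0] != t.shape[0]:
        raise ValueError("features/target length mismatch")
    if x.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    if t.std() == 0:
        raise ValueError("target is constant; Pearson r undefined")
    xc = x - x.mean(axis=0)
    tc = t - t.mean()
    sx = np.sqrt((xc ** 2).sum(axis=0))
    st = np.sqrt((tc ** 2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc.T @ tc) / (sx * st)
    r[sx == 0] = 0.0
    return ScoreTable("pearson", _default_anchors(x.shape[1], mz),
                      np.clip(r, -1.0, 1.0))


def merge_intervals(intervals) -> list[tuple[float, float]]:
    """Merge overlapping or touching [lo, hi] intervals; result is sorted
    and pairwise disjoint."""
    ivs = sorted((float(a), float(b)) for a, b in intervals)
    merged: list[list[float]] = []
    for a, b in ivs:
        if merged and a <= merged[-1][1] + 1e-12:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged]


def refine_bins(tables, top_k: int = 5, window: float = 0.03,
                step: float = 0.01) -> BinConfig:
    """Importance-driven bin refinement.

    For each score table keep the top-k m/z anchors, expand each anchor to
    [anchor − window, anchor + window], pool all intervals across tables,
    merge overlapping/adjacent ones, and emit the merged set as a sorted
    BinConfig whose sub-bin step defaults to 0.01 Da. For Pearson tables the
    ranking uses |r| (sign carries direction, not strength).

    The procedure is idempotent: refining the merged anchors again with the
    same window reproduces the same configuration.
    """
    tables = list(tables)
    if not tables:
        raise ValueError("no score tables given")
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if window <= 0:
        raise ValueError("window must be > 0")
    raw: list[tuple[float, float]] = []
    for tab in tables:
        if tab.method == "pearson":
            tab = ScoreTable(tab.method, tab.mz, np.abs(tab.score))
        for a in tab.top_anchors(top_k):
            raw.append((a - window, a + window))
    merged = merge_intervals(raw)
    return BinConfig(tuple((a, b, min(step, b - a)) for a, b in merged))
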