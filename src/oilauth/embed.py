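"""Feature-representation configurations: NON (identity), PCA and UMAP.

PCA and UMAP both operate on per-feature z-scored data; the scaler is fit
on the training matrix and the same statistics are applied to later data,
so the fitted embedder can project unseen samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler


@dataclass(frozen=True)
class EmbedConfig:
    """Which representation to use and its knobs.

    method: "non", "pca" or "umap".
    n_components: fixed output dimension (PCA/UMAP); for PCA, ``None``
        selects the smallest number of components retaining
        ``variance_fraction`` of the variance.
    variance_fraction: PCA retained-variance target in (0, 1], default 0.95.
    n_neighbors / min_dist: UMAP locality knobs.
    seed: random state for UMAP.
    """

    method: str = "non"
    n_components: int | None = None
    variance_fraction: float = 0.95
    n_neighbors: int = 15
    min_dist: float = 0.1
    seed: int = 42

    def __post_init__(self) -> None:
        if self.method not in ("non", "pca", "umap"):
            raise ValueError(f"unknown embed method {self.method!r}")
        if self.n_components is not None and self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if not 0 < self.variance_fraction <= 1:
            raise ValueError("variance_fraction must be in (0, 1]")


class FittedEmbedder:
    """A fitted representation: transform() projects new samples with the
    training-set standardization statistics."""

    def __init__(self, config: EmbedConfig, scaler, reducer):
        self.config = config
        self._scaler = scaler
        self._reducer = reducer

    def transform(self, features: np.ndarray) -> np.ndarray:
        x = np.asarray(features, dtype=float)
        if self.config.method == "non":
            return x
        z = self._scaler.transform(x)
        return np.asarray(self._reducer.transform(z), dtype=float)


def fit_transform(features: np.ndarray,
                  config: EmbedConfig) -> tuple[np.ndarray, FittedEmbedder]:
    """Fit the configured representation and return (reduced, embedder).

    NON returns the input unchanged; PCA returns scores on orthonormal
    components sorted by explained variance (requesting more components
    than the data's rank truncates with a warning); UMAP returns a seeded,
    deterministic embedding whose fitted model can project new samples.
    Sample count and order are preserved by all three.
    """
    x = np.asarray(features, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 samples")
    if config.method == "non":
        return x, FittedEmbedder(config, None, None)

    scaler = StandardScaler()
    z = scaler.fit_transform(x)

    if config.method == "pca":
        max_rank = min(z.shape)
        if config.n_components is None:
            n_comp: float | int = config.variance_fraction
            if n_comp == 1.0:
                n_comp = max_rank
        else:
            n_comp = config.n_components
            if n_comp > max_rank:
                warnings.warn(
                    f"n_components={n_comp} exceeds rank {max_rank}; "
                    "truncating", RuntimeWarning, stacklevel=2)
                n_comp = max_rank
        pca = PCA(n_components=n_comp, svd_solver="full",
                  random_state=config.seed)
        reduced = pca.fit_transform(z)
        return reduced, FittedEmbedder(config, scaler, pca)

    # umap-learn import is deferred: it is slow and only needed here
    from umap import UMAP

    n_comp = config.n_components or 2
    n_neighbors = min(config.n_neighbors, x.shape[0] - 1)
    um = UMAP(n_components=n_comp, n_neighbors=n_neighbors,
              min_dist=config.min_dist, random_state=config.seed)
    with warnings.catch_warnings():
        # umap warns that a fixed random_state disables parallelism; that
        # determinism is exactly what we want
        warnings.filterwarnings("ignore", module="umap")
        warnings.filterwarnings("ignore", category=UserWarning)
        reduced = um.fit_transform(z)
    return np.asarray(reduced, dtype=float), FittedEmbedder(config, scaler, um)


def explained_variance(embedder: FittedEmbedder) -> np.ndarray:
    """Per-component explained-variance fractions of a fitted PCA
    (non-increasing, summing to <= 1)."""
    if embedder.config.method != "pca" or embedder._reducer is None:
        raise TypeError("explained_variance requires a fitted PCA embedder")
    return np.asarray(embedder._reducer.explained_variance_ratio_)
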