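"""Dynamic m/z binning and feature-vector assembly.

A scan series is turned into a fixed-length fingerprint in three steps:

1. every configured m/z interval is expanded into contiguous half-open
   sub-bins of the interval's step width, and each scan's peak intensities
   are summed per sub-bin;
2. the scans x sub-bins matrix is aggregated along time with five
   statistics per sub-bin (max, mean, median, SD, sum), laid out bin-major;
3. eight descriptors of the total ion chromatogram (TIC) are appended.

With the packaged default configuration (92 intervals, 666 sub-bins) the
full vector has 666*5 + 8 = 3338 dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks, peak_widths

from .io_msdata import BinConfig, ScanSeries

N_TIC_FEATURES = 8
N_AGG_STATS = 5
AGG_STAT_NAMES = ("max", "mean", "median", "sd", "sum")

# local maxima of the TIC count as peaks when their prominence exceeds this
# fraction of the TIC maximum
PEAK_PROMINENCE_FRAC = 0.05


@dataclass(frozen=True)
class SubBinGrid:
    """Expanded sub-bin grid: half-open ranges [lo, hi) with the index of
    the configured interval each sub-bin came from."""

    lo: np.ndarray          # (n_bins,) left edges
    hi: np.ndarray          # (n_bins,) right edges
    interval_index: np.ndarray  # (n_bins,) source interval per sub-bin

    @property
    def n_bins(self) -> int:
        return int(self.lo.size)


@dataclass
class FeatureRecord:
    """One sample's full feature vector with optional supervision.

    ``vector`` is the concatenation of the bin-major aggregated block
    (5 values per sub-bin) and the 8 TIC descriptors; its length is
    5*n_bins + 8.
    """

    sample_id: str
    binned_block: np.ndarray
    tic_block: np.ndarray
    label: str = ""
    fractions: np.ndarray | None = None

    @property
    def vector(self) -> np.ndarray:
        return np.concatenate([self.binned_block, self.tic_block])


@dataclass(frozen=True)
class TICProfile:
    """Total ion chromatogram: per-scan summed intensity over time."""

    times: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        if self.times.shape != self.intensity.shape:
            raise ValueError("times/intensity length mismatch")
        if np.any(self.intensity < 0):
            raise ValueError("negative TIC intensity")


def expand_bins(config: BinConfig) -> SubBinGrid:
    """Expand intervals into contiguous half-open sub-bins.

    An interval whose width is not an integer multiple of its step gets a
    truncated final sub-bin ending exactly at the interval end.
    """
    lo, hi, src = [], [], []
    for idx, (s, e, st) in enumerate(config.intervals):
        width = e - s
        n_full = int(np.floor(width / st + 1e-9))
        edges = s + st * np.arange(n_full + 1)
        l = edges[:-1]
        h = edges[1:].copy()
        if width - n_full * st > 1e-9 * st:  # truncated remainder bin
            l = np.append(l, edges[-1])
            h = np.append(h, e)
        h[-1] = e  # close the interval exactly despite float accumulation
        lo.append(l)
        hi.append(h)
        src.append(np.full(l.size, idx))
    return SubBinGrid(lo=np.concatenate(lo), hi=np.concatenate(hi),
                      interval_index=np.concatenate(src))


def bin_scan(mz: np.ndarray, intensity: np.ndarray,
             grid: SubBinGrid) -> np.ndarray:
    """Sum peak intensities into sub-bins; peaks outside every configured
    interval contribute nothing. ``mz`` must be sorted ascending."""
    out = np.zeros(grid.n_bins)
    if mz.size == 0:
        return out
    # half-open [lo, hi): a peak at exactly hi of the last sub-bin of an
    # interval is excluded
    left = np.searchsorted(mz, grid.lo, side="left")
    right = np.searchsorted(mz, grid.hi, side="left")
    csum = np.concatenate([[0.0], np.cumsum(intensity)])
    return csum[right] - csum[left]


def bin_series(series: ScanSeries, grid: SubBinGrid) -> np.ndarray:
    """Binned matrix (n_scans x n_bins) for a whole scan series."""
    return np.vstack([bin_scan(m, i, grid)
                      for m, i in zip(series.mz, series.intensity)])


def aggregate_time(binned: np.ndarray) -> np.ndarray:
    """Aggregate a scans x n_bins matrix into 5 statistics per sub-bin.

    Per bin: max, mean, median, SD and sum across scans, assembled
    bin-major (bin0: max, mean, median, sd, sum; bin1: ...). SD uses the
    population convention (divide by n) so a single scan yields 0.
    """
    binned = np.atleast_2d(np.asarray(binned, dtype=float))
    if binned.shape[0] < 1:
        raise ValueError("need at least one scan")
    stats = np.stack([
        binned.max(axis=0),
        binned.mean(axis=0),
        np.median(binned, axis=0),
        binned.std(axis=0),       # population SD
        binned.sum(axis=0),
    ], axis=1)                     # (n_bins, 5) -> bin-major on ravel
    return stats.ravel()


def tic_profile(series: ScanSeries) -> TICProfile:
    """Per-scan total intensity as a function of acquisition time."""
    total = np.array([i.sum() for i in series.intensity])
    return TICProfile(times=series.times.copy(), intensity=total)


def tic_features(tic: TICProfile,
                 prominence_frac: float = PEAK_PROMINENCE_FRAC) -> np.ndarray:
    """Eight fixed-order chromatographic descriptors of the TIC.

    1. total area (trapezoidal over time)
    2. time of the TIC maximum (first occurrence on ties) — the "retention
       time of the main peak" for an ambient source
    3. signal-to-noise ratio: max / (MAD * 1.4826), guarded for a zero MAD
    4. number of local maxima with prominence >= prominence_frac * max
    5. intensity-weighted skewness of the time profile
    6. intensity-weighted excess kurtosis
    7. main-peak height (the TIC maximum)
    8. main-peak FWHM (half-prominence width at the main peak; 0 when no
       peak is resolvable)

    A constant TIC has skewness and kurtosis defined as 0 and a peak count
    of 0 (no local maximum has nonzero prominence).
    """
    y = np.asarray(tic.intensity, dtype=float)
    t = np.asarray(tic.times, dtype=float)
    if y.size < 3:
        raise ValueError("TIC shape statistics require at least 3 scans")

    area = float(np.trapezoid(y, t))
    imax = int(np.argmax(y))
    t_main = float(t[imax])
    height = float(y[imax])

    mad = float(np.median(np.abs(y - np.median(y))))
    noise = mad * 1.4826
    snr = float(height / noise) if noise > 0 else float(y.size)

    if height > 0:
        peaks, props = find_peaks(y, prominence=prominence_frac * height)
    else:
        peaks, props = np.array([], dtype=int), {}
    n_peaks = int(peaks.size)

    total = y.sum()
    if total > 0 and np.ptp(y) > 0:
        mu = float((t * y).sum() / total)
        var = float(((t - mu) ** 2 * y).sum() / total)
        if var > 0:
            sd = np.sqrt(var)
            skew = float((((t - mu) / sd) ** 3 * y).sum() / total)
            kurt = float((((t - mu) / sd) ** 4 * y).sum() / total - 3.0)
        else:
            skew = kurt = 0.0
    else:
        skew = kurt = 0.0

    fwhm = 0.0
    if n_peaks:
        main = peaks[np.argmax(y[peaks])]
        widths = peak_widths(y, np.array([main]), rel_height=0.5)[0]
        dt = (t[-1] - t[0]) / (y.size - 1) if y.size > 1 else 0.0
        fwhm = float(widths[0] * dt)

    return np.array([area, t_main, snr, n_peaks, skew, kurt, height, fwhm])


def featurize_sample(series: ScanSeries, grid: SubBinGrid) -> FeatureRecord:
    """Full feature vector for one sample: aggregated binned block followed
    by the 8 TIC descriptors (5*n_bins + 8 values)."""
    binned = bin_series(series, grid)
    return FeatureRecord(
        sample_id=series.sample_id,
        binned_block=aggregate_time(binned),
        tic_block=tic_features(tic_profile(series)),
    )


def featurize_dataset(samples, grid: SubBinGrid) -> list[FeatureRecord]:
    """Featurize (ScanSeries, MixtureDesign) pairs, attaching labels and
    composition vectors from the designs."""
    records = []
    for series, design in samples:
        rec = featurize_sample(series, grid)
        rec.label = design.label
        rec.fractions = np.asarray(design.fractions, dtype=float)
        records.append(rec)
    return records


def records_to_matrix(records) -> np.ndarray:
    """Stack FeatureRecord vectors into an (n_samples, n_features) matrix."""
    return np.vstack([r.vector for r in records])


def grid_summary(config: BinConfig, grid: SubBinGrid):
    """Per-interval sub-bin counts for auditing, as a pandas DataFrame."""
    import pandas as pd

    counts = np.bincount(grid.interval_index, minlength=len(config))
    return pd.DataFrame({
        "start": [s for s, _, _ in config.intervals],
        "end": [e for _, e, _ in config.intervals],
        "step": [st for _, _, st in config.intervals],
        "n_subbins": counts,
    })
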