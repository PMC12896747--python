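"""Reading and writing of mass-spectrometry scan series and tabular artifacts.

Scan series are full-scan (MS1) positive-mode spectra acquired as a short
time series on an ambient ion source; they are exchanged on disk as mzXML.
Bin configurations (the dynamic-binning intervals) and feature tables travel
as plain delimited text so they can be audited and diffed.
"""

from __future__ import annotations

import base64
import hashlib
import struct
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from pyteomics import mzxml as _pyteomics_mzxml

OIL_CLASSES = ("CAO", "COO", "OLO", "SOO", "SUO")
"""Canonical order of the five oil classes: camellia, corn, olive, soybean,
sunflower. Composition vectors follow this order everywhere."""


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ScanSeries:
    """Time-ordered MS1 spectra for one sample.

    Each scan is a centroided peak list: an ascending m/z array and a
    same-length non-negative intensity array, stamped with an acquisition
    time in seconds. Profile-mode data are accepted unchanged — downstream
    binning simply sums whatever peaks are present.
    """

    sample_id: str
    times: np.ndarray            # (n_scans,) strictly increasing, seconds
    mz: list[np.ndarray]         # per-scan ascending m/z
    intensity: list[np.ndarray]  # per-scan non-negative, same length as mz

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.mz = [np.asarray(m, dtype=float) for m in self.mz]
        self.intensity = [np.asarray(i, dtype=float) for i in self.intensity]
        if self.times.ndim != 1 or self.times.size < 1:
            raise ValueError("ScanSeries requires at least one scan")
        if not (len(self.mz) == len(self.intensity) == self.times.size):
            raise ValueError("times, mz and intensity must have equal length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("scan times must be strictly increasing")
        for k, (m, i) in enumerate(zip(self.mz, self.intensity)):
            if m.shape != i.shape:
                raise ValueError(f"scan {k}: mz/intensity length mismatch")
            if m.size > 1 and np.any(np.diff(m) < 0):
                raise ValueError(f"scan {k}: m/z array not sorted ascending")
            if np.any(i < 0):
                raise ValueError(f"scan {k}: negative intensity")

    @property
    def n_scans(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class BinConfig:
    """Ordered, non-overlapping m/z intervals, each carrying a sub-bin step.

    An interval (start, end, step) is later expanded into contiguous
    half-open sub-bins of width ``step``.
    """

    intervals: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        ivs = tuple((float(s), float(e), float(st)) for s, e, st in self.intervals)
        object.__setattr__(self, "intervals", ivs)
        prev_end = -np.inf
        for idx, (s, e, st) in enumerate(ivs):
            if not s < e:
                raise ValueError(f"interval {idx}: start {s} >= end {e}")
            if not st > 0:
                raise ValueError(f"interval {idx}: step {st} <= 0")
            if st > (e - s) + 1e-12:
                raise ValueError(f"interval {idx}: step {st} exceeds width")
            if s < prev_end:
                raise ValueError(f"interval {idx}: overlaps previous interval")
            prev_end = e

    def __len__(self) -> int:
        return len(self.intervals)


# ---------------------------------------------------------------------------
# mzXML
# ---------------------------------------------------------------------------

def read_mzxml(path: str | Path) -> ScanSeries:
    """Read all MS1 scans of an mzXML file, in acquisition order.

    MS2 (and deeper) scans are skipped: the pipeline consumes full-scan data
    only. Peak lists are decoded per the mzXML standard (base64, 32/64-bit,
    optional zlib) by pyteomics.

    Raises FileNotFoundError for a missing file and FormatError (naming the
    offending scan where known) for malformed content.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    times, mzs, intens = [], [], []
    scan_num = None
    try:
        with _pyteomics_mzxml.read(str(path)) as reader:
            for scan in reader:
                scan_num = scan.get("num", "?")
                if int(scan.get("msLevel", 1)) != 1:
                    continue
                rt = scan.get("retentionTime", 0.0)
                # pyteomics reports retention time in minutes
                unit = getattr(rt, "unit_info", "minute")
                times.append(float(rt) * 60.0 if unit == "minute"
                             else float(rt))
                m = np.asarray(scan["m/z array"], dtype=float)
                order = np.argsort(m, kind="stable")
                mzs.append(m[order])
                intens.append(np.asarray(scan["intensity array"], dtype=float)[order])
    except Exception as exc:  # lxml/pyteomics raise assorted parse errors
        raise FormatError(
            f"{path}: malformed mzXML near scan {scan_num}: {exc}"
        ) from exc
    if not times:
        raise FormatError(f"{path}: no MS1 scans found")
    try:
        return ScanSeries(sample_id=path.stem, times=np.asarray(times),
                          mz=mzs, intensity=intens)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def _encode_peaks(mz: np.ndarray, intensity: np.ndarray) -> str:
    pairs = np.empty(2 * mz.size, dtype=">f8")
    pairs[0::2] = mz
    pairs[1::2] = intensity
    return base64.b64encode(pairs.tobytes()).decode("ascii")


def write_mzxml(series: ScanSeries, path: str | Path) -> None:
    """Write a ScanSeries as a minimal standard-conforming mzXML file.

    Peaks are encoded as 64-bit network-byte-order m/z–intensity pairs
    (uncompressed), so ``read_mzxml(write_mzxml(s))`` is the identity up to
    float precision.
    """
    path = Path(path)
    n = series.n_scans
    lines = [
        '<?xml version="1.0" encoding="ISO-8859-1"?>',
        '<mzXML xmlns="http://sashimi.sourceforge.net/schema_revision/mzXML_3.2">',
        f' <msRun scanCount="{n}">',
    ]
    for k in range(n):
        mz, inten = series.mz[k], series.intensity[k]
        lines.append(
            f'  <scan num="{k + 1}" msLevel="1" peaksCount="{mz.size}"'
            f' retentionTime="PT{series.times[k]:.6f}S"'
            f' lowMz="{mz[0] if mz.size else 0:.6f}"'
            f' highMz="{mz[-1] if mz.size else 0:.6f}">'
        )
        lines.append(
            '   <peaks compressionType="none" compressedLen="0" precision="64"'
            ' byteOrder="network" contentType="m/z-int">'
            + _encode_peaks(mz, inten) + "</peaks>"
        )
        lines.append("  </scan>")
    lines += [" </msRun>", "</mzXML>", ""]
    path.write_text("\n".join(lines))


# ---------------------------------------------------------------------------
# Bin configuration tables
# ---------------------------------------------------------------------------

def read_bin_config(path: str | Path) -> BinConfig:
    """Read a three-column delimited text file (start, end, step).

    A header row is detected and skipped. Rows are sorted by start before
    validation; overlapping intervals, non-positive steps or inverted bounds
    raise a validation error naming the offending row.
    """
    path = Path(path)
    rows: list[tuple[float, float, float]] = []
    with open(path) as fh:
        for ln, raw in enumerate(fh):
            raw = raw.strip()
            if not raw:
                continue
            parts = [p.strip() for p in raw.replace("\t", ",").split(",")]
            if len(parts) != 3:
                raise FormatError(f"{path} row {ln}: expected 3 columns")
            try:
                s, e, st = (float(p) for p in parts)
            except ValueError:
                if ln == 0:
                    continue  # header
                raise FormatError(f"{path} row {ln}: non-numeric entry")
            rows.append((s, e, st))
    rows.sort(key=lambda r: r[0])
    try:
        return BinConfig(tuple(rows))
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_bin_config(config: BinConfig, path: str | Path) -> None:
    """Write a BinConfig as sorted CSV with a header; round trip is exact."""
    with open(path, "w") as fh:
        fh.write("start,end,step\n")
        for s, e, st in config.intervals:
            fh.write(f"{s!r},{e!r},{st!r}\n")


def default_bin_config() -> BinConfig:
    """The packaged default dynamic-binning configuration.

    92 intervals over m/z 75–1000, concentrated in the volatile region
    (100–300) and the triglyceride region (800–1000); expands to 666
    sub-bins.
    """
    from importlib import resources

    ref = resources.files("oilauth") / "data" / "default_bins.csv"
    with resources.as_file(ref) as p:
        return read_bin_config(p)


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

def write_feature_table(path: str | Path,
                        sample_ids: Sequence[str],
                        features: np.ndarray,
                        labels: Sequence[str] | None = None,
                        fractions: np.ndarray | None = None) -> None:
    """Write a feature table as CSV: sample_id, label, five composition
    columns, then feature columns f0001…fNNNN."""
    features = np.asarray(features, dtype=float)
    n, d = features.shape
    cols = {"sample_id": list(sample_ids)}
    cols["label"] = list(labels) if labels is not None else [""] * n
    fr = np.zeros((n, 5)) if fractions is None else np.asarray(fractions, float)
    for j, oil in enumerate(OIL_CLASSES):
        cols[f"frac_{oil}"] = fr[:, j]
    df = pd.DataFrame(cols)
    feat = pd.DataFrame(features, columns=[f"f{j + 1:04d}" for j in range(d)])
    pd.concat([df, feat], axis=1).to_csv(path, index=False)


def read_feature_table(path: str | Path) -> tuple[list[str], np.ndarray,
                                                  list[str], np.ndarray]:
    """Read a feature table written by write_feature_table.

    Returns (sample_ids, features, labels, fractions)."""
    df = pd.read_csv(path)
    meta = ["sample_id", "label"] + [f"frac_{o}" for o in OIL_CLASSES]
    missing = [c for c in meta if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    feat_cols = [c for c in df.columns if c not in meta]
    features = df[feat_cols].to_numpy(dtype=float)
    fractions = df[[f"frac_{o}" for o in OIL_CLASSES]].to_numpy(dtype=float)
    labels = df["label"].fillna("").astype(str).tolist()
    return df["sample_id"].astype(str).tolist(), features, labels, fractions


def file_sha256(path: str | Path) -> str:
    """Hex digest of a file, used in run manifests."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
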