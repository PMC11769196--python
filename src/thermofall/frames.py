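"""Data model and I/O for 8x8 thermal-array frame streams.

A low-resolution IR array sensor reports a grid of 64 temperatures per
frame at roughly 16 Hz.  Everything downstream of the sensor operates on
the per-frame *sum statistic*

    S_i = sum_j p_ij        (j over the 64 pixels of frame i)

so this module owns the frame/series containers, the CSV logging dialect
(one frame per row, row-major pixel order), the sum statistic itself,
histogramming of the sums, and sliding windows over a sum series.

CSV dialect
-----------
Header ``p00,...,p77`` (row-major), optionally preceded by a ``t`` column
holding the timestamp in seconds since stream start.  Values are written
with 4 fixed decimal places, so a write/read round trip is value-exact at
that precision (0.1 mC resolution, far below sensor noise).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

logger = logging.getLogger(__name__)

GRID_SHAPE = (8, 8)
N_PIXELS = 64
#: operating range of the sensor, degrees Celsius
SENSOR_RANGE_C = (0.0, 80.0)
#: fixed number of decimal places used when logging frames to CSV
CSV_DECIMALS = 4

_PIXEL_HEADER = [f"p{r}{c}" for r in range(8) for c in range(8)]


class ThermalCSVError(ValueError):
    """Raised when a frame CSV file cannot be parsed."""


class DataQualityError(ValueError):
    """Raised when pixel data violate basic quality requirements."""


@dataclass(frozen=True)
class ThermalFrame:
    """One 8x8 grid of pixel temperatures (degrees C) plus optional timestamp."""

    pixels: np.ndarray
    timestamp: float | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.size != N_PIXELS:
            raise ValueError(f"expected {N_PIXELS} pixel values, got {px.size}")
        object.__setattr__(self, "pixels", px.reshape(GRID_SHAPE))
        if self.timestamp is not None and self.timestamp < 0:
            raise ValueError("timestamp must be non-negative")

    @property
    def out_of_range(self) -> np.ndarray:
        """Boolean mask of pixels outside the sensor range (permitted, flagged)."""
        lo, hi = SENSOR_RANGE_C
        return (self.pixels < lo) | (self.pixels > hi)


@dataclass
class FrameSeries:
    """An ordered stream of frames sampled at a fixed rate.

    Pixels are stored as one ``(n, 8, 8)`` array; ``timestamps`` (seconds,
    strictly increasing) are optional.
    """

    pixels: np.ndarray
    timestamps: np.ndarray | None = None
    sampling_rate_hz: float = 16.0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim == 2 and px.shape[1] == N_PIXELS:
            px = px.reshape(-1, *GRID_SHAPE)
        if px.ndim != 3 or px.shape[1:] != GRID_SHAPE:
            raise ValueError(f"pixels must have shape (n, 8, 8), got {px.shape}")
        self.pixels = px
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.timestamps is not None:
            ts = np.asarray(self.timestamps, dtype=float)
            if ts.shape != (len(px),):
                raise ValueError("timestamps must align 1:1 with frames")
            if len(ts) > 1 and not np.all(np.diff(ts) > 0):
                raise ValueError("timestamps must be strictly increasing")
            self.timestamps = ts

    @classmethod
    def from_frames(
        cls, frames: Sequence[ThermalFrame], sampling_rate_hz: float = 16.0
    ) -> "FrameSeries":
        px = np.stack([f.pixels for f in frames]) if frames else np.empty((0, 8, 8))
        ts = None
        if frames and all(f.timestamp is not None for f in frames):
            ts = np.array([f.timestamp for f in frames], dtype=float)
        return cls(px, ts, sampling_rate_hz)

    def __len__(self) -> int:
        return len(self.pixels)

    def __getitem__(self, i: int) -> ThermalFrame:
        ts = None if self.timestamps is None else float(self.timestamps[i])
        return ThermalFrame(self.pixels[i], ts)

    def __iter__(self) -> Iterator[ThermalFrame]:
        for i in range(len(self)):
            yield self[i]

    def drop_out_of_range(self) -> "FrameSeries":
        """Opt-in outlier guard: drop frames with any pixel outside the sensor range.

        OFF by default everywhere — raw values are used unfiltered.  When
        invoked, the number of dropped frames is logged.
        """
        lo, hi = SENSOR_RANGE_C
        keep = np.all((self.pixels >= lo) & (self.pixels <= hi), axis=(1, 2))
        dropped = int((~keep).sum())
        if dropped:
            logger.info("outlier guard dropped %d of %d frames", dropped, len(self))
        ts = self.timestamps[keep] if self.timestamps is not None else None
        return FrameSeries(self.pixels[keep], ts, self.sampling_rate_hz)


@dataclass
class SumSeries:
    """The per-frame sum statistic S_i; the series all statistics run on."""

    values: np.ndarray
    source_length: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float).ravel()
        if len(v) != self.source_length:
            raise ValueError("values length must equal source_length")
        if v.size and not np.all(np.isfinite(v)):
            raise ValueError("sum values must all be finite")
        self.values = v

    @classmethod
    def from_values(cls, values) -> "SumSeries":
        v = np.asarray(values, dtype=float).ravel()
        return cls(v, len(v))

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class Histogram:
    """Counts f_k of sum values falling into bin k (last bin right-closed)."""

    bin_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        counts = np.asarray(self.counts)
        if not np.all(np.diff(edges) > 0):
            raise ValueError("bin edges must be strictly ascending")
        if len(counts) != len(edges) - 1:
            raise ValueError("need len(edges) == len(counts) + 1")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        self.bin_edges = edges
        self.counts = counts.astype(int)


def frame_sum(frame: ThermalFrame | np.ndarray) -> float:
    """Sum of the 64 pixel temperatures of one frame.

    Raises :class:`DataQualityError` naming the (row-major) index of the
    first non-finite pixel.
    """
    px = frame.pixels if isinstance(frame, ThermalFrame) else np.asarray(frame, float)
    flat = px.ravel()
    if flat.size != N_PIXELS:
        raise ValueError(f"expected {N_PIXELS} pixels, got {flat.size}")
    bad = np.flatnonzero(~np.isfinite(flat))
    if bad.size:
        raise DataQualityError(f"non-finite pixel value at index {bad[0]}")
    return float(flat.sum())


def sum_series(series: FrameSeries) -> SumSeries:
    """Apply the sum statistic to every frame of a series."""
    flat = series.pixels.reshape(len(series), N_PIXELS)
    bad_frame, bad_px = np.where(~np.isfinite(flat))
    if bad_frame.size:
        raise DataQualityError(
            f"non-finite pixel value at index {bad_px[0]} of frame {bad_frame[0]}"
        )
    return SumSeries(flat.sum(axis=1), len(series))


# ---------------------------------------------------------------------------
# CSV I/O


def write_frames_csv(series: FrameSeries, path) -> int:
    """Write a frame series in the logging dialect; returns the row count."""
    path = Path(path)
    with_t = series.timestamps is not None
    fmt = f"%.{CSV_DECIMALS}f"
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow((["t"] if with_t else []) + _PIXEL_HEADER)
        for i in range(len(series)):
            row = [fmt % v for v in series.pixels[i].ravel()]
            if with_t:
                row.insert(0, fmt % series.timestamps[i])
            w.writerow(row)
    return len(series)


def read_frames_csv(path, sampling_rate_hz: float = 16.0) -> FrameSeries:
    """Read a frame series from the logging dialect.

    Accepts files with or without the header line and with or without the
    leading timestamp column; each data row must carry exactly 64 pixel
    fields.  Malformed rows raise :class:`ThermalCSVError` naming the row.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        rows = [r for r in csv.reader(fh) if r and any(f.strip() for f in r)]
    if not rows:
        raise ThermalCSVError(f"{path}: empty file")
    start = 0
    with_t = None
    first = [f.strip() for f in rows[0]]
    if first and not _is_number(first[0]):  # header line
        if first[0].lower() == "t":
            with_t = True
        elif len(first) == N_PIXELS:
            with_t = False
        else:
            raise ThermalCSVError(
                f"{path}: row 1: unrecognized header with {len(first)} fields"
            )
        start = 1
    data_rows = rows[start:]
    if not data_rows:
        raise ThermalCSVError(f"{path}: no data rows")
    pixels, stamps = [], []
    for k, row in enumerate(data_rows, start=start + 1):
        fields = [f.strip() for f in row]
        if with_t is None:
            with_t = len(fields) == N_PIXELS + 1
        if with_t:
            if len(fields) != N_PIXELS + 1:
                raise ThermalCSVError(
                    f"{path}: row {k}: expected 64 pixel fields plus timestamp, "
                    f"got {len(fields)} fields"
                )
            tfield, fields = fields[0], fields[1:]
            try:
                stamps.append(float(tfield))
            except ValueError:
                raise ThermalCSVError(f"{path}: row {k}: non-numeric timestamp {tfield!r}")
        elif len(fields) != N_PIXELS:
            raise ThermalCSVError(
                f"{path}: row {k}: expected 64 pixel fields, got {len(fields)}"
            )
        try:
            pixels.append([float(f) for f in fields])
        except ValueError as exc:
            raise ThermalCSVError(f"{path}: row {k}: non-numeric pixel field ({exc})")
    ts = np.array(stamps) if with_t else None
    return FrameSeries(np.array(pixels), ts, sampling_rate_hz)


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def write_sums_csv(sums: SumSeries, path) -> int:
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["S"])
        for v in sums.values:
            w.writerow([f"%.{CSV_DECIMALS}f" % v])
    return len(sums)


def read_sums_csv(path) -> SumSeries:
    path = Path(path)
    with path.open(newline="") as fh:
        rows = [r for r in csv.reader(fh) if r]
    if rows and rows[0] and not _is_number(rows[0][0]):
        rows = rows[1:]
    return SumSeries.from_values([float(r[0]) for r in rows])


def write_histogram_csv(hist: Histogram, path) -> None:
    """Two-column export: left bin edge, count."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["bin_left", "count"])
        for left, c in zip(hist.bin_edges[:-1], hist.counts):
            w.writerow([f"{left:.6g}", int(c)])


# ---------------------------------------------------------------------------
# Histograms and windows


def build_histogram(sums: SumSeries | np.ndarray, bin_rule="fd") -> Histogram:
    """Histogram of the sums under a binning rule.

    ``bin_rule`` is ``"fd"`` (Freedman–Diaconis, floored at 10 bins — the
    default), an integer bin count, or an explicit edge sequence.  Counts
    always conserve n (numpy's convention: last bin right-closed).
    Constant input under an automatic rule yields a single bin widened by
    a small epsilon.
    """
    values = sums.values if isinstance(sums, SumSeries) else np.asarray(sums, float)
    if values.size == 0:
        raise ValueError("cannot histogram an empty series")
    if isinstance(bin_rule, str):
        if bin_rule != "fd":
            raise ValueError(f"unknown bin rule {bin_rule!r}")
        if np.ptp(values) == 0:
            eps = max(abs(values[0]) * 1e-9, 1e-9)
            edges = np.array([values[0] - eps, values[0] + eps])
        else:
            edges = np.histogram_bin_edges(values, bins="fd")
            if len(edges) - 1 < 10:
                edges = np.histogram_bin_edges(values, bins=10)
    elif np.isscalar(bin_rule):
        if int(bin_rule) < 1:
            raise ValueError("bin count must be >= 1")
        if np.ptp(values) == 0:
            eps = max(abs(values[0]) * 1e-9, 1e-9)
            edges = np.linspace(values[0] - eps, values[0] + eps, int(bin_rule) + 1)
        else:
            edges = np.histogram_bin_edges(values, bins=int(bin_rule))
    else:
        edges = np.asarray(bin_rule, dtype=float)
    counts, edges = np.histogram(values, bins=edges)
    return Histogram(edges, counts)


def sliding_windows(sums: SumSeries, window_len: int, step: int) -> list[SumSeries]:
    """Fixed-length windows starting at 0, step, 2*step, ...

    The trailing partial window is dropped; a window longer than the
    series yields an empty list.
    """
    if window_len < 2:
        raise ValueError("window_len must be >= 2")
    if step < 1:
        raise ValueError("step must be >= 1")
    n = len(sums)
    return [
        SumSeries(sums.values[s : s + window_len], window_len)
        for s in range(0, n - window_len + 1, step)
    ]
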