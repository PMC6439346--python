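"""Multidimensional signal inspection: grid layout, spectra, thresholds.

An n-dimensional recording (e.g. trials x channels x time) is flattened
over its non-time axes and laid out on a near-square 2D grid for visual
inspection; each signal can then be summarized as a histogram, a Welch
power spectral density, or a Morlet-wavelet time-frequency map with the
usual baseline normalizations. Threshold-based extrema detection and an
annotation table support manual review; hypnogram stage statistics cover
polysomnographic recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "SignalDataset",
    "AnnotationTable",
    "Hypnogram",
    "STAGE_NAMES",
    "grid_shape",
    "reshape_to_grid",
    "psd",
    "tf_morlet",
    "histogram",
    "detect_extrema",
    "preprocess",
    "hypnogram_stats",
]

# Sleep-stage integer codes (artefact through REM), the sleep-scoring
# convention used throughout.
STAGE_NAMES = {-1: "Art", 0: "Wake", 1: "N1", 2: "N2", 3: "N3", 4: "REM"}


@dataclass
class SignalDataset:
    """An n-dim array of signals sharing one time axis and sampling rate."""

    data: np.ndarray
    sf: float
    time_axis: int = -1

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.sf <= 0:
            raise ValueError(f"sampling frequency must be > 0, got {self.sf}")
        self.time_axis = int(self.time_axis) % self.data.ndim
        if self.data.shape[self.time_axis] < 2:
            raise ValueError("need at least 2 time points")

    @property
    def n_times(self) -> int:
        return self.data.shape[self.time_axis]

    @property
    def n_signals(self) -> int:
        return int(self.data.size // self.n_times)

    def signals_2d(self) -> np.ndarray:
        """(n_signals, n_times) view with non-time axes flattened row-major."""
        moved = np.moveaxis(self.data, self.time_axis, -1)
        return moved.reshape(-1, self.n_times)


@dataclass
class AnnotationTable:
    """Annotations: (signal index, time in s, text) records."""

    records: list[tuple[int, float, str]] = field(default_factory=list)

    def add(self, signal: int, time_s: float, text: str, duration_s: float | None = None):
        if duration_s is not None and not 0 <= time_s <= duration_s:
            raise ValueError(f"annotation time {time_s}s outside [0, {duration_s}]s")
        self.records.append((int(signal), float(time_s), str(text)))

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class Hypnogram:
    """Per-epoch sleep-stage codes at a fixed epoch length."""

    stages: np.ndarray
    epoch_s: float = 30.0

    def __post_init__(self) -> None:
        self.stages = np.asarray(self.stages, dtype=np.int64)
        if self.stages.ndim != 1 or len(self.stages) == 0:
            raise ValueError("stages must be a non-empty 1D vector")
        bad = set(np.unique(self.stages).tolist()) - set(STAGE_NAMES)
        if bad:
            raise ValueError(f"unknown stage code(s) {sorted(bad)}; known: {STAGE_NAMES}")
        if self.epoch_s <= 0:
            raise ValueError("epoch_s must be > 0")


def grid_shape(n: int) -> tuple[int, int]:
    """Rows and columns for laying ``n`` signals out on a near-square grid.

    Among exact divisor pairs (r, c) with r*c = n and r >= c, the pair
    minimizing r - c is chosen; a dataset of 104 signals lands on a
    13 x 8 grid. When the best exact pair is too elongated (aspect
    r/c > 4, e.g. primes above 3), the grid falls back to
    c = floor(sqrt(n)), r = ceil(n/c), leaving r*c - n trailing empty
    cells. Rows always >= columns (portrait).
    """
    if n < 1:
        raise ValueError(f"need n >= 1, got {n}")
    best = None
    for c in range(1, int(np.sqrt(n)) + 1):
        if n % c == 0:
            best = (n // c, c)  # largest c wins: last hit minimizes r - c
    r, c = best
    if r / c > 4 and n > 3:
        c = int(np.floor(np.sqrt(n)))
        r = int(np.ceil(n / c))
    return r, c


def reshape_to_grid(ds: SignalDataset) -> tuple[tuple[int, int], list[dict]]:
    """Assign each signal of a dataset to a grid cell.

    Non-time axes are flattened in row-major (C) order and the flat
    sequence fills the :func:`grid_shape` grid row by row. Returns the
    (rows, cols) shape and one record per signal with its flat index,
    (row, col) cell and original multi-index; trailing grid cells beyond
    ``n_signals`` stay empty. The flat-index -> cell mapping is a
    bijection.
    """
    shape = tuple(
        s for ax, s in enumerate(ds.data.shape) if ax != ds.time_axis
    ) or (1,)
    n = ds.n_signals
    rows, cols = grid_shape(n)
    mapping = []
    for flat in range(n):
        multi = np.unravel_index(flat, shape)
        mapping.append(
            {
                "flat": flat,
                "row": flat // cols,
                "col": flat % cols,
                "multi_index": tuple(int(m) for m in multi),
            }
        )
    return (rows, cols), mapping


def psd(
    x: np.ndarray, sf: float, nperseg: int | None = None, overlap: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Welch power spectral density of a 1D signal.

    Hann-windowed overlapping segments (default length: 4 s of signal,
    capped at the record length; 50% overlap), averaged periodograms,
    density scaling.
    """
    x = np.asarray(x, dtype=float).ravel()
    if nperseg is None:
        nperseg = min(len(x), int(round(4 * sf)))
    nperseg = min(int(nperseg), len(x))
    noverlap = int(nperseg * overlap)
    freqs, power = sps.welch(
        x, fs=sf, window="hann", nperseg=nperseg, noverlap=noverlap
    )
    return freqs, power


def _morlet_wavelet(sf: float, f: float, width: float) -> np.ndarray:
    """Complex Morlet at frequency f, unit energy, ~4 sigma support."""
    sigma_t = width / (2.0 * np.pi * f)
    half = int(np.ceil(4.0 * sigma_t * sf))
    t = np.arange(-half, half + 1) / sf
    psi = np.exp(-(t**2) / (2.0 * sigma_t**2)) * np.exp(2j * np.pi * f * t)
    return psi / np.sqrt(np.sum(np.abs(psi) ** 2))


def tf_morlet(
    x: np.ndarray,
    sf: float,
    freqs: np.ndarray,
    width: float = 7.0,
    norm: str = "none",
    baseline: tuple[float, float] | None = None,
) -> np.ndarray:
    """Morlet-wavelet time-frequency power map, (n_freqs, n_times).

    Each row is |x * psi_f|^2 where psi_f is a unit-energy complex
    Morlet of ``width`` cycles (sigma_t = width / (2 pi f)). Baseline
    normalization (over samples with t0 <= t < t1, t in seconds) is one
    of:

    - ``none``     raw power
    - ``subtract`` power - mean
    - ``divide``   power / mean
    - ``percent``  100 * (power - mean) / mean
    - ``zscore``   (power - mean) / std

    applied per frequency row.
    """
    x = np.asarray(x, dtype=float).ravel()
    freqs = np.asarray(freqs, dtype=float).ravel()
    if np.any(freqs <= 0) or np.any(freqs >= sf / 2.0):
        raise ValueError(f"freqs must lie in (0, sf/2) = (0, {sf / 2})")
    if norm not in ("none", "subtract", "divide", "percent", "zscore"):
        raise ValueError(f"unknown norm {norm!r}")
    if norm != "none" and baseline is None:
        raise ValueError(f"norm {norm!r} requires baseline=(t0, t1)")

    power = np.empty((len(freqs), len(x)))
    for fi, f in enumerate(freqs):
        psi = _morlet_wavelet(sf, f, width)
        conv = sps.fftconvolve(x, psi, mode="same")
        power[fi] = np.abs(conv) ** 2

    if norm == "none":
        return power
    t0, t1 = baseline
    duration = len(x) / sf
    if not (0 <= t0 < t1 <= duration):
        raise ValueError(f"baseline ({t0}, {t1}) outside record [0, {duration}]s")
    i0, i1 = int(round(t0 * sf)), max(int(round(t1 * sf)), int(round(t0 * sf)) + 1)
    base = power[:, i0:i1]
    mean = base.mean(axis=1, keepdims=True)
    if norm == "subtract":
        return power - mean
    if norm == "divide":
        return power / mean
    if norm == "percent":
        return 100.0 * (power - mean) / mean
    std = base.std(axis=1, keepdims=True)
    return (power - mean) / std


def histogram(x: np.ndarray, nbins: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Equal-width histogram; returns (counts, bin edges)."""
    x = np.asarray(x, dtype=float).ravel()
    if nbins < 1:
        raise ValueError("nbins must be >= 1")
    return np.histogram(x, bins=nbins)


def detect_extrema(
    x: np.ndarray, lower: float, upper: float
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Samples strictly beyond a lower or upper threshold.

    Returns the index vector of samples with ``x > upper`` or
    ``x < lower`` (strict on both sides) and the maximal contiguous runs
    as half-open [start, end) sample intervals. The runs are disjoint
    and cover exactly the index set.
    """
    x = np.asarray(x, dtype=float).ravel()
    hit = (x > upper) | (x < lower)
    idx = np.flatnonzero(hit)
    runs: list[tuple[int, int]] = []
    if len(idx):
        breaks = np.flatnonzero(np.diff(idx) > 1)
        starts = np.concatenate([[idx[0]], idx[breaks + 1]])
        ends = np.concatenate([idx[breaks] + 1, [idx[-1] + 1]])
        runs = [(int(s), int(e)) for s, e in zip(starts, ends)]
    return idx, runs


def preprocess(x: np.ndarray, sf: float, kind: str, **params) -> np.ndarray:
    """Basic signal conditioning: demean, detrend, smooth, or filter.

    - ``demean``: subtract the mean.
    - ``detrend``: remove the least-squares line.
    - ``smooth``: centered moving average of ``window`` samples; edges
      average over the available (truncated) window.
    - ``filter``: zero-phase Butterworth (order ``order``, default 4);
      ``btype`` in {lowpass, highpass, bandpass, bandstop} with cutoff
      ``freq`` (scalar, or (low, high) for band types) in Hz.
    """
    x = np.asarray(x, dtype=float).ravel()
    if kind == "demean":
        return x - x.mean()
    if kind == "detrend":
        return sps.detrend(x, type="linear")
    if kind == "smooth":
        w = int(params.get("window", 5))
        if w < 1:
            raise ValueError("smooth window must be >= 1")
        kernel = np.ones(w)
        num = np.convolve(x, kernel, mode="same")
        den = np.convolve(np.ones_like(x), kernel, mode="same")
        return num / den
    if kind == "filter":
        btype = params.get("btype", "bandpass")
        order = int(params.get("order", 4))
        freq = np.atleast_1d(np.asarray(params["freq"], dtype=float))
        sos = sps.butter(order, freq, btype=btype, fs=sf, output="sos")
        return sps.sosfiltfilt(sos, x)
    raise ValueError(f"unknown preprocessing kind {kind!r}")


def hypnogram_stats(h: Hypnogram) -> dict[str, dict[str, float]]:
    """Per-stage duration (minutes) and percentage of the record.

    Percentages are over all epochs including artefact and sum to 100.
    """
    n = len(h.stages)
    out: dict[str, dict[str, float]] = {}
    for code, name in STAGE_NAMES.items():
        count = int(np.sum(h.stages == code))
        out[name] = {
            "epochs": count,
            "minutes": count * h.epoch_s / 60.0,
            "percent": 100.0 * count / n,
        }
    return out
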