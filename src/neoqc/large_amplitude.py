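"""Large-amplitude fluctuation detection (movement and muscle artifacts).

The recording is tiled with non-overlapping windows (default 3 s) and
three features are computed per channel and window:

* MAFD — maximal absolute first difference, sensitive to abrupt jumps;
* MAA  — maximal absolute amplitude;
* RFC  — ratio of Welch spectral power above 50 Hz to total power, a
  surrogate for muscle (EMG) contamination, computed on the notch-only
  view because the 0.5–40 Hz band-pass would erase that content.

A window is removed when at least one channel meets one of four criteria:

1. MAFD > 4.5·(median + MAD) of that channel's MAFD over all windows;
2. MAA > 150 µV (PT150): certainly non-cortical at term age;
3. 100 µV < MAA < 150 µV (doubtful range) and RFC > 1.5·(median + MAD)
   of that channel's RFC;
4. doubtful-range MAA and the window before and/or after was already
   selected by criteria 1–3 (single sweep, no iterative propagation).

All comparisons are strict, the MAD is unscaled (median of absolute
deviations from the median), and the per-channel thresholds pool every
window of the recording.  Selected windows fuse when consecutive, and
resulting intervals at most 6 s apart fuse again.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .model import DetectorConfig, Interval, IntervalSet, Recording

__all__ = [
    "WindowGrid",
    "WindowFeatures",
    "ChannelThresholds",
    "SelectionTable",
    "segment_windows",
    "compute_mafd",
    "compute_maa",
    "compute_rfc",
    "window_features",
    "channel_thresholds",
    "apply_criteria",
    "merge_selected",
    "detect_large_amplitude",
]


@dataclass
class WindowGrid:
    """Contiguous non-overlapping windows tiling a recording.

    ``edges`` holds sample indices: window ``w`` covers samples
    ``edges[w]:edges[w+1]``.  The last window may be longer (a trailing
    remainder under 1 s is absorbed into it) or shorter (a remainder of
    at least 1 s stands alone), keeping Welch estimates stable.
    """

    window_s: float
    fs: float
    edges: np.ndarray  # int array of length n_windows + 1

    @property
    def n_windows(self) -> int:
        return len(self.edges) - 1

    def bounds_s(self, w: int) -> tuple[float, float]:
        return self.edges[w] / self.fs, self.edges[w + 1] / self.fs


def segment_windows(n_samples: int, fs: float, window_s: float) -> WindowGrid:
    """Tile ``n_samples`` with non-overlapping windows of ``window_s``."""
    if window_s <= 0:
        raise ValueError(f"window_s must be positive, got {window_s}")
    if n_samples <= 0:
        raise ValueError("empty recording")
    wlen = int(round(window_s * fs))
    n_full = n_samples // wlen
    rem = n_samples - n_full * wlen
    if n_full == 0:
        edges = [0, n_samples]
    else:
        edges = list(range(0, (n_full + 1) * wlen, wlen))
        if rem >= fs:            # >= 1 s of remainder: own (short) window
            edges.append(n_samples)
        elif rem > 0:            # < 1 s: absorb into the last window
            edges[-1] = n_samples
    return WindowGrid(window_s, fs, np.asarray(edges, dtype=np.int64))


def compute_mafd(x: np.ndarray) -> float:
    """Maximal absolute first difference of a window."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("MAFD needs at least 2 samples")
    return float(np.max(np.abs(np.diff(x))))


def compute_maa(x: np.ndarray) -> float:
    """Maximal absolute amplitude of a window."""
    x = np.asarray(x, dtype=float)
    if x.size < 1:
        raise ValueError("MAA needs at least 1 sample")
    return float(np.max(np.abs(x)))


def compute_rfc(
    x: np.ndarray,
    fs: float,
    cut_hz: float = 50.0,
    nperseg: int | None = None,
) -> float:
    """Fraction of Welch spectral power strictly above ``cut_hz``.

    One-sided Welch estimate with Hamming sub-windows of
    ``min(256, len(x))`` samples and 50% overlap.  An all-zero window has
    no power anywhere and returns 0 by convention.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("RFC needs at least 2 samples")
    if not np.any(x):
        return 0.0
    if nperseg is None:
        nperseg = min(256, x.size)
    freqs, psd = signal.welch(
        x, fs=fs, window="hamming", nperseg=nperseg, noverlap=nperseg // 2
    )
    total = psd.sum()
    if total <= 0:
        return 0.0
    return float(psd[freqs > cut_hz].sum() / total)


@dataclass
class WindowFeatures:
    """Per-channel, per-window feature arrays of shape (C, W)."""

    mafd: np.ndarray
    maa: np.ndarray
    rfc: np.ndarray

    def __post_init__(self) -> None:
        if not (self.mafd.shape == self.maa.shape == self.rfc.shape):
            raise ValueError("feature arrays must share one (C, W) shape")

    @property
    def n_channels(self) -> int:
        return self.mafd.shape[0]

    @property
    def n_windows(self) -> int:
        return self.mafd.shape[1]

    def to_frame(self, grid: WindowGrid | None = None) -> pd.DataFrame:
        rows = []
        for ch in range(self.n_channels):
            for w in range(self.n_windows):
                rows.append(
                    {
                        "channel": ch,
                        "window": w,
                        "window_start_s": grid.bounds_s(w)[0] if grid else np.nan,
                        "mafd": self.mafd[ch, w],
                        "maa": self.maa[ch, w],
                        "rfc": self.rfc[ch, w],
                    }
                )
        return pd.DataFrame(rows)


def window_features(
    band: Recording,
    notched: Recording,
    grid: WindowGrid,
    config: DetectorConfig | None = None,
) -> WindowFeatures:
    """Compute MAFD/MAA (band view) and RFC (notch-only view) per window."""
    config = config or DetectorConfig()
    if band.data.shape != notched.data.shape:
        raise ValueError("band and notched views are not aligned")
    C, W = band.n_channels, grid.n_windows
    mafd = np.zeros((C, W))
    maa = np.zeros((C, W))
    rfc = np.zeros((C, W))
    for w in range(W):
        i0, i1 = grid.edges[w], grid.edges[w + 1]
        seg_band = band.data[:, i0:i1]
        mafd[:, w] = np.max(np.abs(np.diff(seg_band, axis=1)), axis=1)
        maa[:, w] = np.max(np.abs(seg_band), axis=1)
        for ch in range(C):
            rfc[ch, w] = compute_rfc(
                notched.data[ch, i0:i1], notched.fs, config.rfc_cut_hz
            )
    return WindowFeatures(mafd, maa, rfc)


@dataclass
class ChannelThresholds:
    """Channel-specific robust thresholds: mult·(median + unscaled MAD)."""

    mafd_cut: np.ndarray
    rfc_cut: np.ndarray


def _median_plus_mad(values: np.ndarray) -> np.ndarray:
    med = np.median(values, axis=1)
    mad = np.median(np.abs(values - med[:, None]), axis=1)
    return med + mad


def channel_thresholds(
    features: WindowFeatures, config: DetectorConfig | None = None
) -> ChannelThresholds:
    """Per-channel MAFD and RFC cuts over all windows of the recording."""
    config = config or DetectorConfig()
    if features.n_windows < 2:
        raise ValueError(
            "cannot form channel thresholds from a single window"
        )
    return ChannelThresholds(
        mafd_cut=config.mafd_mult * _median_plus_mad(features.mafd),
        rfc_cut=config.rfc_mult * _median_plus_mad(features.rfc),
    )


@dataclass
class SelectionTable:
    """Window selection outcome.

    ``criterion[w]`` is the lowest-numbered criterion (1–4) that fired
    for a selected window, 0 otherwise; ``channels[w]`` lists the
    channel indices meeting that criterion.
    """

    selected: np.ndarray
    criterion: np.ndarray
    channels: list[tuple[int, ...]] = field(default_factory=list)

    def to_frame(self, grid: WindowGrid | None = None) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "window": np.arange(len(self.selected)),
                "window_start_s": (
                    [grid.bounds_s(w)[0] for w in range(grid.n_windows)]
                    if grid
                    else np.nan
                ),
                "selected": self.selected,
                "criterion": self.criterion,
                "channels": [",".join(map(str, c)) for c in self.channels],
            }
        )


def apply_criteria(
    features: WindowFeatures,
    thresholds: ChannelThresholds,
    config: DetectorConfig | None = None,
) -> SelectionTable:
    """Evaluate the four removal criteria on a feature table.

    Pass A applies criteria 1–3 per channel; pass B (criterion 4) then
    marks doubtful-amplitude windows adjacent to a pass-A selection, in a
    single backward+forward sweep — criterion-4 selections never seed
    further criterion-4 selections.  The doubtful-amplitude channel and
    the neighbour's triggering channel need not coincide.
    """
    config = config or DetectorConfig()
    C, W = features.mafd.shape
    if thresholds.mafd_cut.shape != (C,) or thresholds.rfc_cut.shape != (C,):
        raise ValueError("thresholds are not aligned with the feature table")

    doubtful = (config.pt100 < features.maa) & (features.maa < config.pt150)
    crit = np.zeros((3, C, W), dtype=bool)
    if config.enable_criterion_1:
        crit[0] = features.mafd > thresholds.mafd_cut[:, None]
    if config.enable_criterion_2:
        crit[1] = features.maa > config.pt150
    if config.enable_criterion_3:
        crit[2] = doubtful & (features.rfc > thresholds.rfc_cut[:, None])

    pass_a = crit.any(axis=1)            # (3, W): criterion fired in any channel
    selected_a = pass_a.any(axis=0)

    selected = selected_a.copy()
    criterion = np.zeros(W, dtype=np.int64)
    channels: list[tuple[int, ...]] = [()] * W
    for w in range(W):
        if selected_a[w]:
            k = int(np.argmax(pass_a[:, w]))          # lowest criterion index
            criterion[w] = k + 1
            channels[w] = tuple(np.flatnonzero(crit[k, :, w]))

    if config.enable_criterion_4:
        neighbor_a = np.zeros(W, dtype=bool)
        neighbor_a[:-1] |= selected_a[1:]
        neighbor_a[1:] |= selected_a[:-1]
        doubtful_any = doubtful.any(axis=0)
        pass_b = doubtful_any & neighbor_a & ~selected
        for w in np.flatnonzero(pass_b):
            selected[w] = True
            criterion[w] = 4
            channels[w] = tuple(np.flatnonzero(doubtful[:, w]))

    return SelectionTable(selected, criterion, channels)


def merge_selected(
    selection: SelectionTable,
    grid: WindowGrid,
    merge_gap_s: float = 6.0,
) -> IntervalSet:
    """Fuse selected windows into removal intervals.

    Consecutive selected windows become one interval; intervals separated
    by at most ``merge_gap_s`` (inclusive) fuse again.
    """
    idx = np.flatnonzero(selection.selected)
    if idx.size == 0:
        return IntervalSet()
    raw: list[list[float]] = []
    for w in idx:
        s, e = grid.bounds_s(int(w))
        if raw and s <= raw[-1][1] + 1e-9:
            raw[-1][1] = e
        else:
            raw.append([s, e])
    merged: list[list[float]] = [raw[0]]
    for s, e in raw[1:]:
        if s - merged[-1][1] <= merge_gap_s + 1e-9:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return IntervalSet(
        Interval(s, e, "large_amplitude") for s, e in merged
    )


@dataclass
class LargeAmplitudeResult:
    """Detection output plus the intermediate tables (for reports/plots)."""

    intervals: IntervalSet
    grid: WindowGrid
    features: WindowFeatures
    thresholds: ChannelThresholds
    selection: SelectionTable


def analyze_large_amplitude(
    band: Recording,
    notched: Recording,
    config: DetectorConfig | None = None,
) -> LargeAmplitudeResult:
    """Full chain, returning intervals together with intermediates."""
    config = config or DetectorConfig()
    grid = segment_windows(band.n_samples, band.fs, config.window_s)
    features = window_features(band, notched, grid, config)
    thresholds = channel_thresholds(features, config)
    selection = apply_criteria(features, thresholds, config)
    intervals = merge_selected(selection, grid, config.merge_gap_s)
    return LargeAmplitudeResult(intervals, grid, features, thresholds, selection)


def detect_large_amplitude(
    band: Recording,
    notched: Recording,
    config: DetectorConfig | None = None,
) -> IntervalSet:
    """Detect large-amplitude fluctuation intervals (labelled accordingly)."""
    return analyze_large_amplitude(band, notched, config).intervals
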