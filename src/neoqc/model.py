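"""Core data model: recordings, artifact intervals, detector configuration.

Time convention used throughout the package: seconds, 0-based, half-open
intervals ``[start_s, end_s)``.  Sample ``i`` of a recording sampled at
``fs`` Hz covers the time span ``[i/fs, (i+1)/fs)``, so boolean sample
masks and interval sets are exactly interconvertible on the sample grid.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "LABELS",
    "Recording",
    "Interval",
    "IntervalSet",
    "DetectorConfig",
    "intervals_to_mask",
    "mask_to_intervals",
    "apply_removal",
]

#: Recognised artifact labels.
LABELS = ("flatline", "large_amplitude", "other")

_TOL = 1e-9  # absolute tolerance for interval arithmetic on the time axis


@dataclass
class Recording:
    """Multichannel EEG recording in microvolts.

    Parameters
    ----------
    data
        Array of shape ``(n_channels, n_samples)`` holding amplitudes in µV.
    fs
        Sampling rate in Hz (must be positive).
    channel_names
        One label per row of ``data``.
    start_s
        Onset of the first sample relative to the original acquisition;
        0 for full recordings, nonzero for segments cut out by
        :func:`apply_removal`.
    """

    data: np.ndarray
    fs: float
    channel_names: list[str] = field(default_factory=list)
    start_s: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.data.shape[0])]
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} data rows"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy(self) -> "Recording":
        return Recording(
            self.data.copy(), self.fs, list(self.channel_names), self.start_s
        )


@dataclass(frozen=True)
class Interval:
    """Half-open time interval ``[start_s, end_s)`` with an artifact label.

    ``channels`` optionally restricts the interval to a subset of channel
    indices; ``None`` means all channels (the common case: both detectors
    emit whole-montage intervals).
    """

    start_s: float
    end_s: float
    label: str = "other"
    channels: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError(
                f"interval end {self.end_s} not after start {self.start_s}"
            )
        if self.start_s < 0:
            raise ValueError(f"interval start {self.start_s} is negative")
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}; expected one of {LABELS}")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def _merge_same_label(intervals: Iterable[Interval]) -> list[Interval]:
    """Sort and merge overlapping or touching same-label intervals."""
    by_label: dict[str, list[Interval]] = {}
    for iv in intervals:
        by_label.setdefault(iv.label, []).append(iv)
    merged: list[Interval] = []
    for label, ivs in by_label.items():
        ivs.sort(key=lambda iv: (iv.start_s, iv.end_s))
        cur = ivs[0]
        for nxt in ivs[1:]:
            if nxt.start_s <= cur.end_s + _TOL:
                chans = None
                if cur.channels is not None and nxt.channels is not None:
                    chans = tuple(sorted(set(cur.channels) | set(nxt.channels)))
                cur = Interval(
                    cur.start_s, max(cur.end_s, nxt.end_s), label, chans
                )
            else:
                merged.append(cur)
                cur = nxt
        merged.append(cur)
    merged.sort(key=lambda iv: (iv.start_s, iv.end_s, iv.label))
    return merged


class IntervalSet:
    """Ordered collection of intervals, disjoint within each label.

    Construction normalises the input: intervals are sorted by onset and
    overlapping or touching intervals sharing a label are fused.
    """

    def __init__(self, intervals: Iterable[Interval] = ()) -> None:
        intervals = list(intervals)
        self._intervals: list[Interval] = (
            _merge_same_label(intervals) if intervals else []
        )

    def __iter__(self) -> Iterator[Interval]:
        return iter(self._intervals)

    def __len__(self) -> int:
        return len(self._intervals)

    def __getitem__(self, i: int) -> Interval:
        return self._intervals[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        if len(self) != len(other):
            return False
        return all(
            abs(a.start_s - b.start_s) < _TOL
            and abs(a.end_s - b.end_s) < _TOL
            and a.label == b.label
            for a, b in zip(self, other)
        )

    def __repr__(self) -> str:
        return f"IntervalSet({self._intervals!r})"

    @property
    def total_duration_s(self) -> float:
        """Duration of the union of all intervals (labels pooled)."""
        if not self._intervals:
            return 0.0
        ivs = sorted(self._intervals, key=lambda iv: iv.start_s)
        total = 0.0
        cur_start, cur_end = ivs[0].start_s, ivs[0].end_s
        for iv in ivs[1:]:
            if iv.start_s <= cur_end + _TOL:
                cur_end = max(cur_end, iv.end_s)
            else:
                total += cur_end - cur_start
                cur_start, cur_end = iv.start_s, iv.end_s
        return total + (cur_end - cur_start)

    def with_label(self, label: str) -> "IntervalSet":
        return IntervalSet(iv for iv in self if iv.label == label)

    def clip(self, start_s: float, end_s: float) -> "IntervalSet":
        """Intersect every interval with ``[start_s, end_s)``."""
        out = []
        for iv in self:
            a, b = max(iv.start_s, start_s), min(iv.end_s, end_s)
            if b - a > _TOL:
                out.append(Interval(a, b, iv.label, iv.channels))
        return IntervalSet(out)

    def union(self, other: "IntervalSet") -> "IntervalSet":
        return IntervalSet(list(self) + list(other))

    def to_records(self) -> list[dict]:
        return [
            {"start_s": iv.start_s, "end_s": iv.end_s, "label": iv.label}
            for iv in self
        ]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_records(), fh, indent=1)

    @classmethod
    def from_records(cls, records: Sequence[dict]) -> "IntervalSet":
        return cls(
            Interval(r["start_s"], r["end_s"], r.get("label", "other"))
            for r in records
        )


def intervals_to_mask(
    intervals: Iterable[Interval], fs: float, n_samples: int
) -> np.ndarray:
    """Rasterise intervals onto the sample grid.

    Sample ``i`` is flagged iff its timestamp ``i/fs`` lies inside some
    interval (half-open convention).  Intervals are clipped to the
    recording extent.
    """
    if n_samples < 0:
        raise ValueError("n_samples must be non-negative")
    mask = np.zeros(int(n_samples), dtype=bool)
    for iv in intervals:
        i0 = int(np.ceil(iv.start_s * fs - _TOL))
        i1 = int(np.ceil(iv.end_s * fs - _TOL))
        mask[max(i0, 0) : max(min(i1, n_samples), 0)] = True
    return mask


def mask_to_intervals(
    mask: np.ndarray, fs: float, label: str = "other"
) -> IntervalSet:
    """Convert maximal runs of True samples into intervals (inverse of
    :func:`intervals_to_mask` for grid-aligned sets)."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0 or not mask.any():
        return IntervalSet()
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]
    return IntervalSet(
        Interval(s / fs, e / fs, label) for s, e in zip(starts, ends)
    )


def apply_removal(
    recording: Recording, intervals: IntervalSet | Iterable[Interval]
) -> tuple[list[Recording], IntervalSet]:
    """Cut artifact intervals out of a recording.

    Returns the maximal artifact-free sub-recordings (each carrying its
    original onset in ``start_s``) together with the kept intervals.  Time
    is conserved exactly on the sample grid: kept + removed spans the
    whole recording.
    """
    removed = intervals_to_mask(intervals, recording.fs, recording.n_samples)
    kept = mask_to_intervals(~removed, recording.fs, "other")
    segments = []
    for iv in kept:
        i0 = int(round(iv.start_s * recording.fs))
        i1 = int(round(iv.end_s * recording.fs))
        segments.append(
            Recording(
                recording.data[:, i0:i1].copy(),
                recording.fs,
                list(recording.channel_names),
                start_s=recording.start_s + iv.start_s,
            )
        )
    return segments, kept


@dataclass
class DetectorConfig:
    """All thresholds and durations of the artifact detector.

    Defaults are the published operating point for term-age neonatal EEG
    sampled at 250–256 Hz.

    Flat-line stage
    ---------------
    flat_threshold : µV
        Strict upper bound on the absolute second difference for a sample
        to count as flat (default 1e-4 µV).
    flat_min_flags_per_second : int
        Minimum number of sub-threshold samples within a 1-s bin for the
        bin's sub-threshold samples to be flagged (default 2, the minimal
        reading of "multiple samples").
    flat_group_gap_s : s
        Flagged samples at most this far apart are chained into one
        candidate interval (default 2.5 s).
    consensus_fraction
        Fraction of channels that must exhibit a candidate interval for it
        to be accepted; the channel count is ``round(fraction * C)``,
        giving 14/19 and 7/9 at the default 0.75.
    pad_short_s, pad_long_s, pad_cutoff_s : s
        Detected flat intervals no longer than ``pad_cutoff_s`` (5 s) grow
        by ``pad_short_s`` (1 s) on each side, longer ones by
        ``pad_long_s`` (3 s).

    Large-amplitude stage
    ---------------------
    window_s : s
        Non-overlapping analysis window duration (default 3 s; 1–7 s are
        sensible).
    pt100, pt150 : µV
        Physiological amplitude thresholds: between them a window is
        "doubtful", above ``pt150`` it is removed unconditionally.
    mafd_mult, rfc_mult
        Multipliers of (median + MAD) forming the channel-specific
        thresholds on the maximal absolute first difference and on the
        high-frequency power ratio.
    rfc_cut_hz : Hz
        Spectral split point of the power ratio (default 50 Hz).
    merge_gap_s : s
        Selected intervals separated by at most this much fuse (6 s).

    Pre-processing
    --------------
    notch_hz, notch_q, bandpass_hz, bandpass_order
        Power-line notch frequency/quality factor and band-pass edges/order.
    """

    # flat-line stage
    flat_threshold: float = 1e-4
    flat_min_flags_per_second: int = 2
    flat_group_gap_s: float = 2.5
    consensus_fraction: float = 0.75
    pad_short_s: float = 1.0
    pad_long_s: float = 3.0
    pad_cutoff_s: float = 5.0
    # large-amplitude stage
    window_s: float = 3.0
    pt100: float = 100.0
    pt150: float = 150.0
    mafd_mult: float = 4.5
    rfc_mult: float = 1.5
    rfc_cut_hz: float = 50.0
    merge_gap_s: float = 6.0
    # pre-processing
    notch_hz: float = 50.0
    notch_q: float = 30.0
    bandpass_hz: tuple[float, float] = (0.5, 40.0)
    bandpass_order: int = 4
    # stage / criterion switches
    enable_flatline: bool = True
    enable_large_amplitude: bool = True
    enable_criterion_1: bool = True
    enable_criterion_2: bool = True
    enable_criterion_3: bool = True
    enable_criterion_4: bool = True

    def __post_init__(self) -> None:
        self.bandpass_hz = tuple(self.bandpass_hz)  # type: ignore[assignment]
        self.validate()

    def validate(self) -> None:
        problems = []
        if self.pt100 >= self.pt150:
            problems.append(f"pt100 ({self.pt100}) must be < pt150 ({self.pt150})")
        if not (0 < self.consensus_fraction <= 1):
            problems.append(
                f"consensus_fraction ({self.consensus_fraction}) must be in (0, 1]"
            )
        if self.window_s <= 0:
            problems.append(f"window_s ({self.window_s}) must be positive")
        if self.flat_threshold <= 0:
            problems.append(f"flat_threshold ({self.flat_threshold}) must be positive")
        for key in ("flat_group_gap_s", "pad_short_s", "pad_long_s",
                    "pad_cutoff_s", "merge_gap_s"):
            if getattr(self, key) < 0:
                problems.append(f"{key} ({getattr(self, key)}) must be >= 0")
        if len(self.bandpass_hz) != 2 or self.bandpass_hz[0] >= self.bandpass_hz[1]:
            problems.append(f"bandpass_hz {self.bandpass_hz} must be (lo, hi), lo < hi")
        if problems:
            raise ValueError("invalid configuration: " + "; ".join(problems))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["bandpass_hz"] = list(self.bandpass_hz)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DetectorConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**d)
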