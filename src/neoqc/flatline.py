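"""Flat-line segment detection.

A lost electrode contact leaves the signal exactly constant, so the
absolute second difference of the trace drops (essentially) to zero.
The detector chains five steps per recording:

1. second difference of every channel (insensitive to DC offset and to
   linear drift);
2. per 1-second bin, flag all sub-threshold samples when at least
   ``flat_min_flags_per_second`` of them fall in the bin — isolated
   sub-threshold samples are noise, not flat line;
3. chain flagged samples at most ``flat_group_gap_s`` apart into
   per-channel candidate intervals (bridges samples that sit slightly
   above threshold inside a flat stretch);
4. accept only spans covered by candidates in at least
   ``round(consensus_fraction · C)`` of the C channels (14/19, 7/9 at
   the default 75%) — lost head-box contact affects the whole montage;
5. pad each accepted interval by 1 s (3 s if it is longer than 5 s) on
   both sides, to absorb the sharp deflections that typically flank a
   flat segment.

Detection runs on the *raw* (unfiltered) view: any filtering smears a
constant segment into a non-constant one.
"""

from __future__ import annotations

import numpy as np

from .model import (
    DetectorConfig,
    Interval,
    IntervalSet,
    Recording,
    intervals_to_mask,
    mask_to_intervals,
)

__all__ = [
    "second_difference",
    "flag_flat_samples",
    "group_flags",
    "consensus",
    "pad_intervals",
    "detect_flatlines",
]


def second_difference(x: np.ndarray) -> np.ndarray:
    """z(n) = x(n+2) − 2·x(n+1) + x(n), length N−2.

    Zero for constant and linearly drifting signals alike.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("second difference needs a 1-D signal of >= 3 samples")
    return np.diff(x, n=2)


def flag_flat_samples(
    z: np.ndarray,
    fs: float,
    threshold: float = 1e-4,
    min_flags_per_second: int = 2,
) -> np.ndarray:
    """Times (s) of second-difference samples suspected to be flat.

    Time is partitioned into consecutive 1-s bins; within each bin the
    samples with ``|z| < threshold`` (strict) are flagged only if the bin
    holds at least ``min_flags_per_second`` of them — they need not be
    consecutive.  Sample ``z[n]`` is timestamped ``n / fs``.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    z = np.asarray(z, dtype=float)
    idx = np.flatnonzero(np.abs(z) < threshold)
    if idx.size == 0:
        return np.empty(0, dtype=float)
    bins = np.floor(idx / fs).astype(np.int64)
    _, inverse, counts = np.unique(bins, return_inverse=True, return_counts=True)
    keep = counts[inverse] >= min_flags_per_second
    return idx[keep] / fs


def group_flags(
    times: np.ndarray, fs: float, gap_s: float = 2.5
) -> IntervalSet:
    """Chain flagged sample times into candidate intervals.

    Successive times at most ``gap_s`` apart belong to one chain; a chain
    spanning samples [t_first, t_last] becomes the half-open interval
    ``[t_first, t_last + 1/fs)``.  Singleton chains are allowed.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        return IntervalSet()
    if np.any(np.diff(times) < 0):
        raise ValueError("flagged times must be sorted")
    breaks = np.flatnonzero(np.diff(times) > gap_s + 1e-12) + 1
    intervals = []
    for chunk in np.split(times, breaks):
        intervals.append(Interval(chunk[0], chunk[-1] + 1.0 / fs, "other"))
    return IntervalSet(intervals)


def consensus(
    candidates: list[IntervalSet],
    n_channels: int,
    fraction: float,
    fs: float,
    n_samples: int,
) -> IntervalSet:
    """Keep only time spans flagged in at least ``round(fraction·C)`` channels.

    ``candidates`` holds one per-channel candidate set.  The channel-count
    profile is evaluated sample-wise on the recording grid and maximal
    runs meeting the quorum are returned.
    """
    if n_channels <= 0:
        raise ValueError("n_channels must be positive")
    if len(candidates) != n_channels:
        raise ValueError(
            f"{len(candidates)} candidate sets for {n_channels} channels"
        )
    quorum = max(int(round(fraction * n_channels)), 1)
    counts = np.zeros(n_samples, dtype=np.int32)
    for cset in candidates:
        counts += intervals_to_mask(cset, fs, n_samples)
    return mask_to_intervals(counts >= quorum, fs, "flatline")


def pad_intervals(
    intervals: IntervalSet,
    cutoff_s: float = 5.0,
    pad_short_s: float = 1.0,
    pad_long_s: float = 3.0,
    duration_s: float = np.inf,
) -> IntervalSet:
    """Grow each interval on both sides, more for long ones.

    Intervals of duration ≤ ``cutoff_s`` grow by ``pad_short_s`` per side,
    longer ones by ``pad_long_s``; results are clipped to
    ``[0, duration_s]`` and re-merged where they now overlap.
    """
    out = []
    for iv in intervals:
        pad = pad_short_s if iv.duration_s <= cutoff_s else pad_long_s
        out.append(
            Interval(
                max(iv.start_s - pad, 0.0),
                min(iv.end_s + pad, duration_s),
                iv.label,
                iv.channels,
            )
        )
    return IntervalSet(out)


def detect_flatlines(
    recording: Recording, config: DetectorConfig | None = None
) -> IntervalSet:
    """Full flat-line chain on the raw view of a recording."""
    config = config or DetectorConfig()
    if recording.n_samples < 3:
        raise ValueError("recording too short for flat-line detection")
    candidates = []
    for ch in range(recording.n_channels):
        z = second_difference(recording.data[ch])
        times = flag_flat_samples(
            z,
            recording.fs,
            config.flat_threshold,
            config.flat_min_flags_per_second,
        )
        candidates.append(group_flags(times, recording.fs, config.flat_group_gap_s))
    agreed = consensus(
        candidates,
        recording.n_channels,
        config.consensus_fraction,
        recording.fs,
        recording.n_samples,
    )
    return pad_intervals(
        agreed,
        config.pad_cutoff_s,
        config.pad_short_s,
        config.pad_long_s,
        recording.duration_s,
    )
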