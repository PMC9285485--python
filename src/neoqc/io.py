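"""Readers and writers: EDF recordings, annotation CSV tables, interval JSON.

EDF reading delegates to :mod:`mne`; the writer here is a deliberately
small EDF encoder (16-bit, 1-second data records) used to serialise
synthetic fixtures — it is not a general-purpose exporter.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .model import Interval, IntervalSet, LABELS, Recording

__all__ = [
    "EDFFormatError",
    "AnnotationFormatError",
    "read_edf",
    "write_edf",
    "read_annotations",
    "write_annotations",
]


class EDFFormatError(ValueError):
    """Raised for structurally invalid or unsupported EDF content."""


class AnnotationFormatError(ValueError):
    """Raised for malformed annotation tables."""


def _edf_samples_per_record(path: Path) -> tuple[list[str], list[int], float]:
    """Parse channel labels, samples-per-record and record duration from an
    EDF header (mne silently resamples mixed-rate files, so the rate check
    must look at the raw header)."""
    with open(path, "rb") as fh:
        header = fh.read(256)
        if len(header) < 256:
            raise EDFFormatError(f"{path}: truncated EDF header")
        try:
            record_dur = float(header[244:252].decode("ascii").strip())
            ns = int(header[252:256].decode("ascii").strip())
        except ValueError as exc:
            raise EDFFormatError(f"{path}: malformed EDF header") from exc
        sig = fh.read(ns * 256)
    if len(sig) < ns * 256:
        raise EDFFormatError(f"{path}: truncated EDF signal header")
    labels = [
        sig[16 * i : 16 * (i + 1)].decode("ascii", "replace").strip()
        for i in range(ns)
    ]
    off = ns * 216
    nsamp = [
        int(sig[off + 8 * i : off + 8 * (i + 1)].decode("ascii").strip())
        for i in range(ns)
    ]
    return labels, nsamp, record_dur


def read_edf(path, channels: list[str] | None = None) -> Recording:
    """Load an EDF/EDF+ file into a :class:`Recording` in µV.

    Parameters
    ----------
    path
        EDF file path.
    channels
        Optional channel-name whitelist (e.g. to drop non-EEG channels);
        ``None`` keeps every signal except EDF+ annotation channels.

    Raises
    ------
    EDFFormatError
        If the selected channels do not share one sampling rate, or the
        header is malformed.
    """
    import mne

    path = Path(path)
    labels, nsamp, record_dur = _edf_samples_per_record(path)
    keep = [
        (lab, n)
        for lab, n in zip(labels, nsamp)
        if lab != "EDF Annotations" and (channels is None or lab in channels)
    ]
    if not keep:
        raise EDFFormatError(f"{path}: no matching signal channels")
    rates = {n / record_dur for _, n in keep}
    if len(rates) > 1:
        raise EDFFormatError(
            f"{path}: mixed sampling rates among selected channels: "
            f"{sorted(rates)} Hz"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    picks = [lab for lab, _ in keep if lab in raw.ch_names]
    raw.pick(picks)
    data_uv = raw.get_data() * 1e6  # mne returns Volts
    if not np.all(np.isfinite(data_uv)):
        raise EDFFormatError(f"{path}: non-finite samples after loading")
    return Recording(data_uv, float(raw.info["sfreq"]), list(raw.ch_names))


def _ascii_field(value, width: int) -> bytes:
    s = f"{value}"
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def write_edf(
    recording: Recording, path, physical_max_uv: float = 1000.0
) -> None:
    """Serialise a recording to a minimal EDF file (fixture writer).

    Samples are quantised to 16 bits over ``±physical_max_uv`` (default
    ±1000 µV, wide enough for >150 µV artifacts without clipping) in
    1-second data records; the recording duration must therefore be a
    whole number of seconds and ``fs`` integral.
    """
    path = Path(path)
    fs = recording.fs
    if abs(fs - round(fs)) > 1e-9:
        raise EDFFormatError(f"fixture writer needs an integer fs, got {fs}")
    fs = int(round(fs))
    n_ch, n_samp = recording.data.shape
    if n_samp % fs:
        raise EDFFormatError(
            "fixture writer needs a whole number of seconds "
            f"({n_samp} samples at {fs} Hz)"
        )
    n_records = n_samp // fs
    if np.max(np.abs(recording.data)) > physical_max_uv:
        raise EDFFormatError(
            f"data exceed the ±{physical_max_uv} µV physical range"
        )

    header = b"".join(
        [
            _ascii_field("0", 8),                      # version
            _ascii_field("X X X X", 80),               # patient id
            _ascii_field("Startdate X X X X", 80),     # recording id
            _ascii_field("01.01.00", 8),
            _ascii_field("00.00.00", 8),
            _ascii_field(256 * (1 + n_ch), 8),         # header bytes
            _ascii_field("", 44),
            _ascii_field(n_records, 8),
            _ascii_field(1, 8),                        # record duration (s)
            _ascii_field(n_ch, 4),
        ]
    )
    fields = [
        [_ascii_field(name, 16) for name in recording.channel_names],
        [_ascii_field("", 80)] * n_ch,                 # transducer
        [_ascii_field("uV", 8)] * n_ch,
        [_ascii_field(-physical_max_uv, 8)] * n_ch,
        [_ascii_field(physical_max_uv, 8)] * n_ch,
        [_ascii_field(-32768, 8)] * n_ch,
        [_ascii_field(32767, 8)] * n_ch,
        [_ascii_field("", 80)] * n_ch,                 # prefiltering
        [_ascii_field(fs, 8)] * n_ch,                  # samples per record
        [_ascii_field("", 32)] * n_ch,
    ]
    scale = 32767.0 / physical_max_uv
    digital = np.clip(
        np.round(recording.data * scale), -32768, 32767
    ).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        for block in fields:
            fh.write(b"".join(block))
        for r in range(n_records):
            fh.write(digital[:, r * fs : (r + 1) * fs].tobytes())


def read_annotations(path) -> IntervalSet:
    """Read an annotation table (CSV with header onset_s,duration_s,label).

    Overlapping same-label rows are merged; rows with an unrecognised
    label are kept with label ``other`` and a warning; negative durations
    are rejected.
    """
    df = pd.read_csv(path)
    required = {"onset_s", "duration_s", "label"}
    if not required.issubset(df.columns):
        raise AnnotationFormatError(
            f"{path}: expected columns {sorted(required)}, got {list(df.columns)}"
        )
    intervals = []
    for row in df.itertuples(index=False):
        if row.duration_s <= 0:
            raise AnnotationFormatError(
                f"{path}: non-positive duration {row.duration_s} at onset {row.onset_s}"
            )
        label = str(row.label)
        if label not in LABELS:
            warnings.warn(
                f"unknown annotation label {label!r}; keeping as 'other'",
                stacklevel=2,
            )
            label = "other"
        intervals.append(
            Interval(float(row.onset_s), float(row.onset_s + row.duration_s), label)
        )
    return IntervalSet(intervals)


def write_annotations(intervals: IntervalSet, path) -> None:
    """Write intervals as an onset/duration/label CSV (round-trips with
    :func:`read_annotations` to within 1e-9 s)."""
    pd.DataFrame(
        [
            {"onset_s": iv.start_s, "duration_s": iv.duration_s, "label": iv.label}
            for iv in intervals
        ],
        columns=["onset_s", "duration_s", "label"],
    ).to_csv(path, index=False, float_format="%.9f")
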