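"""Seeded generator of neonatal-like multichannel EEG with ground truth.

The background is 1/f-shaped Gaussian noise scaled to a target RMS
(default 20 µV) — enough to exercise every threshold of the detector,
though it carries none of the sleep-stage structure, asymmetries or
non-stationarities of real neonatal EEG.  Two artifact families can be
injected on top, each recorded as a ground-truth interval:

* flat events — selected channels (default: all, as when head-box
  contact is lost) hold a constant value, optionally flanked by a
  one-sample sharp deflection just outside the event;
* bursts — "movement" (low-frequency, default 2 Hz, peaks well above
  150 µV) or "muscle" (default 60 Hz, visible only to the RFC feature
  before band-pass filtering), Tukey-tapered to confine their energy to
  the event span.

Everything is deterministic given the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal.windows import tukey

from .model import Interval, IntervalSet, Recording

__all__ = [
    "FlatEvent",
    "BurstEvent",
    "SimulationSpec",
    "generate_background",
    "inject_flat",
    "inject_burst",
    "generate_dataset",
    "default_spec",
]


@dataclass(frozen=True)
class FlatEvent:
    """All-channel (or subset) constant segment, as from lost contact."""

    onset_s: float
    duration_s: float
    channels: tuple[int, ...] | None = None  # None = all channels
    edge_deflection_uv: float = 0.0


@dataclass(frozen=True)
class BurstEvent:
    """High-amplitude transient: movement (low-f) or muscle (high-f)."""

    onset_s: float
    duration_s: float
    peak_uv: float = 300.0
    kind: str = "movement"  # "movement" (<=5 Hz) or "muscle" (>=55 Hz)
    freq_hz: float | None = None
    channels: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("movement", "muscle"):
            raise ValueError(f"unknown burst kind {self.kind!r}")

    @property
    def frequency_hz(self) -> float:
        if self.freq_hz is not None:
            return self.freq_hz
        return 2.0 if self.kind == "movement" else 60.0


@dataclass
class SimulationSpec:
    """Recipe for one synthetic recording."""

    n_channels: int = 9
    fs: float = 250.0
    duration_s: float = 1200.0
    background_rms_uv: float = 20.0
    spectral_exponent: float = 1.0  # power ~ 1/f^exponent
    flat_events: list[FlatEvent] = field(default_factory=list)
    burst_events: list[BurstEvent] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        for ev in list(self.flat_events) + list(self.burst_events):
            if ev.onset_s < 0 or ev.onset_s + ev.duration_s > self.duration_s:
                raise ValueError(
                    f"event [{ev.onset_s}, {ev.onset_s + ev.duration_s}) s "
                    f"outside the {self.duration_s}-s recording"
                )


def generate_background(spec: SimulationSpec) -> Recording:
    """Per-channel 1/f Gaussian noise at the requested RMS (seeded)."""
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.fs))
    white = rng.standard_normal((spec.n_channels, n))
    spectrum = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n, d=1.0 / spec.fs)
    shape = np.zeros_like(freqs)
    nonzero = freqs > 0
    shape[nonzero] = freqs[nonzero] ** (-spec.spectral_exponent / 2.0)
    data = np.fft.irfft(spectrum * shape, n=n, axis=1)
    rms = np.sqrt(np.mean(data**2, axis=1, keepdims=True))
    data *= spec.background_rms_uv / rms
    names = [f"EEG{i + 1}" for i in range(spec.n_channels)]
    return Recording(data, spec.fs, names)


def inject_flat(
    recording: Recording, event: FlatEvent, copy: bool = True
) -> tuple[Recording, Interval]:
    """Overwrite the event span with a constant and return the truth interval.

    The held value is the last pre-onset sample of each channel (0 at the
    very start of the recording).  An optional deflection of
    ``edge_deflection_uv`` is added to the single sample just before and
    just after the event, emulating the sharp transients that flank real
    contact losses while keeping the event itself exactly constant.
    """
    rec = recording.copy() if copy else recording
    fs = rec.fs
    i0 = int(round(event.onset_s * fs))
    i1 = int(round((event.onset_s + event.duration_s) * fs))
    if not (0 <= i0 < i1 <= rec.n_samples):
        raise ValueError("flat event outside the recording")
    chans = (
        range(rec.n_channels) if event.channels is None else event.channels
    )
    for ch in chans:
        hold = rec.data[ch, i0 - 1] if i0 > 0 else 0.0
        rec.data[ch, i0:i1] = hold
        if event.edge_deflection_uv:
            if i0 > 0:
                rec.data[ch, i0 - 1] += event.edge_deflection_uv
            if i1 < rec.n_samples:
                rec.data[ch, i1] -= event.edge_deflection_uv
    truth = Interval(i0 / fs, i1 / fs, "flatline")
    return rec, truth


def inject_burst(
    recording: Recording, event: BurstEvent, copy: bool = True
) -> tuple[Recording, Interval]:
    """Add a Tukey-tapered oscillatory burst and return the truth interval.

    The burst is rescaled after tapering so its largest sample equals
    ``peak_uv`` exactly; outside the event span the signal is untouched.
    """
    rec = recording.copy() if copy else recording
    fs = rec.fs
    i0 = int(round(event.onset_s * fs))
    i1 = int(round((event.onset_s + event.duration_s) * fs))
    if not (0 <= i0 < i1 <= rec.n_samples):
        raise ValueError("burst event outside the recording")
    n = i1 - i0
    t = np.arange(n) / fs
    wave = tukey(n, alpha=0.5) * np.sin(2 * np.pi * event.frequency_hz * t)
    peak = np.max(np.abs(wave))
    if peak > 0:
        wave *= event.peak_uv / peak
    chans = (
        range(rec.n_channels) if event.channels is None else event.channels
    )
    for ch in chans:
        rec.data[ch, i0:i1] += wave
    truth = Interval(i0 / fs, i1 / fs, "large_amplitude")
    return rec, truth


def generate_dataset(
    spec: SimulationSpec, out_dir: str | Path | None = None
) -> tuple[Recording, IntervalSet]:
    """Compose background + events; optionally serialise EDF + truth CSV.

    Overlapping flat events end up merged in the truth set (IntervalSet
    normalisation), mirroring what a single longer contact loss would
    look like.
    """
    rec = generate_background(spec)
    truth: list[Interval] = []
    for ev in spec.flat_events:
        rec, iv = inject_flat(rec, ev, copy=False)
        truth.append(iv)
    for ev in spec.burst_events:
        rec, iv = inject_burst(rec, ev, copy=False)
        truth.append(iv)
    truth_set = IntervalSet(truth)
    if out_dir is not None:
        from .io import write_annotations, write_edf

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_edf(rec, out_dir / "recording.edf")
        write_annotations(truth_set, out_dir / "annotations.csv")
    return rec, truth_set


def default_spec(
    seed: int = 0,
    duration_s: float = 1200.0,
    n_channels: int = 9,
    fs: float = 250.0,
) -> SimulationSpec:
    """Reference study condition: 9 channels, 250 Hz, 20 min, 2 flat
    events (3 s and 10 s) and 6 bursts, placed at seeded random onsets
    without overlap (one event per eighth of the recording; durations
    below ~2 minutes leave no room for the 10-s flat event)."""
    rng = np.random.default_rng(seed)
    duration = float(duration_s)
    slot = duration / 8.0
    starts = rng.permutation(8) * slot + rng.uniform(0.1, 0.35, size=8) * slot
    flats = [
        FlatEvent(float(starts[0]), 3.0, edge_deflection_uv=500.0),
        FlatEvent(float(starts[1]), 10.0, edge_deflection_uv=500.0),
    ]
    bursts = []
    for i, s in enumerate(starts[2:]):
        if i % 3 == 2:
            # combined movement + muscle event in the doubtful amplitude
            # range: the configuration that only the RFC criterion catches
            bursts.append(
                BurstEvent(float(s), 4.0, peak_uv=120.0, kind="movement")
            )
            bursts.append(
                BurstEvent(float(s), 4.0, peak_uv=60.0, kind="muscle")
            )
        else:
            bursts.append(
                BurstEvent(
                    float(s), 5.0, peak_uv=float(rng.uniform(250, 350)),
                    kind="movement",
                )
            )
    return SimulationSpec(
        n_channels=n_channels,
        fs=fs,
        duration_s=duration,
        flat_events=flats,
        burst_events=bursts,
        seed=seed,
    )
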