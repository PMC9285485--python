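"""Zero-phase frequency-domain conditioning preceding artifact detection.

The detector needs three aligned views of one recording:

* ``raw`` — unfiltered; a lost-contact flat segment is exactly constant
  only here, so flat-line detection runs on this view;
* ``notched`` — power-line notch only; the high-frequency power ratio
  (muscle surrogate) needs content above 50 Hz, which the 0.5–40 Hz
  band-pass would destroy, so it is computed on this view;
* ``band`` — notch followed by 0.5–40 Hz band-pass; amplitude-based
  features (MAFD, MAA) are computed here.

All filters are applied forward–backward (zero phase) so that event
onsets are not shifted, and never change the sample count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .model import DetectorConfig, Recording

__all__ = ["notch_filter", "bandpass_filter", "prepare_views", "Views"]


def notch_filter(recording: Recording, f0: float = 50.0, q: float = 30.0) -> Recording:
    """Remove a narrow band around ``f0`` (power-line interference).

    Second-order IIR notch with quality factor ``q``, applied with
    ``filtfilt``: ≥20 dB attenuation at ``f0``, passband essentially flat
    beyond a few Hz from the notch.
    """
    if not 0 < f0 < recording.fs / 2:
        raise ValueError(f"notch frequency {f0} Hz must lie in (0, fs/2)")
    b, a = signal.iirnotch(f0, q, fs=recording.fs)
    out = signal.filtfilt(b, a, recording.data, axis=-1)
    return Recording(out, recording.fs, list(recording.channel_names),
                     recording.start_s)


def bandpass_filter(
    recording: Recording, lo: float = 0.5, hi: float = 40.0, order: int = 4
) -> Recording:
    """Butterworth band-pass (default 0.5–40 Hz), zero phase.

    ``order`` is the overall filter order of a single pass; the
    forward–backward application doubles the effective roll-off.
    """
    if not 0 < lo < hi < recording.fs / 2:
        raise ValueError(
            f"band ({lo}, {hi}) Hz must satisfy 0 < lo < hi < fs/2 "
            f"= {recording.fs / 2}"
        )
    sos = signal.butter(order, [lo, hi], btype="bandpass",
                        fs=recording.fs, output="sos")
    out = signal.sosfiltfilt(sos, recording.data, axis=-1)
    return Recording(out, recording.fs, list(recording.channel_names),
                     recording.start_s)


@dataclass
class Views:
    """Three aligned views of one recording (see module docstring)."""

    raw: Recording
    notched: Recording
    band: Recording


def prepare_views(
    recording: Recording, config: DetectorConfig | None = None
) -> Views:
    """Build the raw / notch-only / notch+band-pass views used downstream."""
    config = config or DetectorConfig()
    notched = notch_filter(recording, config.notch_hz, config.notch_q)
    band = bandpass_filter(
        notched, *config.bandpass_hz, order=config.bandpass_order
    )
    return Views(raw=recording, notched=notched, band=band)
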