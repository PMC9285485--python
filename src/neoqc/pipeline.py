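"""End-to-end artifact removal: preprocess → detect → union → cut.

The pipeline is fully deterministic: its output depends only on the
input samples and the configuration.  Where a flat-line interval and a
large-amplitude interval overlap, the flat-line label wins (a constant
segment carries no cortical signal regardless of what surrounds it).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .flatline import detect_flatlines
from .large_amplitude import analyze_large_amplitude
from .model import (
    DetectorConfig,
    IntervalSet,
    Recording,
    apply_removal,
    intervals_to_mask,
    mask_to_intervals,
)
from .preprocess import prepare_views

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline", "load_config", "save_config"]


@dataclass
class PipelineResult:
    """Artifact intervals, surviving clean segments and a summary report."""

    artifacts: IntervalSet
    segments: list[Recording]
    kept: IntervalSet
    report: dict


def _labelled_union(
    flat: IntervalSet, large: IntervalSet, fs: float, n_samples: int
) -> IntervalSet:
    """Union of both detectors' intervals; flatline label wins on overlap."""
    flat_mask = intervals_to_mask(flat, fs, n_samples)
    large_mask = intervals_to_mask(large, fs, n_samples) & ~flat_mask
    return mask_to_intervals(flat_mask, fs, "flatline").union(
        mask_to_intervals(large_mask, fs, "large_amplitude")
    )


def run_pipeline(
    source: Recording | str | Path,
    config: DetectorConfig | None = None,
) -> PipelineResult:
    """Detect and remove flat-line and large-amplitude artifacts.

    Parameters
    ----------
    source
        A :class:`Recording` or a path to an EDF file.
    config
        Detector configuration; defaults to the published operating point.
    """
    config = config or DetectorConfig()
    if not isinstance(source, Recording):
        from .io import read_edf

        source = read_edf(source)
    if source.n_samples == 0:
        raise ValueError("empty recording")

    views = prepare_views(source, config)
    flat = IntervalSet()
    large = IntervalSet()
    crit_counts = {k: 0 for k in (1, 2, 3, 4)}
    if config.enable_flatline:
        flat = detect_flatlines(views.raw, config)
        logger.info("flat-line detector: %d interval(s)", len(flat))
    if config.enable_large_amplitude:
        la = analyze_large_amplitude(views.band, views.notched, config)
        large = la.intervals
        for k in crit_counts:
            crit_counts[k] = int(np.sum(la.selection.criterion == k))
        logger.info("large-amplitude detector: %d interval(s)", len(large))

    artifacts = _labelled_union(flat, large, source.fs, source.n_samples)
    segments, kept = apply_removal(source, artifacts)

    dur = source.duration_s
    flat_s = artifacts.with_label("flatline").total_duration_s
    large_s = artifacts.with_label("large_amplitude").total_duration_s
    report = {
        "duration_s": dur,
        "n_channels": source.n_channels,
        "fs": source.fs,
        "removed_total_pct": 100.0 * artifacts.total_duration_s / dur,
        "removed_flatline_pct": 100.0 * flat_s / dur,
        "removed_large_amplitude_pct": 100.0 * large_s / dur,
        "n_artifact_intervals": len(artifacts),
        "n_clean_segments": len(segments),
        "selected_windows_per_criterion": crit_counts,
        "config": config.to_dict(),
    }
    return PipelineResult(artifacts, segments, kept, report)


def load_config(path: str | Path) -> DetectorConfig:
    """Load a YAML or JSON configuration; unknown keys are rejected and
    missing keys fall back to the defaults."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping of configuration keys")
    if "bandpass_hz" in data:
        data["bandpass_hz"] = tuple(data["bandpass_hz"])
    return DetectorConfig.from_dict(data)


def save_config(config: DetectorConfig, path: str | Path) -> None:
    path = Path(path)
    d = config.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=1))
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))
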