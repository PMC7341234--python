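"""End-to-end orchestration: calibrate, subsample, difference, aggregate.

Shared by the command-line interface and the simulation experiments. A run
calibrates the motion threshold on the clip's leading empty-background
frames, builds the background-reference segmentation model from the same
frames, drops them, then for each requested sampling interval computes the
per-pair activity-index series and its cumulative windows, finishing with
the ratio-to-baseline comparison table.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Optional, Sequence

from .activity import (
    ActivitySample,
    SegmentationModel,
    ThresholdConfig,
    ai_series,
    build_segmentation_model,
    calibrate_threshold,
)
from .imaging_io import FrameSequence
from .sampling import (
    DEFAULT_WINDOW,
    STUDY_INTERVALS,
    CumulativeWindow,
    IntervalComparison,
    cumulative_windows,
    ratio_to_baseline,
    subsample,
)

__all__ = ["AnalysisResult", "analyze_sequence"]


@dataclasses.dataclass
class AnalysisResult:
    """Everything one clip analysis produced."""

    tau: float
    model: SegmentationModel
    samples_by_interval: dict[float, list[ActivitySample]]
    windows_by_interval: dict[float, list[CumulativeWindow]]
    comparisons: list[IntervalComparison]
    n_frames: int
    n_calibration_frames: int
    clip_duration: float


def analyze_sequence(
    seq: FrameSequence,
    intervals: Sequence[float] = STUDY_INTERVALS,
    threshold_cfg: ThresholdConfig = ThresholdConfig(),
    window: float = DEFAULT_WINDOW,
    baseline: Optional[float] = None,
    min_blob_area: int = 4,
    roi_label: str = "",
    meta: Optional[Mapping] = None,
    drop_calibration: bool = True,
) -> AnalysisResult:
    """Run the full activity-index analysis of one (cropped) clip.

    The first ``threshold_cfg.calibration_frames`` frames are treated as the
    empty-background calibration run: they set the motion threshold tau and
    the segmentation background, and by default are excluded from the
    analysed footage. ``baseline`` defaults to the shortest interval.
    """
    if baseline is None:
        baseline = min(intervals)
    if not any(abs(baseline - i) < 1e-12 for i in intervals):
        raise ValueError(f"baseline interval {baseline} s not in intervals {list(intervals)}")

    tau = calibrate_threshold(seq, threshold_cfg)
    model = build_segmentation_model(
        seq, tau, calibration_frames=threshold_cfg.calibration_frames, min_blob_area=min_blob_area
    )
    body = seq.slice_frames(threshold_cfg.calibration_frames) if drop_calibration else seq
    if len(body) < 2:
        raise ValueError("no analysable frames remain after the calibration run")
    t0 = float(body.timestamps[0])
    clip_duration = float(body.timestamps[-1]) - t0

    samples_by_interval: dict[float, list[ActivitySample]] = {}
    windows_by_interval: dict[float, list[CumulativeWindow]] = {}
    for interval in intervals:
        key = float(interval)
        sub = subsample(body, interval)
        samples = ai_series(sub, model, tau, mode=threshold_cfg.mode, roi_label=roi_label)
        samples_by_interval[key] = samples
        windows_by_interval[key] = cumulative_windows(
            samples, window=window, clip_duration=clip_duration, t0=t0, meta=dict(meta or {})
        )

    comparisons = ratio_to_baseline(windows_by_interval, baseline=baseline)
    return AnalysisResult(
        tau=tau,
        model=model,
        samples_by_interval=samples_by_interval,
        windows_by_interval=windows_by_interval,
        comparisons=comparisons,
        n_frames=len(seq),
        n_calibration_frames=threshold_cfg.calibration_frames,
        clip_duration=clip_duration,
    )
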