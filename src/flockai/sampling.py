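"""Temporal subsampling and cumulative-window aggregation.

The study compared activity indices computed from frames taken every 0.04 s
(the camera's full 25 fps stream) against subsampled streams at 0.2, 1, 10,
60 and 300 s. Per-pair AI values are summed into 300-s cumulative windows —
the unit of statistical analysis — and each interval's cumulative AI is
expressed as a percentage of the full-frame baseline within the same window.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .activity import ActivitySample
from .imaging_io import FrameSequence

__all__ = [
    "STUDY_INTERVALS",
    "IntervalSpec",
    "CumulativeWindow",
    "IntervalComparison",
    "subsample",
    "cumulative_windows",
    "ratio_to_baseline",
    "summarize_groups",
    "windows_to_frame",
    "comparisons_to_frame",
]

log = logging.getLogger(__name__)

#: Sampling time intervals investigated by the study, seconds.
STUDY_INTERVALS = (0.04, 0.2, 1.0, 10.0, 60.0, 300.0)

#: Length of the cumulative-AI analysis window, seconds.
DEFAULT_WINDOW = 300.0


@dataclasses.dataclass(frozen=True)
class IntervalSpec:
    """A sampling time interval; must be an integer multiple of 1/fps."""

    interval: float

    def __post_init__(self) -> None:
        if self.interval <= 0:
            raise ValueError("interval must be positive")

    def stride(self, frame_rate: float) -> int:
        """Frame stride realising this interval at ``frame_rate``."""
        exact = self.interval * frame_rate
        stride = round(exact)
        if stride < 1 or abs(exact - stride) > 1e-6:
            raise ValueError(
                f"interval {self.interval} s at {frame_rate} fps gives "
                f"non-integer frame stride {exact}"
            )
        return stride


@dataclasses.dataclass
class CumulativeWindow:
    """Sum of activity indices over one fixed-length time window.

    Samples are assigned by current-frame timestamp into half-open windows
    ``(start, end]``: the pair ending exactly at the window boundary belongs
    to the window it closes, so a 300-s window holds exactly
    ``window / interval`` pairs at every admissible interval (7500 at 0.04 s,
    one single pair at 300 s). Missing samples (no bird pixels) are skipped
    and counted.
    """

    window_start: float
    window_end: float
    cumulative_ai: float
    n_samples: int
    n_missing: int
    interval: float
    roi_label: str = ""
    source_id: str = ""
    meta: dict = dataclasses.field(default_factory=dict)


@dataclasses.dataclass
class IntervalComparison:
    """Per-interval cumulative-AI summary with ratio to the baseline interval.

    ``ratio_pct`` is the primary statistic: the mean over windows of
    100 x (window AI at this interval / window AI at baseline).
    ``ratio_of_means_pct`` is the secondary pooled statistic,
    100 x (mean AI at this interval / mean AI at baseline).
    """

    interval: float
    n_windows: int
    mean_cumulative_ai: float
    sem: float
    ratio_pct: float
    ratio_sem_pct: float
    ratio_of_means_pct: float


def subsample(seq: FrameSequence, interval: float | IntervalSpec) -> FrameSequence:
    """Keep frames at indices 0, stride, 2*stride, ...; timestamps preserved.

    At 25 fps an interval of 0.2 s keeps every 5th frame, dropping 80% of
    the stream.
    """
    spec = interval if isinstance(interval, IntervalSpec) else IntervalSpec(interval)
    stride = spec.stride(seq.frame_rate)
    # effective rate drops with the stride so intervals remain wall-clock
    # and subsampling composes: subsample(subsample(s, a), b) == subsample(s, b)
    return FrameSequence(
        frames=seq.frames[::stride],
        frame_rate=seq.frame_rate / stride,
        timestamps=seq.timestamps[::stride],
        source_id=seq.source_id,
    )


def cumulative_windows(
    samples: Sequence[ActivitySample],
    window: float = DEFAULT_WINDOW,
    clip_duration: Optional[float] = None,
    t0: float = 0.0,
    meta: Optional[dict] = None,
) -> list[CumulativeWindow]:
    """Partition a sorted sample series into complete cumulative-AI windows.

    Only the ``floor(clip_duration / window)`` complete windows are emitted;
    a trailing partial window is dropped (a 56-min clip yields 11 complete
    300-s windows). ``clip_duration`` defaults to the span from ``t0`` to the
    last sample time.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    samples = list(samples)
    if any(samples[i].t > samples[i + 1].t for i in range(len(samples) - 1)):
        raise ValueError("samples must be sorted by time")
    if clip_duration is None:
        clip_duration = (samples[-1].t - t0) if samples else 0.0
    n_windows = int(math.floor(clip_duration / window + 1e-9))

    sums = np.zeros(n_windows)
    counts = np.zeros(n_windows, dtype=int)
    missing = np.zeros(n_windows, dtype=int)
    for s in samples:
        # window k covers (t0 + k*window, t0 + (k+1)*window]
        k = math.ceil((s.t - t0) / window - 1e-9) - 1
        if k < 0 or k >= n_windows:
            continue
        if s.missing:
            missing[k] += 1
        else:
            sums[k] += s.ai
            counts[k] += 1
    if missing.sum():
        log.info("skipped %d missing samples across %d windows", int(missing.sum()), n_windows)

    interval = samples[0].interval if samples else float("nan")
    roi_label = samples[0].roi_label if samples else ""
    source_id = samples[0].source_id if samples else ""
    return [
        CumulativeWindow(
            window_start=t0 + k * window,
            window_end=t0 + (k + 1) * window,
            cumulative_ai=float(sums[k]),
            n_samples=int(counts[k]),
            n_missing=int(missing[k]),
            interval=interval,
            roi_label=roi_label,
            source_id=source_id,
            meta=dict(meta) if meta else {},
        )
        for k in range(n_windows)
    ]


def _match_interval(keys: Iterable[float], target: float) -> Optional[float]:
    for k in keys:
        if math.isclose(k, target, rel_tol=1e-9, abs_tol=1e-12):
            return k
    return None


def ratio_to_baseline(
    windows_by_interval: Mapping[float, Sequence[CumulativeWindow]],
    baseline: float = 0.04,
) -> list[IntervalComparison]:
    """Summarise cumulative AI per interval relative to the baseline interval.

    All interval series must come from the same clip with identical window
    boundaries (checked). Ratios are computed per window then averaged —
    the primary statistic — with the pooled ratio of means reported
    alongside. Windows whose baseline cumulative AI is zero are excluded
    from ratios and logged.
    """
    base_key = _match_interval(windows_by_interval.keys(), baseline)
    if base_key is None:
        raise ValueError(
            f"baseline interval {baseline} s absent from intervals "
            f"{sorted(windows_by_interval.keys())}"
        )
    base = list(windows_by_interval[base_key])
    base_ai = np.array([w.cumulative_ai for w in base])
    usable = base_ai > 0
    if not usable.all():
        log.info("excluding %d windows with zero baseline cumulative AI", int((~usable).sum()))

    out = []
    for interval in sorted(windows_by_interval.keys()):
        wins = list(windows_by_interval[interval])
        if len(wins) != len(base) or any(
            not math.isclose(w.window_start, b.window_start, abs_tol=1e-6)
            for w, b in zip(wins, base)
        ):
            raise ValueError(
                f"interval {interval} s windows do not share the baseline's boundaries"
            )
        ai = np.array([w.cumulative_ai for w in wins])
        ratios = 100.0 * ai[usable] / base_ai[usable]
        out.append(
            IntervalComparison(
                interval=interval,
                n_windows=len(wins),
                mean_cumulative_ai=float(ai.mean()) if len(ai) else float("nan"),
                sem=_sem(ai),
                ratio_pct=float(ratios.mean()) if len(ratios) else float("nan"),
                ratio_sem_pct=_sem(ratios),
                ratio_of_means_pct=(
                    float(100.0 * ai.mean() / base_ai.mean()) if base_ai.mean() > 0 else float("nan")
                ),
            )
        )
    return out


def _sem(values: np.ndarray) -> float:
    """Plain standard error of the mean; undefined (NaN) for n < 2."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        return float("nan")
    return float(values.std(ddof=1) / math.sqrt(len(values)))


def windows_to_frame(windows: Sequence[CumulativeWindow]) -> pd.DataFrame:
    """Tabulate windows, expanding any grouping metadata into columns."""
    rows = []
    for w in windows:
        row = {
            "source_id": w.source_id,
            "roi_label": w.roi_label,
            "interval": w.interval,
            "window_start": w.window_start,
            "window_end": w.window_end,
            "cumulative_ai": w.cumulative_ai,
            "n_samples": w.n_samples,
            "n_missing": w.n_missing,
        }
        row.update(w.meta)
        rows.append(row)
    return pd.DataFrame(rows)


def comparisons_to_frame(comparisons: Sequence[IntervalComparison]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(c) for c in comparisons])


def summarize_groups(
    windows: Sequence[CumulativeWindow] | pd.DataFrame,
    keys: Sequence[str],
) -> pd.DataFrame:
    """Group cumulative-AI windows and report n, mean and SEM per group.

    ``keys`` may name any window column or metadata field (e.g. age_week,
    roi_label, time_of_day, interval). SEM is sd/sqrt(n), reported as
    missing for singleton groups.
    """
    keys = list(keys)
    if not keys:
        raise ValueError("at least one grouping key is required")
    df = windows if isinstance(windows, pd.DataFrame) else windows_to_frame(windows)
    missing_cols = [k for k in keys if k not in df.columns]
    if missing_cols:
        raise KeyError(f"grouping keys not present in windows: {missing_cols}")
    grouped = df.groupby(keys, sort=True)["cumulative_ai"]
    out = grouped.agg(n="count", mean_cumulative_ai="mean", sem=lambda v: _sem(v.to_numpy()))
    return out.reset_index()
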