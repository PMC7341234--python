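"""Synthetic top-view flock simulator with exact ground truth.

Generates image sequences with the statistical structure the activity-index
analysis assumes: bright bird-shaped ellipses on a darker, static, textured
litter background, plus additive sensor noise. Birds alternate between
moving bouts (correlated random walk with reflecting walls) and resting
bouts, and occasionally perform sub-second "transient" movements — in-place
mask jitter emulating turning, bobbling, preening and shaking — that return
the bird to its base position afterwards. Those transients are exactly the
motion that long sampling intervals fail to capture.

Birds are rendered as filled hard-edged ellipses (no anti-aliasing), so the
per-frame bird mask, the bird pixel count, and the per-pair changed-pixel
count all have exact integer ground truth.

The first ``calibration_frames`` frames are bird-free "empty background",
mirroring how the motion threshold is calibrated on an empty scene before
analysis begins.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import pipeline
from .activity import ThresholdConfig
from .imaging_io import FrameSequence
from .sampling import (
    DEFAULT_WINDOW,
    STUDY_INTERVALS,
    IntervalComparison,
    ratio_to_baseline,
)

__all__ = [
    "FlockSimConfig",
    "GroundTruth",
    "simulate_flock",
    "interval_sweep_experiment",
    "config_for_week",
    "AGE_ACTIVITY",
]


@dataclasses.dataclass(frozen=True)
class FlockSimConfig:
    """All parameters of the synthetic flock generator.

    Geometry defaults match the study ROI: a 200 x 200 px crop covering
    0.71 x 0.71 m (0.00355 m/px) filmed at 25 fps. Behavioural and
    photometric defaults are simulator choices, not field measurements.

    Parameters
    ----------
    duration
        Seconds of bird footage; frames are generated so pairs cover the
        half-open span (0, duration] at full frame rate (duration * fps + 1
        frames), preceded by ``calibration_frames`` bird-free frames.
    speed_mean
        Mean walking speed of a bird during a moving bout, m/s.
    resting_prob
        Long-run fraction of time a bird rests (no displacement).
    turn_rate_sd
        Spread of the per-bout constant turning rate, rad/s; moving birds
        follow smooth curved paths, with ``heading_sd`` (rad/frame) adding a
        small per-frame heading perturbation on top.
    transient_rate
        Sub-second in-place movement events per bird per minute.
    noise_sd
        Additive Gaussian sensor noise, intensity units; must stay well
        below the calibrated motion threshold (3 x noise_sd < tau).
    """

    arena_px: int = 200
    scale: float = 0.00355
    frame_rate: float = 25.0
    duration: float = 60.0
    n_birds: int = 5
    bird_axes_px: tuple[float, float] = (14.0, 9.0)
    bird_intensity: int = 200
    background_intensity: int = 65
    background_texture: int = 20
    speed_mean: float = 0.08
    speed_sd_frac: float = 0.3
    turn_rate_sd: float = 0.6
    heading_sd: float = 0.01
    resting_prob: float = 0.5
    rest_bout_mean: float = 4.0
    transient_rate: float = 4.0
    transient_duration: float = 0.3
    transient_jitter_px: float = 1.5
    noise_sd: float = 2.0
    calibration_frames: int = 20
    bit_depth: int = 8
    seed: int = 0

    @property
    def max_intensity(self) -> int:
        return 2**self.bit_depth - 1

    def validate(self) -> None:
        a, b = self.bird_axes_px
        if a <= 0 or b <= 0:
            raise ValueError("bird semi-axes must be positive")
        margin = self._margin()
        if self.n_birds > 0 and self.arena_px - 1 - 2 * margin <= 0:
            raise ValueError(
                f"infeasible packing: bird of semi-axes {self.bird_axes_px} px "
                f"cannot fit inside a {self.arena_px} px arena"
            )
        if self.n_birds * math.pi * a * b > 0.7 * self.arena_px**2:
            raise ValueError(
                f"infeasible packing: {self.n_birds} birds of area ~{math.pi * a * b:.0f} px^2 "
                f"exceed 70% of the {self.arena_px}x{self.arena_px} arena"
            )
        bg_peak = self.background_intensity + self.background_texture
        if self.bird_intensity <= bg_peak:
            raise ValueError("bird_intensity must exceed the brightest background pixel")
        # noise alone must not trigger the motion threshold (tau ~ 15% of
        # the empty-background maximum)
        approx_tau = 0.15 * bg_peak
        if 3 * self.noise_sd >= approx_tau:
            raise ValueError(
                f"noise_sd {self.noise_sd} too large: 3*sd must stay below the "
                f"~{approx_tau:.1f} intensity-unit motion threshold"
            )
        if not 0 <= self.resting_prob < 1:
            raise ValueError("resting_prob must be in [0, 1)")

    def _margin(self) -> float:
        return max(self.bird_axes_px) + 3 * self.transient_jitter_px + 1.0

    @property
    def n_body_frames(self) -> int:
        return int(round(self.duration * self.frame_rate)) + 1

    @property
    def speed_px(self) -> float:
        """Per-frame displacement of a moving bird at the mean speed, px."""
        return self.speed_mean / self.scale / self.frame_rate


@dataclasses.dataclass
class GroundTruth:
    """Exact per-frame truth emitted alongside the rendered frames.

    ``masks`` may be omitted (None) for long runs; the derived counts are
    always present. ``changed_pixels[i]`` counts pixels whose bird/background
    classification differs between consecutive frames i and i+1 (the
    noise-free motion-mask truth).
    """

    bird_pixels: np.ndarray
    changed_pixels: np.ndarray
    masks: Optional[np.ndarray] = None

    def to_frame(self) -> pd.DataFrame:
        changed = np.concatenate([[0], self.changed_pixels])
        return pd.DataFrame(
            {
                "frame": np.arange(len(self.bird_pixels)),
                "bird_pixels": self.bird_pixels,
                "changed_pixels_vs_prev": changed,
            }
        )


class _Bird:
    __slots__ = (
        "pos",
        "heading",
        "moving",
        "bout_left",
        "speed",
        "turn_rate",
        "transient_left",
        "jitter",
    )

    def __init__(self, pos, heading):
        self.pos = pos
        self.heading = heading
        self.moving = False
        self.bout_left = 0.0
        self.speed = 0.0
        self.turn_rate = 0.0
        self.transient_left = 0.0
        self.jitter = np.zeros(2)


def _ellipse_mask_into(mask, cx, cy, a, b, theta, arena):
    """Rasterise a filled rotated ellipse into ``mask`` (hard edges)."""
    c, s = math.cos(theta), math.sin(theta)
    rx = math.hypot(a * c, b * s)
    ry = math.hypot(a * s, b * c)
    x_lo = max(0, int(math.floor(cx - rx)))
    x_hi = min(arena - 1, int(math.ceil(cx + rx)))
    y_lo = max(0, int(math.floor(cy - ry)))
    y_hi = min(arena - 1, int(math.ceil(cy + ry)))
    if x_lo > x_hi or y_lo > y_hi:
        return
    xs = np.arange(x_lo, x_hi + 1) - cx
    ys = np.arange(y_lo, y_hi + 1) - cy
    dx = xs[None, :]
    dy = ys[:, None]
    u = (dx * c + dy * s) / a
    v = (-dx * s + dy * c) / b
    inside = u * u + v * v <= 1.0
    mask[y_lo : y_hi + 1, x_lo : x_hi + 1] |= inside


def _draw_bout(rng, cfg: FlockSimConfig, moving: bool) -> tuple[float, float, float]:
    """Sample a bout duration (s), speed (m/s) and turning rate (rad/s)."""
    p = cfg.resting_prob
    if moving:
        # mean moving-bout length chosen so the long-run resting fraction is p
        mean = cfg.rest_bout_mean * (1 - p) / p if p > 0 else cfg.rest_bout_mean
        duration = rng.exponential(mean)
        sd = cfg.speed_sd_frac
        speed = cfg.speed_mean * rng.lognormal(-0.5 * sd * sd, sd) if sd > 0 else cfg.speed_mean
        return duration, speed, rng.normal(0.0, cfg.turn_rate_sd)
    return rng.exponential(cfg.rest_bout_mean), 0.0, 0.0


def simulate_flock(
    cfg: FlockSimConfig, keep_masks: bool = True
) -> tuple[FrameSequence, GroundTruth]:
    """Render a flock sequence and its exact ground truth.

    Fully reproducible from ``cfg.seed``: identical configs yield
    bit-identical integer frames on any platform.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    arena = cfg.arena_px
    n_total = cfg.calibration_frames + cfg.n_body_frames
    dt = 1.0 / cfg.frame_rate
    a, b = cfg.bird_axes_px
    margin = cfg._margin()
    lo, hi = margin, arena - 1 - margin

    # static litter texture, fixed for the whole clip
    texture = cfg.background_intensity + rng.integers(
        -cfg.background_texture, cfg.background_texture + 1, size=(arena, arena)
    )
    texture = np.clip(texture, 0, cfg.max_intensity).astype(np.float32)

    birds = []
    for _ in range(cfg.n_birds):
        pos = rng.uniform(lo, hi, size=2) if hi > lo else np.full(2, (arena - 1) / 2)
        bird = _Bird(pos, rng.uniform(0, 2 * math.pi))
        bird.moving = rng.random() > cfg.resting_prob
        bird.bout_left, bird.speed, bird.turn_rate = _draw_bout(rng, cfg, bird.moving)
        birds.append(bird)

    p_transient = cfg.transient_rate / 60.0 * dt
    frames = np.empty((n_total, arena, arena), dtype=np.uint8 if cfg.bit_depth <= 8 else np.uint16)
    bird_pixels = np.zeros(n_total, dtype=np.int64)
    changed = np.zeros(max(n_total - 1, 0), dtype=np.int64)
    masks = np.zeros((n_total, arena, arena), dtype=bool) if keep_masks else None
    prev_mask = np.zeros((arena, arena), dtype=bool)

    for t in range(n_total):
        mask = np.zeros((arena, arena), dtype=bool)
        if t >= cfg.calibration_frames:  # empty background during calibration
            if t > cfg.calibration_frames:
                _step_birds(birds, rng, cfg, dt, lo, hi, p_transient)
            for bird in birds:
                cx, cy = bird.pos + bird.jitter
                _ellipse_mask_into(mask, cx, cy, a, b, bird.heading, arena)
        frame = np.where(mask, np.float32(cfg.bird_intensity), texture)
        if cfg.noise_sd > 0:
            noise = rng.standard_normal((arena, arena), dtype=np.float32)
            frame += np.float32(cfg.noise_sd) * noise
        np.rint(frame, out=frame)
        np.clip(frame, 0, cfg.max_intensity, out=frame)
        frames[t] = frame
        bird_pixels[t] = int(mask.sum())
        if t > 0:
            changed[t - 1] = int(np.logical_xor(mask, prev_mask).sum())
        if masks is not None:
            masks[t] = mask
        prev_mask = mask

    seq = FrameSequence(
        frames=frames,
        frame_rate=cfg.frame_rate,
        source_id=f"sim-seed{cfg.seed}",
    )
    return seq, GroundTruth(bird_pixels=bird_pixels, changed_pixels=changed, masks=masks)


def _step_birds(birds, rng, cfg, dt, lo, hi, p_transient) -> None:
    for bird in birds:
        bird.bout_left -= dt
        if bird.bout_left <= 0:
            bird.moving = not bird.moving
            bird.bout_left, bird.speed, bird.turn_rate = _draw_bout(rng, cfg, bird.moving)
        if bird.moving and bird.speed > 0:
            bird.heading += bird.turn_rate * dt + rng.normal(0.0, cfg.heading_sd)
            step = bird.speed / cfg.scale * dt
            bird.pos[0] += step * math.cos(bird.heading)
            bird.pos[1] += step * math.sin(bird.heading)
            # reflecting walls
            for k in range(2):
                if bird.pos[k] < lo:
                    bird.pos[k] = 2 * lo - bird.pos[k]
                    bird.heading = (math.pi - bird.heading) if k == 0 else -bird.heading
                elif bird.pos[k] > hi:
                    bird.pos[k] = 2 * hi - bird.pos[k]
                    bird.heading = (math.pi - bird.heading) if k == 0 else -bird.heading
        # transient in-place movement: jitter while active, return to base after
        if bird.transient_left > 0:
            bird.transient_left -= dt
            if bird.transient_left <= 0:
                bird.jitter[:] = 0.0
            else:
                bird.jitter = rng.normal(0.0, cfg.transient_jitter_px, size=2)
        elif rng.random() < p_transient:
            bird.transient_left = cfg.transient_duration
            bird.jitter = rng.normal(0.0, cfg.transient_jitter_px, size=2)


#: Relative activity level per bird-age week; week 1 chicks dart around,
#: older heavier birds slow down and rest more. A single scalar scaled onto
#: (speed, resting fraction, body size); illustrative, not a field calibration.
AGE_ACTIVITY = {1: 1.6, 2: 1.3, 3: 1.0, 4: 0.75, 5: 0.6, 6: 0.5, 7: 0.45}


def config_for_week(cfg: FlockSimConfig, week: int) -> FlockSimConfig:
    """Preset emulating the age trend: slower, restier, larger birds with age."""
    if week not in AGE_ACTIVITY:
        raise ValueError(f"week must be one of {sorted(AGE_ACTIVITY)}")
    act = AGE_ACTIVITY[week]
    size = 0.6 + 0.1 * week  # body grows roughly linearly over the cycle
    a, b = cfg.bird_axes_px
    return dataclasses.replace(
        cfg,
        speed_mean=cfg.speed_mean * act,
        resting_prob=min(0.9, cfg.resting_prob * (2 - act) if act < 1 else cfg.resting_prob / act),
        bird_axes_px=(a * size, b * size),
    )


def interval_sweep_experiment(
    cfg: FlockSimConfig,
    intervals: Sequence[float] = STUDY_INTERVALS,
    replicates: int = 20,
    window: float = DEFAULT_WINDOW,
    threshold_cfg: ThresholdConfig = ThresholdConfig(),
) -> list[IntervalComparison]:
    """Run the full pipeline over seeded replicates and summarise per interval.

    Each replicate simulates an independent flock (seeds derived from
    ``cfg.seed``), analyses it at every interval, and contributes its
    complete cumulative windows; means, SEMs and ratios to the shortest
    interval are pooled across all replicate-windows.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    baseline = min(intervals)
    seeds = np.random.SeedSequence(cfg.seed).generate_state(replicates) % (2**31)
    pooled: dict[float, list] = {float(i): [] for i in intervals}
    for r, seed in enumerate(seeds):
        rep_cfg = dataclasses.replace(cfg, seed=int(seed))
        try:
            seq, _ = simulate_flock(rep_cfg, keep_masks=False)
            result = pipeline.analyze_sequence(
                seq,
                intervals=intervals,
                threshold_cfg=threshold_cfg,
                window=window,
                baseline=baseline,
            )
        except Exception as exc:  # pragma: no cover - context for debugging
            raise RuntimeError(f"replicate {r} (seed {seed}) failed") from exc
        for interval, wins in result.windows_by_interval.items():
            pooled[interval].extend(wins)
    return ratio_to_baseline(pooled, baseline=baseline)
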