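"""Frame-sequence input/output.

Loads ordered grayscale image sequences from directories of PNG/TIFF files,
converts color input to luma, crops rectangular regions of interest, and
writes frames and binary masks back to disk. Timestamps are always derived
from frame order and the declared frame rate, never from file metadata, so a
re-run on the same directory is reproducible.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Callable, Optional, Sequence

import imageio.v3 as iio
import numpy as np

__all__ = [
    "ROI",
    "FrameSequence",
    "to_grayscale",
    "load_sequence",
    "write_frames",
    "write_mask",
    "crop",
    "pixel_scale",
]

_IMAGE_SUFFIXES = {".png", ".tif", ".tiff"}

# ITU-R BT.601 luma weights for R, G, B.
_BT601 = np.array([0.299, 0.587, 0.114])


@dataclasses.dataclass(frozen=True)
class ROI:
    """Rectangular region of interest, 0-based, half-open [x0, x0+width).

    The study geometry is a 200 x 200 px square covering 0.71 x 0.71 m of
    litter floor, placed at a feeder, drinker, or open area.
    """

    x0: int
    y0: int
    width: int
    height: int
    label: str = "custom"

    def __post_init__(self) -> None:
        if self.x0 < 0 or self.y0 < 0:
            raise ValueError(f"ROI origin must be non-negative, got ({self.x0}, {self.y0})")
        if self.width <= 0 or self.height <= 0:
            raise ValueError(f"ROI extent must be positive, got {self.width}x{self.height}")

    def validate_within(self, height: int, width: int) -> None:
        """Raise if the ROI is not fully inside a ``height`` x ``width`` frame."""
        if self.x0 + self.width > width or self.y0 + self.height > height:
            raise ValueError(
                f"ROI [{self.x0}:{self.x0 + self.width}) x [{self.y0}:{self.y0 + self.height}) "
                f"exceeds frame bounds {width}x{height}"
            )

    @property
    def slices(self) -> tuple[slice, slice]:
        """(row, column) slices selecting the ROI from a frame array."""
        return (
            slice(self.y0, self.y0 + self.height),
            slice(self.x0, self.x0 + self.width),
        )


@dataclasses.dataclass
class FrameSequence:
    """An ordered stack of same-sized grayscale frames at a fixed frame rate.

    Parameters
    ----------
    frames
        Array of shape ``(n_frames, height, width)`` with unsigned-integer
        intensities.
    frame_rate
        Frames per second (the study camera ran at 25 fps).
    timestamps
        Seconds from sequence start, strictly increasing; defaults to
        ``index / frame_rate``.
    source_id
        Free-text clip label (location, age, time of day, ...).
    """

    frames: np.ndarray
    frame_rate: float
    timestamps: Optional[np.ndarray] = None
    source_id: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be (n, height, width), got shape {self.frames.shape}")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.timestamps is None:
            self.timestamps = np.arange(len(self.frames)) / self.frame_rate
        else:
            self.timestamps = np.asarray(self.timestamps, dtype=float)
            if self.timestamps.shape != (len(self.frames),):
                raise ValueError("timestamps must have one entry per frame")
            if len(self.timestamps) > 1 and not np.all(np.diff(self.timestamps) > 0):
                raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def duration(self) -> float:
        """Time span covered, last timestamp minus first (0 for <2 frames)."""
        if len(self) < 2:
            return 0.0
        return float(self.timestamps[-1] - self.timestamps[0])

    def slice_frames(self, start: int, stop: Optional[int] = None) -> "FrameSequence":
        """Sub-sequence by frame index, keeping original timestamps."""
        sl = slice(start, stop)
        return FrameSequence(
            frames=self.frames[sl],
            frame_rate=self.frame_rate,
            timestamps=self.timestamps[sl],
            source_id=self.source_id,
        )


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Reduce an image to single-channel luma (BT.601), round half up.

    Already-gray input is returned unchanged (identity), so repeated
    conversion is safe.
    """
    image = np.asarray(image)
    if image.ndim == 2:
        return image
    if image.ndim == 3 and image.shape[-1] in (3, 4):
        luma = image[..., :3].astype(np.float64) @ _BT601
        return np.floor(luma + 0.5).astype(image.dtype)
    raise ValueError(f"cannot interpret image of shape {image.shape} as gray or RGB(A)")


def load_sequence(
    path: str | Path,
    frame_rate: float,
    source_id: Optional[str] = None,
    remap: Optional[Callable[[np.ndarray], np.ndarray]] = None,
) -> FrameSequence:
    """Load an ordered frame sequence from a directory of images.

    Files are taken in lexicographic order, which is assumed to be temporal
    order; timestamps are ``index / frame_rate``. Color frames are reduced to
    luma. A multi-page TIFF (or any multi-frame file imageio can decode) is
    also accepted.

    Parameters
    ----------
    remap
        Optional per-frame remapping callable applied before grayscale
        conversion — the hook for an externally supplied lens-distortion
        correction. The pipeline ships no lens model of its own.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES)
        if not files:
            raise ValueError(f"no frames: {path} contains no PNG/TIFF files")
        raw = [iio.imread(f) for f in files]
    elif path.is_file():
        stack = iio.imread(path)
        if stack.ndim == 2 or (stack.ndim == 3 and stack.shape[-1] in (3, 4)):
            raw = [stack]
        else:
            raw = list(stack)
    else:
        raise FileNotFoundError(path)

    if remap is not None:
        raw = [remap(frame) for frame in raw]
    gray = [to_grayscale(frame) for frame in raw]
    shapes = {g.shape for g in gray}
    if len(shapes) > 1:
        raise ValueError(f"inconsistent geometry: frame shapes {sorted(shapes)}")
    return FrameSequence(
        frames=np.stack(gray),
        frame_rate=frame_rate,
        source_id=source_id if source_id is not None else path.name,
    )


def write_frames(seq: FrameSequence, directory: str | Path, prefix: str = "frame") -> list[Path]:
    """Write each frame as a zero-padded, lexicographically ordered PNG."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    digits = max(6, len(str(len(seq))))
    paths = []
    for i, frame in enumerate(seq.frames):
        p = directory / f"{prefix}_{i:0{digits}d}.png"
        iio.imwrite(p, np.ascontiguousarray(frame))
        paths.append(p)
    return paths


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a binary mask as an 8-bit PNG with values 0/255."""
    mask = np.asarray(mask)
    iio.imwrite(Path(path), (mask > 0).astype(np.uint8) * 255)


def crop(seq: FrameSequence, roi: ROI) -> FrameSequence:
    """Crop every frame to ``roi``; timestamps are unchanged."""
    h, w = seq.frame_shape
    roi.validate_within(h, w)
    rows, cols = roi.slices
    return FrameSequence(
        frames=seq.frames[:, rows, cols],
        frame_rate=seq.frame_rate,
        timestamps=seq.timestamps.copy(),
        source_id=seq.source_id,
    )


def pixel_scale(roi: ROI, physical_side: float) -> float:
    """Meters per pixel of a square ROI covering ``physical_side`` meters.

    The study ROI maps 200 px onto 0.71 m, i.e. 0.00355 m/px.
    """
    if physical_side <= 0:
        raise ValueError("physical_side must be positive")
    if roi.width != roi.height:
        raise ValueError(
            f"single physical side given for non-square ROI {roi.width}x{roi.height}"
        )
    return physical_side / roi.width
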