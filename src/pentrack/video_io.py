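"""Frame-sequence I/O, light-gated capture logic, and frame-rate downsampling.

A recording is a directory of grayscale PNG/PGM images named
``frame_%06d.png`` plus a ``manifest.csv`` with columns ``frame_index`` and
``timestamp_s``.  Frames are yielded lazily in manifest order so long runs
fit in bounded memory.  All pixel data is single-channel uint8; color input
is converted to luma with Rec. 601 weights on read.

Capture in the facility being modelled is light-gated: the pens are lit on a
12 h cycle and are pitch black otherwise, so recording starts when light is
detected and stops when the lights go off.  :class:`LightGate` reproduces
that behaviour with hysteresis so a slowly dimming scene does not flicker
the gate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "Frame",
    "StreamInfo",
    "VideoFormatError",
    "read_sequence",
    "write_sequence",
    "lights_on",
    "LightGate",
    "downsample",
]

#: Rec. 601 luma weights used to collapse RGB input to grayscale.
_LUMA = np.array([0.299, 0.587, 0.114])

MANIFEST_NAME = "manifest.csv"
FRAME_PATTERN = "frame_{:06d}.png"


class VideoFormatError(RuntimeError):
    """Raised when a frame directory is malformed or a frame is unreadable."""


@dataclass(frozen=True)
class Frame:
    """One grayscale image with its stream position and wall-clock time."""

    pixels: np.ndarray  # 2-D uint8
    frame_index: int
    timestamp_s: float

    def __post_init__(self) -> None:
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("Frame pixels must be a non-empty 2-D array")

    @property
    def mean_intensity(self) -> float:
        return float(self.pixels.mean())

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class StreamInfo:
    fps: float
    frame_count: int
    width: int
    height: int


def _to_gray(arr: np.ndarray) -> np.ndarray:
    if arr.ndim == 3:
        arr = arr[..., :3] @ _LUMA
    return np.clip(np.rint(arr), 0, 255).astype(np.uint8)


def read_sequence(path: str | Path) -> tuple[StreamInfo, Iterator[Frame]]:
    """Open an image-sequence directory.

    Returns stream metadata plus a lazy iterator over frames in manifest
    order (which wins over filename order).  fps is inferred from the median
    timestamp spacing; a single-frame stream reports 1 fps.
    """
    path = Path(path)
    manifest_path = path / MANIFEST_NAME
    if not manifest_path.exists():
        raise VideoFormatError(f"missing {MANIFEST_NAME} in {path}")
    manifest = pd.read_csv(manifest_path)
    for col in ("frame_index", "timestamp_s"):
        if col not in manifest.columns:
            raise VideoFormatError(f"manifest lacks required column {col!r}")
    if len(manifest) == 0:
        raise VideoFormatError(f"empty manifest in {path}")
    ts = manifest["timestamp_s"].to_numpy(dtype=float)
    if len(ts) > 1:
        dt = float(np.median(np.diff(ts)))
        if dt <= 0:
            raise VideoFormatError("manifest timestamps must be strictly increasing")
        fps = 1.0 / dt
    else:
        fps = 1.0

    first = _read_frame_file(path, int(manifest["frame_index"].iloc[0]))
    info = StreamInfo(
        fps=fps,
        frame_count=len(manifest),
        width=first.shape[1],
        height=first.shape[0],
    )

    def _iter() -> Iterator[Frame]:
        prev_ts = -math.inf
        for row in manifest.itertuples(index=False):
            idx = int(row.frame_index)
            t = float(row.timestamp_s)
            if t <= prev_ts:
                raise VideoFormatError(
                    f"timestamps not strictly increasing at frame {idx}"
                )
            prev_ts = t
            yield Frame(_read_frame_file(path, idx), idx, t)

    return info, _iter()


def _read_frame_file(directory: Path, index: int) -> np.ndarray:
    fname = directory / FRAME_PATTERN.format(index)
    if not fname.exists():
        raise VideoFormatError(f"frame file missing for index {index}: {fname}")
    try:
        arr = iio.imread(fname)
    except Exception as exc:  # noqa: BLE001 - surface the index, keep the cause
        raise VideoFormatError(f"unreadable frame at index {index}: {fname}") from exc
    return _to_gray(np.asarray(arr))


def write_sequence(frames: Iterable[Frame], out_dir: str | Path) -> StreamInfo:
    """Write frames plus manifest.csv; returns the resulting StreamInfo."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    width = height = 0
    for frame in frames:
        iio.imwrite(out_dir / FRAME_PATTERN.format(frame.frame_index), frame.pixels)
        rows.append((frame.frame_index, frame.timestamp_s))
        height, width = frame.shape
    if not rows:
        raise ValueError("no frames to write")
    manifest = pd.DataFrame(rows, columns=["frame_index", "timestamp_s"])
    manifest.to_csv(out_dir / MANIFEST_NAME, index=False)
    ts = manifest["timestamp_s"].to_numpy(dtype=float)
    fps = 1.0 / float(np.median(np.diff(ts))) if len(ts) > 1 else 1.0
    return StreamInfo(fps=fps, frame_count=len(rows), width=width, height=height)


def lights_on(frame: Frame, threshold: float = 40.0) -> bool:
    """Stateless light check: mean intensity strictly above ``threshold``."""
    return frame.mean_intensity > threshold


class LightGate:
    """Stateful light detector with hysteresis.

    Turns on when the mean intensity exceeds ``threshold`` and stays on
    until it drops below ``threshold - hysteresis``, so dusk-like ramps do
    not toggle recording repeatedly.
    """

    def __init__(self, threshold: float = 40.0, hysteresis: float = 10.0) -> None:
        if not threshold > hysteresis >= 0:
            raise ValueError("require threshold > hysteresis >= 0")
        self.threshold = threshold
        self.hysteresis = hysteresis
        self._on = False

    @property
    def is_on(self) -> bool:
        return self._on

    def update(self, frame: Frame) -> bool:
        mean = frame.mean_intensity
        if self._on:
            if mean < self.threshold - self.hysteresis:
                self._on = False
        elif mean > self.threshold:
            self._on = True
        return self._on


def downsample(
    frames: Iterable[Frame], in_fps: int, out_fps: int
) -> Iterator[Frame]:
    """Keep the first frame of every ``in_fps // out_fps`` block.

    Mirrors dropping frames from a live low-rate capture: surviving frames
    keep their original index and timestamp.  ``in_fps`` must be divisible
    by ``out_fps``; for n input frames, ceil(n * out_fps / in_fps) survive.
    """
    if in_fps <= 0 or out_fps <= 0:
        raise ValueError("frame rates must be positive")
    if in_fps % out_fps != 0:
        raise ValueError(f"in_fps {in_fps} not divisible by out_fps {out_fps}")
    step = in_fps // out_fps
    for pos, frame in enumerate(frames):
        if pos % step == 0:
            yield frame
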