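"""The posture-then-movement cascade producing coded activity states.

Two stages, run per lit frame: a posture detector decides lying vs
standing; only for a standing pig is sparse optical flow consulted to
decide whether it is actually walking.  States are coded numerically —
1 lying, 2 standing, 3 walking — and that scale is what aggregation and
validation operate on.

Movement is expressed as accumulated distance per second: per-frame mean
feature displacements are summed over a one-second window aligned to
timestamps and divided by the window length.  At 25 fps that sums 25 small
inter-frame displacements; at 1 fps it is the single inter-frame
displacement itself, so the same walk threshold (in px/s) applies at both
rates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .detection import BoundingBox, Detector, Label, keeper_present, select_pig
from .flow import FlowParams, build_pyramid, lucas_kanade, mean_displacement, shi_tomasi_features
from .video_io import Frame

__all__ = [
    "ActivityRecord",
    "ThresholdConfig",
    "accumulate_displacement",
    "classify",
    "run_pipeline",
    "records_to_csv",
    "records_from_csv",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ActivityRecord:
    """Per-frame coded activity; ``state is None`` means no pig was found."""

    timestamp_s: float
    frame_index: int
    state: int | None  # 1 lying / 2 standing / 3 walking / None unknown
    keeper_present: bool
    displacement_px_per_s: float | None
    pig_box: BoundingBox | None
    low_confidence: bool = False

    @property
    def is_unknown(self) -> bool:
        return self.state is None


@dataclass(frozen=True)
class ThresholdConfig:
    """Movement thresholding, frame-rate aware by construction.

    walk_threshold is in px/s of accumulated distance; the default sits
    between the generator's standing jitter (<1 px/s) and walking speed
    (~30 px/s) with an order of magnitude of slack on either side.
    """

    walk_threshold_px_per_s: float = 5.0
    accumulation_window_s: float = 1.0

    def __post_init__(self) -> None:
        if self.walk_threshold_px_per_s <= 0 or self.accumulation_window_s <= 0:
            raise ValueError("threshold and window must be positive")


def accumulate_displacement(
    per_frame_displacements: Sequence[float], fps: float, window_s: float = 1.0
) -> float | None:
    """Accumulated distance per second over one window.

    Sum of per-frame mean displacements divided by the window length;
    ``None`` for an empty window (unknown movement propagates, it is not
    zero).  ``fps`` is accepted for interface symmetry — the px/s scale
    already normalizes across frame rates.
    """
    del fps
    if len(per_frame_displacements) == 0:
        return None
    return float(np.sum(per_frame_displacements)) / window_s


def classify(
    posture: Label,
    displacement_px_per_s: float | None,
    thresholds: ThresholdConfig | None = None,
) -> tuple[int, bool]:
    """Map (posture, movement) to a coded state.

    Returns (state, low_confidence).  Lying is state 1 regardless of flow —
    the cascade never computes flow for a lying pig.  A standing pig with
    no movement estimate falls back to state 2 with the low-confidence flag
    set.
    """
    thresholds = thresholds or ThresholdConfig()
    if posture is Label.PIG_LYING:
        return 1, False
    if posture is not Label.PIG_STANDING:
        raise ValueError(f"not a posture label: {posture}")
    if displacement_px_per_s is None:
        return 2, True
    if displacement_px_per_s > thresholds.walk_threshold_px_per_s:
        return 3, False
    return 2, False


# -- pipeline ----------------------------------------------------------------


@dataclass
class _PendingFrame:
    frame_index: int
    timestamp_s: float
    window_id: int
    posture: Label | None  # None -> no pig selected
    keeper: bool
    pig_box: BoundingBox | None
    pair_displacement: float | None = None  # mean px moved into the NEXT lit frame


def run_pipeline(
    frames: Iterable[Frame],
    detector: Detector,
    *,
    fps: float,
    flow_params: FlowParams | None = None,
    thresholds: ThresholdConfig | None = None,
    confidence_threshold: float = 0.25,
    light_threshold: float = 40.0,
) -> list[ActivityRecord]:
    """Run the full cascade over a frame stream.

    Per lit frame: detect -> select the pig -> if the *previous* lit frame
    held a standing pig, track features from it into this frame and credit
    the displacement to the previous frame's accumulation window (motion
    measured between two captures happened during the interval they span)
    -> once a window is complete, accumulate its displacement and classify
    every frame in it.  Dark frames produce no records and break flow
    pairing.  Frames with no selected pig yield UNKNOWN records (honest
    missingness; the aggregation layer decides how to treat them).
    Per-frame failures are logged, never raised.
    """
    flow_params = flow_params or FlowParams()
    thresholds = thresholds or ThresholdConfig()
    records: list[ActivityRecord] = []
    pending: list[_PendingFrame] = []
    prev: dict | None = None  # pixels, pyramid (lazy), pig_box, posture

    def flush(up_to_window: int | None) -> None:
        """Emit records for all pending windows strictly before ``up_to_window``."""
        nonlocal pending
        while pending:
            wid = pending[0].window_id
            if up_to_window is not None and wid >= up_to_window:
                return
            group = [p for p in pending if p.window_id == wid]
            pending = pending[len(group):]
            pair_disps = [p.pair_displacement for p in group if p.pair_displacement is not None]
            px_per_s = accumulate_displacement(
                pair_disps, fps, thresholds.accumulation_window_s
            )
            for p in group:
                if p.posture is None:
                    state: int | None = None
                    low_conf = True
                    disp = None
                else:
                    disp = px_per_s if p.posture is Label.PIG_STANDING else None
                    state, low_conf = classify(p.posture, disp, thresholds)
                records.append(
                    ActivityRecord(
                        timestamp_s=p.timestamp_s,
                        frame_index=p.frame_index,
                        state=state,
                        keeper_present=p.keeper,
                        displacement_px_per_s=disp,
                        pig_box=p.pig_box,
                        low_confidence=low_conf,
                    )
                )

    for frame in frames:
        if frame.mean_intensity <= light_threshold:
            prev = None  # recording gap: never pair flow across darkness
            continue
        wid = int(math.floor(frame.timestamp_s / thresholds.accumulation_window_s))

        try:
            detections = detector.detect(frame, confidence_threshold)
        except Exception:  # noqa: BLE001 - a bad frame must not kill the run
            logger.exception("detector failed on frame %d", frame.frame_index)
            detections = []
        pig = select_pig(detections)
        keeper = keeper_present(detections)

        cur_pyramid = None
        if (
            prev is not None
            and prev["posture"] is Label.PIG_STANDING
            and prev["pig_box"] is not None
            and pending
        ):
            try:
                pair_disp, cur_pyramid = _pair_displacement(
                    prev, frame.pixels, flow_params
                )
                pending[-1].pair_displacement = pair_disp
            except Exception:  # noqa: BLE001
                logger.exception("flow failed on frame %d", frame.frame_index)

        # The previous window is complete only now that its last frame has
        # received its pair displacement.
        flush(up_to_window=wid)

        pending.append(
            _PendingFrame(
                frame_index=frame.frame_index,
                timestamp_s=frame.timestamp_s,
                window_id=wid,
                posture=pig.label if pig is not None else None,
                keeper=keeper,
                pig_box=pig.box if pig is not None else None,
            )
        )
        prev = {
            "pixels": frame.pixels,
            "pyramid": cur_pyramid,
            "pig_box": pig.box if pig is not None else None,
            "posture": pig.label if pig is not None else None,
        }
    flush(up_to_window=None)
    return records


def _pair_displacement(
    prev: dict, cur_pixels: np.ndarray, params: FlowParams
) -> tuple[float | None, list[np.ndarray]]:
    """Mean tracked displacement from the previous frame into the current one.

    Features are re-detected in the previous frame inside its pig box
    (scoring crops to the box, so cost tracks the pig, not the pen);
    tracking runs on full-frame pyramids so large 1 fps motions stay
    inside the image.
    """
    prev_px = prev["pixels"]
    features = shi_tomasi_features(prev_px, prev["pig_box"], params)
    cur_pyramid = build_pyramid(cur_pixels, params.pyramid_levels)
    if not features:
        return None, cur_pyramid
    if prev["pyramid"] is None:
        prev["pyramid"] = build_pyramid(prev_px, params.pyramid_levels)
    vectors = lucas_kanade(
        prev_px, cur_pixels, features, params, pyramids=(prev["pyramid"], cur_pyramid)
    )
    mean_px, n_tracked = mean_displacement(vectors)
    if n_tracked == 0:
        return None, cur_pyramid
    return mean_px, cur_pyramid


# -- CSV round-trip ----------------------------------------------------------

_CSV_COLUMNS = [
    "frame_index",
    "timestamp_s",
    "state",
    "keeper_present",
    "displacement_px_per_s",
    "x_min",
    "y_min",
    "x_max",
    "y_max",
    "low_confidence",
]


def records_to_csv(records: Sequence[ActivityRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        box = r.pig_box
        rows.append(
            (
                r.frame_index,
                r.timestamp_s,
                "" if r.state is None else r.state,
                r.keeper_present,
                "" if r.displacement_px_per_s is None else r.displacement_px_per_s,
                *((box.x_min, box.y_min, box.x_max, box.y_max) if box else ("",) * 4),
                r.low_confidence,
            )
        )
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)


def records_from_csv(path: str | Path) -> list[ActivityRecord]:
    df = pd.read_csv(path)
    out = []
    for r in df.itertuples(index=False):
        box = (
            None
            if pd.isna(r.x_min)
            else BoundingBox(int(r.x_min), int(r.y_min), int(r.x_max), int(r.y_max))
        )
        out.append(
            ActivityRecord(
                timestamp_s=float(r.timestamp_s),
                frame_index=int(r.frame_index),
                state=None if pd.isna(r.state) else int(r.state),
                keeper_present=bool(r.keeper_present),
                displacement_px_per_s=(
                    None if pd.isna(r.displacement_px_per_s) else float(r.displacement_px_per_s)
                ),
                pig_box=box,
                low_confidence=bool(r.low_confidence),
            )
        )
    return out
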