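"""Posture detection: a pluggable detector interface plus a reference detector.

The posture stage of the cascade decides whether the (single) pig in a pen
is lying or standing, and whether a human keeper is in the picture.  In
deployment this stage is a trained object-detection model; here it is an
interface (:class:`Detector`) with a reference implementation tuned to the
synthetic imaging model, so the full pipeline is testable without footage
or a trained network.  Any detector that honours the interface contract —
return class-labelled, confidence-scored boxes at or above the requested
confidence — is interchangeable.

Conventions shared by all modules: boxes are half-open pixel intervals
``[x_min, x_max) × [y_min, y_max)`` with the origin at the top-left corner,
x rightward and y downward.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Callable, Iterable, Protocol, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .video_io import Frame

__all__ = [
    "Label",
    "BoundingBox",
    "Detection",
    "Detector",
    "DetectorParams",
    "ReferenceDetector",
    "select_pig",
    "keeper_present",
    "detections_to_csv",
    "detections_from_csv",
]


class Label(str, Enum):
    PIG_LYING = "pig_lying"
    PIG_STANDING = "pig_standing"
    KEEPER = "keeper"

    @property
    def is_pig(self) -> bool:
        return self in (Label.PIG_LYING, Label.PIG_STANDING)


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned half-open pixel rectangle."""

    x_min: int
    y_min: int
    x_max: int
    y_max: int

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError(f"degenerate box {self}")

    @property
    def width(self) -> int:
        return self.x_max - self.x_min

    @property
    def height(self) -> int:
        return self.y_max - self.y_min

    @property
    def area(self) -> int:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return ((self.x_min + self.x_max) / 2, (self.y_min + self.y_max) / 2)

    def clipped(self, width: int, height: int) -> "BoundingBox":
        return BoundingBox(
            max(self.x_min, 0),
            max(self.y_min, 0),
            min(self.x_max, width),
            min(self.y_max, height),
        )

    def expanded(self, margin: int, width: int, height: int) -> "BoundingBox":
        return BoundingBox(
            max(self.x_min - margin, 0),
            max(self.y_min - margin, 0),
            min(self.x_max + margin, width),
            min(self.y_max + margin, height),
        )


@dataclass(frozen=True)
class Detection:
    box: BoundingBox
    label: Label
    confidence: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")


class Detector(Protocol):
    """Contract for posture detectors.

    Implementations return only detections with confidence >= the given
    threshold; an empty list is a valid result.  The optional ``nms``
    callable is a hook for model-based detectors whose raw boxes overlap;
    the reference detector never needs it.
    """

    def detect(
        self,
        frame: Frame,
        confidence_threshold: float = 0.5,
        nms: Callable[[list[Detection]], list[Detection]] | None = None,
    ) -> list[Detection]: ...


@dataclass(frozen=True)
class DetectorParams:
    """Knobs of the reference (background-subtraction) detector.

    background_gray is the pen floor intensity of the imaging model;
    anything brighter than background + binarize_offset is foreground.
    Components brighter than keeper_mean_gray are the keeper; the largest
    remaining component is the pig, lying if its area reaches area_split
    (a lying pig's top-down footprint is roughly twice a standing pig's).
    """

    background_gray: float = 60.0
    binarize_offset: float = 40.0
    min_area_px: int = 100
    area_split_px: float = 1100.0
    keeper_mean_gray: float = 200.0
    keeper_confidence: float = 0.99


_EIGHT_CONNECTED = np.ones((3, 3), dtype=int)


class ReferenceDetector:
    """Connected-component posture detector for the synthetic imaging model.

    Background-subtracts against a known uniform floor gray, binarizes,
    fills holes, labels 8-connected components and discards specks.  It is
    deliberately simple: its job is to stand behind the :class:`Detector`
    interface so the cascade, flow and statistics layers can be exercised
    end to end.
    """

    def __init__(self, params: DetectorParams | None = None) -> None:
        self.params = params or DetectorParams()

    def detect(
        self,
        frame: Frame,
        confidence_threshold: float = 0.5,
        nms: Callable[[list[Detection]], list[Detection]] | None = None,
    ) -> list[Detection]:
        p = self.params
        img = frame.pixels.astype(np.float64)
        mask = img > p.background_gray + p.binarize_offset
        if not mask.any():
            return []
        mask = ndimage.binary_fill_holes(mask)
        labels, n = ndimage.label(mask, structure=_EIGHT_CONNECTED)
        if n == 0:
            return []
        areas = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
        means = ndimage.mean(img, labels, index=range(1, n + 1))
        slices = ndimage.find_objects(labels)

        detections: list[Detection] = []
        pig_candidates: list[tuple[float, BoundingBox]] = []
        for area, mean, slc in zip(areas, means, slices):
            if area < p.min_area_px or slc is None:
                continue
            box = BoundingBox(slc[1].start, slc[0].start, slc[1].stop, slc[0].stop)
            if mean >= p.keeper_mean_gray:
                detections.append(Detection(box, Label.KEEPER, p.keeper_confidence))
            else:
                pig_candidates.append((float(area), box))
        if pig_candidates:
            area, box = max(pig_candidates, key=lambda c: c[0])
            label = Label.PIG_LYING if area >= p.area_split_px else Label.PIG_STANDING
            confidence = min(1.0, area / (2.0 * p.area_split_px))
            detections.append(Detection(box, label, confidence))
        if nms is not None:
            detections = nms(detections)
        return [d for d in detections if d.confidence >= confidence_threshold]


def select_pig(detections: Sequence[Detection]) -> Detection | None:
    """Single-pig-pen policy: the best pig-labelled detection, if any.

    Highest confidence wins; ties break to the larger box, then to the
    smaller x_min.  Keeper detections are never returned.
    """
    pigs = [d for d in detections if d.label.is_pig]
    if not pigs:
        return None
    return max(pigs, key=lambda d: (d.confidence, d.box.area, -d.box.x_min))


def keeper_present(detections: Sequence[Detection]) -> bool:
    return any(d.label is Label.KEEPER for d in detections)


# -- CSV round-trip ---------------------------------------------------------

_CSV_COLUMNS = ["frame_index", "label", "confidence", "x_min", "y_min", "x_max", "y_max"]


def detections_to_csv(
    per_frame: Iterable[tuple[int, Sequence[Detection]]], path: str | Path
) -> None:
    rows = [
        (idx, d.label.value, d.confidence, d.box.x_min, d.box.y_min, d.box.x_max, d.box.y_max)
        for idx, dets in per_frame
        for d in dets
    ]
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)


def detections_from_csv(path: str | Path) -> dict[int, list[Detection]]:
    df = pd.read_csv(path)
    out: dict[int, list[Detection]] = {}
    for row in df.itertuples(index=False):
        det = Detection(
            BoundingBox(int(row.x_min), int(row.y_min), int(row.x_max), int(row.y_max)),
            Label(row.label),
            float(row.confidence),
        )
        out.setdefault(int(row.frame_index), []).append(det)
    return out
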