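"""Synthetic overhead-pen scenes with per-frame ground truth.

Emulates the facility the tracker targets: a fixed ceiling camera over a
single-pig pen (240 cm x 266 cm, rendered at 1 px/cm by default), constant
LED lighting on a 12 h on/off cycle with pitch-black nights, one Goettingen
minipig alternating lying / standing / walking on a diurnal schedule with
morning and afternoon activity peaks, occasional keeper visits, and a ball
as a distractor object.

The pig is a textured ellipse seen top-down: a lying pig presents a larger
footprint (60 x 28 px axes) than a standing one (44 x 20 px), which is what
the reference detector keys on.  Multiplicative speckle on the body gives
the Lucas-Kanade tracker corner structure to lock onto.  A walking pig
moves at 30 px/s with a random-turn heading; lying and standing pigs hold
position, so motion separates walking from standing jitter at both 1 and
25 fps.  Dark frames are emitted rather than skipped so light gating is
testable end to end.

Everything is a pure function of (config, seed): per-frame render noise is
drawn from seeds derived from (scene seed, frame index), so lazily
re-iterating the frames gives byte-identical pixels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .detection import BoundingBox
from .video_io import Frame, write_sequence

__all__ = [
    "SceneConfig",
    "SceneConfigError",
    "GroundTruthRecord",
    "PigPose",
    "Scene",
    "generate_scene",
    "behavior_state_machine",
    "render_frame",
    "write_scene",
    "read_truth",
    "LYING",
    "STANDING",
    "WALKING",
]

# Activity state codes used throughout the package.
LYING, STANDING, WALKING = 1, 2, 3

# Imaging-model constants (gray levels in [0, 255], lengths in px).
BACKGROUND_GRAY = 60.0
NOISE_SIGMA = 3.0
PIG_GRAY = 150.0
LYING_SEMI_AXES = (30.0, 14.0)  # semi-major, semi-minor -> area ~ 1319 px^2
STANDING_SEMI_AXES = (22.0, 10.0)  # -> area ~ 691 px^2
TEXTURE_AMPLITUDE = 0.22
KEEPER_GRAY = 220.0
KEEPER_SIZE = (24, 50)  # width, height
BALL_GRAY = 90.0
BALL_RADIUS = 8.0
DARK_GRAY = 3.0
WALK_SPEED_PX_PER_S = 30.0
TURN_SIGMA_RAD_PER_S = 0.3  # heading random walk, per simulated second

# Per-second transition probabilities of the behaviour chain as a function
# of the hour's walking propensity w.  Chosen so that a mid-range w yields
# an activity budget of roughly 45% lying / 45% standing / 10% walking with
# lying bouts on the minute scale and walking bouts of a few seconds.
_P_LIE_TO_STAND = (0.005, 0.03)  # a + b*w
_P_STAND_TO_LIE = (0.002, 0.02)  # a + b*(1-w)
_P_STAND_TO_WALK = 0.08  # * w
_P_WALK_TO_STAND = 0.15


class SceneConfigError(ValueError):
    """Invalid scene configuration."""


@dataclass(frozen=True)
class SceneConfig:
    """Full description of a synthetic recording session.

    light_schedule and keeper_events are (start_s, end_s) intervals in
    scene-relative seconds; a ``None`` light schedule means lights on for
    the whole duration.  activity_profile maps hour-of-day to walking
    propensity in [0, 1] (a bare float applies to every hour).
    start_hour anchors scene time to wall-clock hour of day so hourly
    aggregation is meaningful.
    """

    pen_width_px: int = 240
    pen_height_px: int = 266
    fps: int = 25
    duration_s: float = 60.0
    light_schedule: Sequence[tuple[float, float]] | None = None
    activity_profile: Mapping[int, float] | float = 0.4
    keeper_events: Sequence[tuple[float, float]] = field(default_factory=tuple)
    ball_present: bool = False
    seed: int = 0
    start_hour: float = 6.5

    def __post_init__(self) -> None:
        if self.pen_width_px < 64 or self.pen_height_px < 64:
            raise SceneConfigError("pen dimensions must be >= 64 px")
        if self.fps not in (1, 25):
            raise SceneConfigError(f"fps must be 1 or 25, got {self.fps}")
        if self.duration_s <= 0:
            raise SceneConfigError("duration must be positive")
        for name, intervals in (
            ("light_schedule", self.light_schedule or ()),
            ("keeper_events", self.keeper_events),
        ):
            prev_end = -math.inf
            for interval in sorted(intervals):
                start, end = interval
                if not (0 <= start < end <= self.duration_s):
                    raise SceneConfigError(
                        f"{name} interval {interval} outside [0, {self.duration_s}]"
                    )
                if start < prev_end:
                    raise SceneConfigError(f"{name} interval {interval} overlaps previous")
                prev_end = end
        for hour, w in self._profile_items():
            if not 0.0 <= w <= 1.0:
                raise SceneConfigError(f"propensity {w} for hour {hour} outside [0, 1]")

    def _profile_items(self) -> list[tuple[int, float]]:
        if isinstance(self.activity_profile, Mapping):
            return [(int(h), float(w)) for h, w in self.activity_profile.items()]
        return [(-1, float(self.activity_profile))]

    def propensity(self, hour_of_day: int) -> float:
        if isinstance(self.activity_profile, Mapping):
            return float(self.activity_profile.get(hour_of_day % 24, 0.0))
        return float(self.activity_profile)

    @property
    def n_frames(self) -> int:
        return int(round(self.fps * self.duration_s))

    def lights_on_at(self, t_s: float) -> bool:
        if self.light_schedule is None:
            return True
        return any(start <= t_s < end for start, end in self.light_schedule)

    def keeper_at(self, t_s: float) -> bool:
        return any(start <= t_s < end for start, end in self.keeper_events)


@dataclass(frozen=True)
class GroundTruthRecord:
    frame_index: int
    timestamp_s: float
    state: int  # LYING / STANDING / WALKING
    pig_box: BoundingBox
    keeper_present: bool
    lights_on: bool


@dataclass(frozen=True)
class PigPose:
    """Pig centre, heading (radians, 0 = +x) and posture footprint."""

    x: float
    y: float
    heading: float
    lying: bool

    @property
    def semi_axes(self) -> tuple[float, float]:
        return LYING_SEMI_AXES if self.lying else STANDING_SEMI_AXES


# -- behaviour ---------------------------------------------------------------


def behavior_state_machine(
    profile: Mapping[int, float] | float,
    n_steps: int,
    rng: np.random.Generator,
    *,
    step_s: float = 1.0,
    start_s: float = 0.0,
) -> np.ndarray:
    """Markov dwell-time chain over lying/standing/walking, 1 Hz steps.

    Walking is reachable only from standing (matching the cascade's
    semantics: flow is consulted only for a standing pig), and the
    standing->walking rate scales with the hour's walking propensity, so
    the expected hourly walking fraction is monotone in the profile.
    """
    get = (
        (lambda h: float(profile.get(h % 24, 0.0)))
        if isinstance(profile, Mapping)
        else (lambda h: float(profile))
    )
    states = np.empty(n_steps, dtype=np.int8)
    state = LYING
    for i in range(n_steps):
        hour = int((start_s + i * step_s) // 3600) % 24
        w = get(hour)
        u = rng.random()
        if state == LYING:
            if u < _P_LIE_TO_STAND[0] + _P_LIE_TO_STAND[1] * w:
                state = STANDING
        elif state == STANDING:
            p_walk = _P_STAND_TO_WALK * w
            p_lie = _P_STAND_TO_LIE[0] + _P_STAND_TO_LIE[1] * (1.0 - w)
            if u < p_walk:
                state = WALKING
            elif u < p_walk + p_lie:
                state = LYING
        else:  # WALKING
            if u < _P_WALK_TO_STAND:
                state = STANDING
        states[i] = state
    return states


# -- rendering ---------------------------------------------------------------


def _make_texture_tile(rng: np.random.Generator, size: int = 64) -> np.ndarray:
    """Smooth unit-variance speckle field, sampled in pig-body coordinates."""
    tile = rng.standard_normal((size, size))
    tile = ndimage.gaussian_filter(tile, sigma=1.2, mode="wrap")
    return tile / tile.std()


_DEFAULT_TILE: np.ndarray | None = None


def _default_tile() -> np.ndarray:
    global _DEFAULT_TILE
    if _DEFAULT_TILE is None:
        _DEFAULT_TILE = _make_texture_tile(np.random.default_rng(0xA11CE))
    return _DEFAULT_TILE


def _sample_tile_wrap(tile: np.ndarray, us: np.ndarray, vs: np.ndarray) -> np.ndarray:
    n = tile.shape[0]
    u0 = np.floor(us).astype(int)
    v0 = np.floor(vs).astype(int)
    fu = us - u0
    fv = vs - v0
    u0 %= n
    v0 %= n
    u1 = (u0 + 1) % n
    v1 = (v0 + 1) % n
    return (
        tile[v0, u0] * (1 - fv) * (1 - fu)
        + tile[v0, u1] * (1 - fv) * fu
        + tile[v1, u0] * fv * (1 - fu)
        + tile[v1, u1] * fv * fu
    )


def _keeper_box(pen_w: int, pen_h: int) -> BoundingBox:
    # Keeper works from a fixed spot by the pen gate (top-left corner).
    return BoundingBox(4, 4, 4 + KEEPER_SIZE[0], 4 + KEEPER_SIZE[1])


def _ball_center(pen_w: int, pen_h: int) -> tuple[float, float]:
    return pen_w - 16.0, pen_h - 16.0


def render_frame(
    pig_pose: PigPose,
    keeper_present: bool,
    ball_present: bool,
    lights_on: bool,
    pen_dims: tuple[int, int],
    rng: np.random.Generator,
    texture: np.ndarray | None = None,
) -> np.ndarray:
    """Rasterize one grayscale frame of the imaging model.

    Lights off yields a near-black frame (every pixel < 10).  Otherwise the
    pig is a speckled ellipse of mean gray 150, the keeper a gray-220
    rectangle, the ball a gray-90 disc, over a gray-60 floor; sensor noise
    (sigma = 3) is added to the whole frame last.
    """
    pen_w, pen_h = pen_dims
    if lights_on and not (0 <= pig_pose.x < pen_w and 0 <= pig_pose.y < pen_h):
        raise ValueError("pig pose outside pen")
    if not lights_on:
        dark = DARK_GRAY + rng.standard_normal((pen_h, pen_w))
        return np.clip(dark, 0, 9).astype(np.uint8)

    img = np.full((pen_h, pen_w), BACKGROUND_GRAY)
    if ball_present:
        bx, by = _ball_center(pen_w, pen_h)
        ys, xs = np.ogrid[:pen_h, :pen_w]
        img[(xs - bx) ** 2 + (ys - by) ** 2 <= BALL_RADIUS**2] = BALL_GRAY
    if keeper_present:
        kb = _keeper_box(pen_w, pen_h)
        img[kb.y_min : kb.y_max, kb.x_min : kb.x_max] = KEEPER_GRAY

    a, b = pig_pose.semi_axes
    tile = texture if texture is not None else _default_tile()
    reach = int(math.ceil(max(a, b))) + 2
    x0 = max(int(pig_pose.x) - reach, 0)
    x1 = min(int(pig_pose.x) + reach + 1, pen_w)
    y0 = max(int(pig_pose.y) - reach, 0)
    y1 = min(int(pig_pose.y) + reach + 1, pen_h)
    ys, xs = np.mgrid[y0:y1, x0:x1]
    dx = xs - pig_pose.x
    dy = ys - pig_pose.y
    cos_h, sin_h = math.cos(pig_pose.heading), math.sin(pig_pose.heading)
    u = cos_h * dx + sin_h * dy  # body-long axis
    v = -sin_h * dx + cos_h * dy
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    n = tile.shape[0]
    speckle = _sample_tile_wrap(tile, u + n / 2.0, v + n / 2.0)
    body = PIG_GRAY * (1.0 + TEXTURE_AMPLITUDE * speckle)
    patch = img[y0:y1, x0:x1]
    patch[inside] = body[inside]

    img += NOISE_SIGMA * rng.standard_normal(img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


# -- scene assembly ----------------------------------------------------------


class Scene:
    """A fully simulated recording: lazy frames plus eager ground truth.

    The behaviour chain and trajectory are simulated once at construction
    (cheap); pixels are rendered on demand in :meth:`frames`, with per-frame
    noise seeded from (scene seed, frame index) so repeated iteration is
    byte-identical.
    """

    def __init__(self, config: SceneConfig) -> None:
        self.config = config
        self._tile = _make_texture_tile(
            np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(0,)))
        )
        self._poses: list[PigPose] = []
        self.truth: list[GroundTruthRecord] = []
        self._simulate()

    def _pig_region(self) -> tuple[float, float, float, float]:
        """(x_min, x_max, y_min, y_max) for the pig centre.

        Keeps the full body inside the pen and clear of the keeper's spot
        and the ball's corner, so components never merge in the detector.
        """
        cfg = self.config
        margin = LYING_SEMI_AXES[0] + 6.0
        x_min = max(margin, _keeper_box(cfg.pen_width_px, cfg.pen_height_px).x_max + margin)
        return (x_min, cfg.pen_width_px - margin, margin, cfg.pen_height_px - margin)

    def _simulate(self) -> None:
        cfg = self.config
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=cfg.seed, spawn_key=(1,))
        )
        n_seconds = int(math.ceil(cfg.duration_s))
        states = behavior_state_machine(
            cfg.activity_profile, n_seconds, rng, start_s=cfg.start_hour * 3600.0
        )
        x_lo, x_hi, y_lo, y_hi = self._pig_region()
        x = (x_lo + x_hi) / 2.0
        y = (y_lo + y_hi) / 2.0
        # Heading drifts once per second, so within-second motion is straight
        # and a low-rate sampler sees bounded body rotation between captures.
        turn_deltas = rng.normal(0.0, TURN_SIGMA_RAD_PER_S, n_seconds)
        step = WALK_SPEED_PX_PER_S / cfg.fps
        heading = rng.uniform(0, 2 * math.pi)
        motion_second = 0

        for i in range(cfg.n_frames):
            t = i / cfg.fps
            state = int(states[min(int(t), n_seconds - 1)])
            if i > 0:
                # Motion entering this frame belongs to the elapsed interval,
                # i.e. the previous frame's second: a 1 fps sampler then sees
                # exactly the distance walked during the second it spans.
                s_prev = min(int((i - 1) / cfg.fps), n_seconds - 1)
                if s_prev != motion_second:
                    motion_second = s_prev
                    # Only a walking pig turns; a resting pig holds its pose,
                    # so non-walking captures differ by sensor noise alone.
                    if int(states[s_prev]) == WALKING:
                        heading += float(turn_deltas[s_prev])
                if int(states[s_prev]) == WALKING:
                    x += step * math.cos(heading)
                    y += step * math.sin(heading)
                    if x < x_lo or x > x_hi:
                        x = min(max(x, x_lo), x_hi)
                        heading = math.pi - heading
                    if y < y_lo or y > y_hi:
                        y = min(max(y, y_lo), y_hi)
                        heading = -heading
            pose = PigPose(x, y, heading, lying=state == LYING)
            self._poses.append(pose)
            a, b = pose.semi_axes
            cos_h, sin_h = abs(math.cos(heading)), abs(math.sin(heading))
            half_w = math.hypot(a * cos_h, b * sin_h)
            half_h = math.hypot(a * sin_h, b * cos_h)
            box = BoundingBox(
                max(int(math.floor(x - half_w)), 0),
                max(int(math.floor(y - half_h)), 0),
                min(int(math.ceil(x + half_w)) + 1, cfg.pen_width_px),
                min(int(math.ceil(y + half_h)) + 1, cfg.pen_height_px),
            )
            self.truth.append(
                GroundTruthRecord(
                    frame_index=i,
                    timestamp_s=cfg.start_hour * 3600.0 + t,
                    state=state,
                    pig_box=box,
                    keeper_present=cfg.keeper_at(t),
                    lights_on=cfg.lights_on_at(t),
                )
            )

    def frames(self) -> Iterator[Frame]:
        cfg = self.config
        dims = (cfg.pen_width_px, cfg.pen_height_px)
        for record, pose in zip(self.truth, self._poses):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=cfg.seed, spawn_key=(2, record.frame_index))
            )
            pixels = render_frame(
                pose,
                keeper_present=record.keeper_present,
                ball_present=cfg.ball_present,
                lights_on=record.lights_on,
                pen_dims=dims,
                rng=rng,
                texture=self._tile,
            )
            yield Frame(pixels, record.frame_index, record.timestamp_s)


def generate_scene(
    config: SceneConfig,
) -> tuple[Iterator[Frame], list[GroundTruthRecord]]:
    """Simulate a scene; returns (lazy frame iterator, ground-truth records)."""
    scene = Scene(config)
    return scene.frames(), scene.truth


# -- persistence -------------------------------------------------------------

_TRUTH_COLUMNS = [
    "frame_index",
    "timestamp_s",
    "state",
    "x_min",
    "y_min",
    "x_max",
    "y_max",
    "keeper_present",
    "lights_on",
]


def write_scene(scene: Scene, out_dir: str | Path) -> None:
    """Write frames as PNGs + manifest.csv, and ground truth as truth.csv."""
    out_dir = Path(out_dir)
    write_sequence(scene.frames(), out_dir)
    rows = [
        (
            r.frame_index,
            r.timestamp_s,
            r.state,
            r.pig_box.x_min,
            r.pig_box.y_min,
            r.pig_box.x_max,
            r.pig_box.y_max,
            r.keeper_present,
            r.lights_on,
        )
        for r in scene.truth
    ]
    pd.DataFrame(rows, columns=_TRUTH_COLUMNS).to_csv(out_dir / "truth.csv", index=False)


def read_truth(path: str | Path) -> list[GroundTruthRecord]:
    path = Path(path)
    if path.is_dir():
        path = path / "truth.csv"
    df = pd.read_csv(path)
    return [
        GroundTruthRecord(
            frame_index=int(r.frame_index),
            timestamp_s=float(r.timestamp_s),
            state=int(r.state),
            pig_box=BoundingBox(int(r.x_min), int(r.y_min), int(r.x_max), int(r.y_max)),
            keeper_present=bool(r.keeper_present),
            lights_on=bool(r.lights_on),
        )
        for r in df.itertuples(index=False)
    ]
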