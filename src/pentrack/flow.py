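"""Sparse optical flow: Shi–Tomasi features and pyramidal Lucas–Kanade.

Implemented from first principles on numpy.  The movement stage of the
cascade needs per-frame displacement of the pig inside its bounding box;
sparse flow gives that at a cost that scales with the feature budget, not
the pen area, which is what makes the method viable on low-power hardware.

Model: brightness constancy plus locally uniform motion within a window.
For a point p with window W, the displacement d solves the normal equations
G d = b with G = Σ_W [Ix² IxIy; IxIy Iy²] (the structure tensor of the
previous frame) and b = Σ_W ∇I · (I_prev − I_next(p+d)), iterated to a
fixed point.  A coarse-to-fine image pyramid extends the usable motion
range well beyond the window radius.  Shi–Tomasi selects points where the
structure tensor is well conditioned (large minimum eigenvalue), i.e. where
the system is solvable in both directions.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import ndimage

from .detection import BoundingBox

__all__ = [
    "FlowParams",
    "FeaturePoint",
    "FlowStatus",
    "FlowVector",
    "structure_tensor_eigmin",
    "shi_tomasi_features",
    "build_pyramid",
    "lucas_kanade",
    "mean_displacement",
]


@dataclass(frozen=True)
class FlowParams:
    """Free parameters of the feature selection and tracking stages.

    Defaults follow the conventional settings of widely used sparse-flow
    implementations: a 21 px window, 3 pyramid levels, at most 50 features
    re-detected per frame.
    """

    window: int = 21
    pyramid_levels: int = 3
    max_iters: int = 10
    epsilon: float = 0.01
    max_features: int = 50
    quality_level: float = 0.01
    min_distance: float = 7.0
    #: structure-tensor block used for feature scoring (smaller than the
    #: tracking window; corners are local structures)
    feature_block: int = 5

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")
        if self.pyramid_levels < 1:
            raise ValueError("pyramid_levels must be >= 1")


@dataclass(frozen=True)
class FeaturePoint:
    x: float
    y: float
    score: float


class FlowStatus(Enum):
    TRACKED = "tracked"
    LOST = "lost"


@dataclass(frozen=True)
class FlowVector:
    origin: FeaturePoint
    dx: float
    dy: float
    status: FlowStatus
    residual: float  # mean absolute window error, gray levels

    @property
    def magnitude(self) -> float:
        return float(np.hypot(self.dx, self.dy))


# -- feature scoring and selection ------------------------------------------


def structure_tensor_eigmin(image: np.ndarray, window: int) -> np.ndarray:
    """Per-pixel minimum eigenvalue of the windowed structure tensor.

    Gradients by central differences; the tensor entries are box sums over
    ``window``.  Flat patches score 0, edges score ~0 (rank-1 tensor), and
    only two-dimensional structure (corners, texture) scores high.
    """
    img = np.asarray(image, dtype=np.float64)
    if min(img.shape) < window:
        raise ValueError("image smaller than scoring window")
    gy, gx = np.gradient(img)
    area = window * window
    gxx = ndimage.uniform_filter(gx * gx, size=window) * area
    gxy = ndimage.uniform_filter(gx * gy, size=window) * area
    gyy = ndimage.uniform_filter(gy * gy, size=window) * area
    trace_half = (gxx + gyy) / 2.0
    disc = np.sqrt(((gxx - gyy) / 2.0) ** 2 + gxy**2)
    return np.maximum(trace_half - disc, 0.0)


def shi_tomasi_features(
    image: np.ndarray, roi: BoundingBox, params: FlowParams | None = None
) -> list[FeaturePoint]:
    """Best trackable points inside ``roi``, greedily spaced.

    Local maxima of the eigmin map whose score reaches quality_level times
    the ROI's best score, kept best-first subject to a pairwise distance of
    at least min_distance, capped at max_features.  A featureless ROI
    yields an empty list, which callers treat as zero movement confidence.
    """
    params = params or FlowParams()
    img = np.asarray(image, dtype=np.float64)
    roi = roi.clipped(img.shape[1], img.shape[0])
    crop = img[roi.y_min : roi.y_max, roi.x_min : roi.x_max]
    if min(crop.shape) < params.feature_block:
        return []
    score = structure_tensor_eigmin(crop, params.feature_block)
    peak = float(score.max())
    if peak <= 0.0:
        return []
    is_max = score == ndimage.maximum_filter(score, size=3)
    candidates = np.argwhere(is_max & (score >= params.quality_level * peak) & (score > 0))
    if candidates.size == 0:
        return []
    order = np.argsort(score[candidates[:, 0], candidates[:, 1]])[::-1]
    candidates = candidates[order]

    kept: list[FeaturePoint] = []
    kept_xy = np.empty((0, 2))
    min_d2 = params.min_distance**2
    for r, c in candidates:
        if len(kept) >= params.max_features:
            break
        if len(kept) and np.min(np.sum((kept_xy - (c, r)) ** 2, axis=1)) < min_d2:
            continue
        kept.append(
            FeaturePoint(float(c + roi.x_min), float(r + roi.y_min), float(score[r, c]))
        )
        kept_xy = np.vstack([kept_xy, (c, r)])
    return kept


# -- pyramid -----------------------------------------------------------------

_BINOMIAL_5 = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0


def build_pyramid(image: np.ndarray, levels: int) -> list[np.ndarray]:
    """Coarse-to-fine pyramid: 5-tap binomial blur then 2x decimation.

    Level 0 is the input; dimensions halve (floor) per level.  The blur is
    mean-preserving, so coarse levels keep the scene's intensity scale.
    """
    img = np.asarray(image, dtype=np.float64)
    if levels < 1:
        raise ValueError("levels must be >= 1")
    min_dim = 2 ** (levels - 1)
    if min(img.shape) < min_dim:
        raise ValueError(
            f"image {img.shape} too small for {levels} pyramid levels"
        )
    pyramid = [img]
    for _ in range(levels - 1):
        blurred = ndimage.correlate1d(img, _BINOMIAL_5, axis=0, mode="reflect")
        blurred = ndimage.correlate1d(blurred, _BINOMIAL_5, axis=1, mode="reflect")
        h, w = img.shape[0] // 2, img.shape[1] // 2
        img = blurred[: 2 * h : 2, : 2 * w : 2]
        pyramid.append(img)
    return pyramid


# -- Lucas–Kanade ------------------------------------------------------------


def _bilinear(img: np.ndarray, ys: np.ndarray, xs: np.ndarray) -> np.ndarray:
    """Sample img at float coords, clamping to the border."""
    h, w = img.shape
    ys = np.clip(ys, 0.0, h - 1.0)
    xs = np.clip(xs, 0.0, w - 1.0)
    y0 = np.minimum(np.floor(ys).astype(int), h - 2)
    x0 = np.minimum(np.floor(xs).astype(int), w - 2)
    fy = ys - y0
    fx = xs - x0
    return (
        img[y0, x0] * (1 - fy) * (1 - fx)
        + img[y0, x0 + 1] * (1 - fy) * fx
        + img[y0 + 1, x0] * fy * (1 - fx)
        + img[y0 + 1, x0 + 1] * fy * fx
    )


def lucas_kanade(
    prev: np.ndarray,
    next_: np.ndarray,
    points: list[FeaturePoint],
    params: FlowParams | None = None,
    pyramids: tuple[list[np.ndarray], list[np.ndarray]] | None = None,
) -> list[FlowVector]:
    """Track ``points`` from ``prev`` to ``next_``, coarse to fine.

    Per level, iterate d <- d + G^{-1} b until the update falls below
    epsilon or max_iters is hit; the estimate doubles when descending a
    level.  A point is LOST when its structure tensor is near singular at
    the finest level (min eigenvalue < 1e-4 * window^2), when it leaves the
    frame, or when the final mean absolute window error exceeds 20 gray
    levels.  Subpixel sampling is bilinear; gradients come from ``prev``
    (classical formulation).  Prebuilt ``pyramids`` may be passed to avoid
    recomputation across consecutive frame pairs.
    """
    params = params or FlowParams()
    prev = np.asarray(prev, dtype=np.float64)
    next_ = np.asarray(next_, dtype=np.float64)
    if prev.shape != next_.shape:
        raise ValueError(f"frame shape mismatch: {prev.shape} vs {next_.shape}")
    if pyramids is None:
        pyr_prev = build_pyramid(prev, params.pyramid_levels)
        pyr_next = build_pyramid(next_, params.pyramid_levels)
    else:
        pyr_prev, pyr_next = pyramids

    if not points:
        return []
    r = params.window // 2
    offs = np.arange(-r, r + 1, dtype=np.float64)
    oy, ox = np.meshgrid(offs, offs, indexing="ij")
    eig_floor = 1e-4 * params.window**2

    # All points are tracked together; per-point state lives in arrays.
    n = len(points)
    pts = np.array([(p.x, p.y) for p in points])  # (n, 2)
    g = np.zeros((n, 2))  # accumulated estimate at the current level's scale
    lost = np.zeros(n, dtype=bool)
    residual = np.full(n, np.inf)

    for level in range(params.pyramid_levels - 1, -1, -1):
        prev_l = pyr_prev[level]
        next_l = pyr_next[level]
        h, w = prev_l.shape
        scale = 2.0**level
        p = pts / scale
        lost |= (p[:, 0] < 0) | (p[:, 0] > w - 1) | (p[:, 1] < 0) | (p[:, 1] > h - 1)

        # A point whose window falls off this level would see clamped,
        # duplicated border samples; above the finest level it simply skips
        # refinement here (finer levels can still lock on), at the finest
        # level it is refined anyway so border features are not discarded.
        if level > 0:
            refine = (
                (p[:, 0] >= r + 1)
                & (p[:, 0] <= w - 2 - r)
                & (p[:, 1] >= r + 1)
                & (p[:, 1] <= h - 2 - r)
            )
        else:
            refine = np.ones(n, dtype=bool)

        ys = p[:, 1, None, None] + oy  # (n, win, win)
        xs = p[:, 0, None, None] + ox
        patch = _bilinear(prev_l, ys, xs)
        ix = (_bilinear(prev_l, ys, xs + 1.0) - _bilinear(prev_l, ys, xs - 1.0)) / 2.0
        iy = (_bilinear(prev_l, ys + 1.0, xs) - _bilinear(prev_l, ys - 1.0, xs)) / 2.0
        gxx = np.sum(ix * ix, axis=(1, 2))
        gxy = np.sum(ix * iy, axis=(1, 2))
        gyy = np.sum(iy * iy, axis=(1, 2))
        eig_min = (gxx + gyy) / 2.0 - np.sqrt(((gxx - gyy) / 2.0) ** 2 + gxy**2)
        det = gxx * gyy - gxy * gxy
        if level == 0:
            lost |= eig_min < eig_floor
        lost |= refine & (det <= 1e-12)
        safe_det = np.where(det > 1e-12, det, 1.0)

        d = np.zeros((n, 2))
        done = lost | ~refine
        diff = patch.copy()
        for _ in range(params.max_iters):
            if done.all():
                break
            cx = p[:, 0] + g[:, 0] + d[:, 0]
            cy = p[:, 1] + g[:, 1] + d[:, 1]
            wandered = ~done & ((cx < 0) | (cx > w - 1) | (cy < 0) | (cy > h - 1))
            lost |= wandered
            done |= wandered
            active = ~done
            if not active.any():
                break
            qy = ys[active] + (g[active, 1] + d[active, 1])[:, None, None]
            qx = xs[active] + (g[active, 0] + d[active, 0])[:, None, None]
            warped = _bilinear(next_l, qy, qx)
            diff[active] = patch[active] - warped
            bx = np.sum(ix[active] * diff[active], axis=(1, 2))
            by = np.sum(iy[active] * diff[active], axis=(1, 2))
            delta_x = (gyy[active] * bx - gxy[active] * by) / safe_det[active]
            delta_y = (gxx[active] * by - gxy[active] * bx) / safe_det[active]
            d[active, 0] += delta_x
            d[active, 1] += delta_y
            converged = np.hypot(delta_x, delta_y) < params.epsilon
            idx = np.flatnonzero(active)
            done[idx[converged]] = True
        if level > 0:
            g = 2.0 * (g + d)
        else:
            g = g + d
            # Final warp at the converged position scores the match quality.
            ok = ~lost
            if ok.any():
                qy = ys[ok] + g[ok, 1][:, None, None]
                qx = xs[ok] + g[ok, 0][:, None, None]
                final_diff = patch[ok] - _bilinear(next_l, qy, qx)
                residual[ok] = np.mean(np.abs(final_diff), axis=(1, 2))

    lost |= residual > 20.0
    return [
        FlowVector(
            pt,
            float(g[i, 0]),
            float(g[i, 1]),
            FlowStatus.LOST if lost[i] else FlowStatus.TRACKED,
            float(residual[i]),
        )
        for i, pt in enumerate(points)
    ]


def mean_displacement(vectors: list[FlowVector]) -> tuple[float, int]:
    """Mean displacement magnitude over TRACKED vectors.

    Returns ``(mean_px, n_tracked)``; (0.0, 0) when nothing tracked, which
    callers must treat as a zero-confidence movement estimate rather than
    evidence of stillness.
    """
    mags = [v.magnitude for v in vectors if v.status is FlowStatus.TRACKED]
    if not mags:
        return 0.0, 0
    return float(np.mean(mags)), len(mags)
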