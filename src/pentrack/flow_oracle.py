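"""Exhaustive block-matching displacement: an independent cross-check for flow.

Deliberately naive — no gradients, no pyramids, no iteration — so it shares
no code path or failure mode with the Lucas–Kanade tracker.  Useful only at
small search radii on synthetic pairs with a single global translation.
"""

from __future__ import annotations

import numpy as np

__all__ = ["block_matching_shift"]


def block_matching_shift(
    prev: np.ndarray, next_: np.ndarray, search: int = 5
) -> tuple[int, int]:
    """Integer (dx, dy) minimizing mean absolute error over the overlap.

    The returned shift is the motion of scene content from ``prev`` to
    ``next_``: content at (x, y) in prev appears at (x + dx, y + dy) in
    next.  Ties break toward the smaller shift magnitude, then
    lexicographically.
    """
    prev = np.asarray(prev, dtype=np.float64)
    next_ = np.asarray(next_, dtype=np.float64)
    if prev.shape != next_.shape:
        raise ValueError("shape mismatch")
    h, w = prev.shape
    if min(h, w) <= 2 * search:
        raise ValueError("image too small for requested search radius")

    best: tuple[float, int, int, int] | None = None
    for dy in range(-search, search + 1):
        for dx in range(-search, search + 1):
            # overlap of prev[y, x] with next[y + dy, x + dx]
            py0, py1 = max(0, -dy), min(h, h - dy)
            px0, px1 = max(0, -dx), min(w, w - dx)
            a = prev[py0:py1, px0:px1]
            b = next_[py0 + dy : py1 + dy, px0 + dx : px1 + dx]
            err = float(np.mean(np.abs(a - b)))
            key = (err, abs(dx) + abs(dy), dx, dy)
            if best is None or key < best:
                best = key
    assert best is not None
    return best[2], best[3]
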