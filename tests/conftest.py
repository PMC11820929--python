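"""Shared fixtures: synthetic scenes, textured image pairs, pipeline runs.

The expensive end-to-end scene (300 s at 25 fps) is generated and tracked
once per session and shared by the accuracy, consistency and comparison
tests.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage

from pentrack.activity import run_pipeline
from pentrack.detection import ReferenceDetector
from pentrack.synthetic import Scene, SceneConfig
from pentrack.video_io import downsample


def make_textured(h: int, w: int, rng: np.random.Generator) -> np.ndarray:
    """Random texture with both fine and coarse structure.

    Two smoothed noise octaves, so corners exist at full resolution and
    coarse pyramid levels still carry trackable gradients.
    """
    fine = ndimage.gaussian_filter(rng.standard_normal((h, w)), 1.5)
    coarse = ndimage.gaussian_filter(rng.standard_normal((h, w)), 6.0)
    img = fine / fine.std() + 1.5 * coarse / coarse.std()
    img = (img - img.min()) / (img.max() - img.min())
    return img * 200.0 + 20.0


def translated_pair(
    h: int, w: int, shift: tuple[int, int], rng: np.random.Generator, margin: int = 8
) -> tuple[np.ndarray, np.ndarray]:
    """Two views of one larger texture offset by an exact integer shift.

    Content at (x, y) in the first view appears at (x + dx, y + dy) in the
    second; no wrap-around artifacts.
    """
    dx, dy = shift
    if max(abs(dx), abs(dy)) > margin:
        raise ValueError("shift exceeds margin")
    big = make_textured(h + 2 * margin, w + 2 * margin, rng)
    prev = big[margin : margin + h, margin : margin + w]
    next_ = big[margin - dy : margin - dy + h, margin - dx : margin - dx + w]
    return prev.copy(), next_.copy()


@pytest.fixture(scope="session")
def e2e_scene() -> Scene:
    """A clean 5-minute daytime scene: one pig, no keeper, no ball."""
    return Scene(SceneConfig(duration_s=300.0, fps=25, seed=1, activity_profile=0.5))


@pytest.fixture(scope="session")
def e2e_records_25(e2e_scene: Scene):
    detector = ReferenceDetector()
    return run_pipeline(e2e_scene.frames(), detector, fps=25)


@pytest.fixture(scope="session")
def e2e_records_1(e2e_scene: Scene):
    detector = ReferenceDetector()
    return run_pipeline(downsample(e2e_scene.frames(), 25, 1), detector, fps=1)
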