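"""Track a known translation with sparse Lucas-Kanade flow.

Creates two views of one texture offset by an exact (3, -2) px shift,
selects Shi-Tomasi corners in a region of interest, tracks them, and
compares the mean recovered displacement with an exhaustive block-matching
search.  Both should land on the true shift; the flow estimate is subpixel.
"""

import numpy as np
from scipy import ndimage

from pentrack.detection import BoundingBox
from pentrack.flow import FlowParams, FlowStatus, lucas_kanade, shi_tomasi_features
from pentrack.flow_oracle import block_matching_shift

rng = np.random.default_rng(0)
fine = ndimage.gaussian_filter(rng.standard_normal((80, 80)), 1.5)
coarse = ndimage.gaussian_filter(rng.standard_normal((80, 80)), 6.0)
big = fine / fine.std() + 1.5 * coarse / coarse.std()
big = (big - big.min()) / (big.max() - big.min()) * 200 + 20

dx, dy = 3, -2
prev = big[8:72, 8:72]
next_ = big[8 - dy : 72 - dy, 8 - dx : 72 - dx]

params = FlowParams(pyramid_levels=2)
features = shi_tomasi_features(prev, BoundingBox(16, 16, 48, 48), params)
vectors = lucas_kanade(prev, next_, features, params)
tracked = [v for v in vectors if v.status is FlowStatus.TRACKED]

mean_dx = np.mean([v.dx for v in tracked])
mean_dy = np.mean([v.dy for v in tracked])
print(f"true shift:            ({dx}, {dy}) px")
print(f"flow estimate:         ({mean_dx:.3f}, {mean_dy:.3f}) px "
      f"from {len(tracked)}/{len(vectors)} tracked features")
print(f"block-matching oracle: {block_matching_shift(prev, next_, 5)} px")
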