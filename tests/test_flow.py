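"""Optical-flow correctness: scoring, selection, pyramid, tracking vs oracle."""

import numpy as np
import pytest

from pentrack.detection import BoundingBox
from pentrack.flow import (
    FlowParams,
    FlowStatus,
    FlowVector,
    FeaturePoint,
    build_pyramid,
    lucas_kanade,
    mean_displacement,
    shi_tomasi_features,
    structure_tensor_eigmin,
)
from pentrack.flow_oracle import block_matching_shift

from conftest import make_textured, translated_pair


class TestStructureTensor:
    def test_constant_image_scores_zero(self):
        score = structure_tensor_eigmin(np.full((32, 32), 7.0), 5)
        assert np.allclose(score, 0.0)

    def test_corner_outscores_both_edges(self):
        img = np.zeros((32, 32))
        img[:16, :16] = 100.0  # corner at (16, 16), edges along row/col 16
        score = structure_tensor_eigmin(img, 5)
        corner = score[16, 16]
        edge_h = score[16, 8]
        edge_v = score[8, 16]
        assert corner > edge_h and corner > edge_v

    def test_pure_ramp_is_aperture_blind(self):
        img = np.tile(np.arange(32, dtype=float), (32, 1))
        score = structure_tensor_eigmin(img, 5)
        assert np.all(score < 1e-9)


class TestShiTomasi:
    def test_featureless_roi_yields_empty(self):
        img = np.full((64, 64), 50.0)
        assert shi_tomasi_features(img, BoundingBox(8, 8, 56, 56)) == []

    def test_textured_roi_yields_spaced_features(self):
        img = make_textured(64, 64, np.random.default_rng(0))
        feats = shi_tomasi_features(img, BoundingBox(8, 8, 56, 56))
        assert len(feats) >= 5
        pts = np.array([(f.x, f.y) for f in feats])
        assert (pts[:, 0] >= 8).all() and (pts[:, 0] < 56).all()
        d2 = np.sum((pts[:, None] - pts[None]) ** 2, axis=-1)
        d2[np.diag_indices(len(pts))] = np.inf
        assert d2.min() >= 7.0**2

    def test_huge_min_distance_packs_single_feature(self):
        img = make_textured(64, 64, np.random.default_rng(1))
        roi = BoundingBox(8, 8, 56, 56)
        diag = np.hypot(roi.width, roi.height)
        feats = shi_tomasi_features(img, roi, FlowParams(min_distance=diag + 1))
        assert len(feats) <= 1

    def test_feature_budget_respected(self):
        img = make_textured(96, 96, np.random.default_rng(2))
        feats = shi_tomasi_features(
            img, BoundingBox(4, 4, 92, 92), FlowParams(max_features=9, min_distance=3)
        )
        assert len(feats) <= 9


class TestPyramid:
    def test_dims_halve_per_level(self):
        pyr = build_pyramid(np.zeros((64, 64)), 3)
        assert [p.shape for p in pyr] == [(64, 64), (32, 32), (16, 16)]

    def test_constant_image_stays_constant(self):
        pyr = build_pyramid(np.full((32, 32), 9.0), 3)
        assert all(np.allclose(p, 9.0) for p in pyr)

    def test_blur_preserves_mean_within_one_percent(self):
        img = make_textured(64, 64, np.random.default_rng(3))
        pyr = build_pyramid(img, 3)
        for level in pyr[1:]:
            assert level.mean() == pytest.approx(img.mean(), rel=0.01)

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            build_pyramid(np.zeros((3, 3)), 4)


class TestLucasKanade:
    def test_zero_motion_is_a_fixed_point(self):
        img = make_textured(64, 64, np.random.default_rng(4))
        feats = shi_tomasi_features(img, BoundingBox(16, 16, 48, 48), FlowParams(pyramid_levels=2))
        vecs = lucas_kanade(img, img, feats, FlowParams(pyramid_levels=2))
        assert vecs and all(v.status is FlowStatus.TRACKED for v in vecs)
        assert all(v.magnitude < 0.05 for v in vecs)

    @pytest.mark.parametrize("shift", [(3, -2), (-4, 1), (0, 4)])
    def test_small_shift_matches_block_matching_oracle(self, shift):
        rng = np.random.default_rng(sum(shift) + 17)
        prev, next_ = translated_pair(64, 64, shift, rng)
        params = FlowParams(pyramid_levels=2)
        feats = shi_tomasi_features(prev, BoundingBox(16, 16, 48, 48), params)
        vecs = lucas_kanade(prev, next_, feats, params)
        tracked = [v for v in vecs if v.status is FlowStatus.TRACKED]
        assert tracked
        ox, oy = block_matching_shift(prev, next_, 5)
        assert (ox, oy) == shift
        assert np.mean([v.dx for v in tracked]) == pytest.approx(ox, abs=0.5)
        assert np.mean([v.dy for v in tracked]) == pytest.approx(oy, abs=0.5)

    def test_large_shift_needs_and_uses_the_pyramid(self):
        rng = np.random.default_rng(99)
        prev, next_ = translated_pair(128, 128, (12, 0), rng, margin=16)
        params = FlowParams(pyramid_levels=3)
        feats = shi_tomasi_features(prev, BoundingBox(30, 30, 98, 98), params)
        vecs = lucas_kanade(prev, next_, feats, params)
        tracked = [v for v in vecs if v.status is FlowStatus.TRACKED]
        assert len(tracked) >= 5
        assert np.mean([v.dx for v in tracked]) == pytest.approx(12.0, abs=1.0)
        assert np.mean([v.dy for v in tracked]) == pytest.approx(0.0, abs=1.0)

    def test_translation_equivariance(self):
        """Shifting both frames equally leaves recovered flow unchanged."""
        rng = np.random.default_rng(7)
        big = make_textured(112, 112, rng)
        prev, next_ = big[8:104, 8:104], big[6:102, 5:101]  # motion (3, 2)
        params = FlowParams(pyramid_levels=2)
        feats = shi_tomasi_features(prev, BoundingBox(30, 30, 66, 66), params)
        base = lucas_kanade(prev, next_, feats, params)
        shifted_feats = [FeaturePoint(f.x + 4, f.y + 4, f.score) for f in feats]
        shifted = lucas_kanade(
            np.roll(prev, (4, 4), (0, 1)), np.roll(next_, (4, 4), (0, 1)),
            shifted_feats, params,
        )
        for a, b in zip(base, shifted):
            if a.status is FlowStatus.TRACKED and b.status is FlowStatus.TRACKED:
                assert (a.dx, a.dy) == pytest.approx((b.dx, b.dy), abs=0.1)

    def test_reverse_tracking_negates_displacement(self):
        rng = np.random.default_rng(8)
        prev, next_ = translated_pair(96, 96, (3, -2), rng)
        params = FlowParams(pyramid_levels=2)
        f_fwd = shi_tomasi_features(prev, BoundingBox(24, 24, 72, 72), params)
        fwd = lucas_kanade(prev, next_, f_fwd, params)
        f_bwd = shi_tomasi_features(next_, BoundingBox(24, 24, 72, 72), params)
        bwd = lucas_kanade(next_, prev, f_bwd, params)
        mean_fwd = np.mean([[v.dx, v.dy] for v in fwd if v.status is FlowStatus.TRACKED], axis=0)
        mean_bwd = np.mean([[v.dx, v.dy] for v in bwd if v.status is FlowStatus.TRACKED], axis=0)
        assert mean_fwd[0] == pytest.approx(-mean_bwd[0], abs=0.5)
        assert mean_fwd[1] == pytest.approx(-mean_bwd[1], abs=0.5)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            lucas_kanade(
                np.zeros((32, 32)), np.zeros((32, 16)),
                [FeaturePoint(8.0, 8.0, 1.0)],
            )


class TestMeanDisplacement:
    @staticmethod
    def _vec(dx, dy, status=FlowStatus.TRACKED):
        return FlowVector(FeaturePoint(0, 0, 1.0), dx, dy, status, 0.0)

    def test_all_lost_reports_zero_with_no_support(self):
        vecs = [self._vec(3, 4, FlowStatus.LOST)]
        assert mean_displacement(vecs) == (0.0, 0)

    def test_mean_of_magnitudes(self):
        vecs = [self._vec(3, 4), self._vec(0, 0)]
        value, n = mean_displacement(vecs)
        assert (value, n) == (2.5, 2)

    def test_lost_vectors_excluded_from_the_mean(self):
        vecs = [self._vec(3, 4), self._vec(100, 0, FlowStatus.LOST)]
        assert mean_displacement(vecs) == (5.0, 1)
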