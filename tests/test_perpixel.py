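"""Per-pixel similarity mapping: formula, gate, sliding oracle, masks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from backmatch import (
    make_fractal_texture,
    mean_gate,
    ra_stats,
    similarity,
    sliding_map,
    threshold_overlay,
)
from backmatch.errors import BoundsError, UndefinedReferenceError
from backmatch.perpixel import GateResult
from backmatch.regions import Region, RegionSet


class TestSimilarity:
    @pytest.mark.parametrize(
        "ref,win,expected",
        [
            (-2.0, -2.0, 1.0),
            (10.0, 9.0, 0.90),
            (-2.0, -4.5, 0.0),  # clamped
            (4.0, 5.0, 0.75),
            (-3.0, 3.0, 0.0),
        ],
    )
    def test_reference_values(self, ref, win, expected):
        assert similarity(ref, win) == pytest.approx(expected)

    def test_zero_reference_undefined(self):
        with pytest.raises(UndefinedReferenceError):
            similarity(0.0, 1.0)

    @given(st.floats(-50, 50).filter(lambda v: abs(v) > 1e-6),
           st.floats(-50, 50))
    @settings(max_examples=50, deadline=None)
    def test_bounded_and_equal_iff_one(self, ref, win):
        s = similarity(ref, win)
        assert 0.0 <= s <= 1.0
        if win == ref:
            assert s == 1.0


class TestMeanGate:
    def test_self_window_passes(self, beta2_texture):
        stats = ra_stats(beta2_texture, (30, 30), 128)
        gate = mean_gate(stats, stats)
        assert gate.passed and gate.mean_similarity == 1.0 and gate.mw_p == 1.0

    def test_tenfold_power_fails_mean_similarity(self, beta2_texture):
        ref = ra_stats(beta2_texture, (30, 30), 128)
        scaled = ra_stats(beta2_texture * np.sqrt(10.0), (30, 30), 128)
        # 10x power shifts ra_mean by one decade
        assert scaled.ra_mean == pytest.approx(ref.ra_mean + 1.0, abs=1e-9)
        gate = mean_gate(ref, scaled)
        assert gate.mean_similarity < 0.9
        assert not gate.passed

    def test_linear_domain_variant_is_stricter(self, beta2_texture):
        ref = ra_stats(beta2_texture, (30, 30), 128)
        other = ra_stats(beta2_texture, (40, 45), 128)
        log_sim = mean_gate(ref, other, mean_domain="log").mean_similarity
        lin_sim = mean_gate(ref, other, mean_domain="linear").mean_similarity
        assert lin_sim <= log_sim


def naive_sliding_map(scene, mantle_origin, side, threshold=0.9, alpha=0.05):
    """Independent oracle: recompute RAStats per window from the public
    primitives, gate and score, assign to the central pixel."""
    h, w = scene.shape
    hw = side // 2
    mantle = ra_stats(scene, mantle_origin, side, is_mantle=True,
                      min_mantle_side=side)
    slope_sim = np.full((h, w), np.nan)
    gate = np.zeros((h, w), dtype=bool)
    for cr in range(hw, h - hw):
        for cc in range(hw, w - hw):
            win = ra_stats(scene, (cr - hw, cc - hw), side)
            g = mean_gate(mantle, win, alpha=alpha, threshold=threshold)
            gate[cr, cc] = g.passed
            if g.passed:
                slope_sim[cr, cc] = similarity(mantle.slope, win.slope)
    return slope_sim, gate


class TestSlidingMap:
    def test_equals_naive_recompute_oracle(self):
        scene = make_fractal_texture(96, 96, 2.0, seed=3)
        m = sliding_map(scene, (20, 20), 32, stride=1, min_mantle_side=32)
        naive_sim, naive_gate = naive_sliding_map(scene, (20, 20), 32)
        np.testing.assert_array_equal(m.gate_mask, naive_gate)
        np.testing.assert_array_equal(np.isnan(m.slope_similarity),
                                      np.isnan(naive_sim))
        both = ~np.isnan(naive_sim)
        np.testing.assert_allclose(m.slope_similarity[both], naive_sim[both],
                                   rtol=0, atol=1e-12)

    def test_self_match_is_one_and_gated_in(self):
        scene = make_fractal_texture(96, 96, 2.0, seed=5)
        m = sliding_map(scene, (32, 32), 32, stride=1, min_mantle_side=32)
        center = (32 + 16, 32 + 16)
        assert m.gate_mask[center]
        assert m.slope_similarity[center] == 1.0

    def test_edge_exclusion_matches_half_window_formula(self):
        scene = make_fractal_texture(120, 100, 2.0, seed=1)
        m = sliding_map(scene, (10, 10), 32, stride=1, min_mantle_side=32)
        assert m.edge_mask.sum() == (120 - 2 * 16) * (100 - 2 * 16)
        # mean similarity computed exactly on the analyzable area
        assert np.isfinite(m.mean_similarity).sum() == m.edge_mask.sum()

    def test_uniform_scene_mostly_passes(self):
        # a homogeneous texture with the mantle sampled from it: nearly all
        # windows pass the gate with slope similarity >= 0.9 (the MW
        # sub-gate alone removes ~5% by construction)
        scene = make_fractal_texture(384, 384, 2.0, seed=2)
        m = sliding_map(scene, (100, 100), 150, stride=4)
        filled = m.filled()
        good = (filled >= 0.9) & m.analyzable
        assert good.sum() / m.analyzable.sum() >= 0.90

    def test_monotone_gating_in_threshold(self):
        scene = make_fractal_texture(96, 96, 2.0, seed=8)
        lo = sliding_map(scene, (20, 20), 32, threshold=0.85, min_mantle_side=32)
        hi = sliding_map(scene, (20, 20), 32, threshold=0.95, min_mantle_side=32)
        sel_lo = np.isfinite(lo.slope_similarity) & (lo.slope_similarity >= 0.85)
        sel_hi = np.isfinite(hi.slope_similarity) & (hi.slope_similarity >= 0.95)
        assert not np.any(sel_hi & ~sel_lo)

    def test_stride_fills_by_nearest_and_flags(self):
        scene = make_fractal_texture(96, 96, 2.0, seed=3)
        s1 = sliding_map(scene, (20, 20), 32, stride=1, min_mantle_side=32)
        s3 = sliding_map(scene, (20, 20), 32, stride=3, min_mantle_side=32)
        assert np.isfinite(s3.mean_similarity).sum() == s3.edge_mask.sum()
        # computed centers agree exactly with the stride-1 map
        centers = np.zeros_like(s3.interpolated)
        centers[16:80:3, 16:80:3] = True
        inter = s3.interpolated
        assert not inter[centers].any() and inter[s3.edge_mask & ~centers].all()
        np.testing.assert_allclose(
            s3.mean_similarity[centers], s1.mean_similarity[centers], atol=1e-12
        )

    def test_hidden_zone_removed_from_map(self):
        scene = make_fractal_texture(96, 96, 2.0, seed=3)
        hidden = RegionSet([Region("hidden_zone", rect=(40, 40, 20, 20))])
        m = sliding_map(scene, (20, 20), 32, hidden_rois=hidden,
                        min_mantle_side=32)
        assert not m.hidden_mask[45, 45]
        assert np.all(np.isnan(m.slope_similarity[40:60, 40:60]))

    def test_mantle_overlapping_border_rejected(self):
        scene = make_fractal_texture(96, 96, 2.0, seed=3)
        with pytest.raises(BoundsError):
            sliding_map(scene, (80, 80), 32, min_mantle_side=32)

    def test_bit_identical_reruns(self):
        scene = make_fractal_texture(96, 96, 2.0, seed=4)
        a = sliding_map(scene, (20, 20), 32, stride=2, min_mantle_side=32)
        b = sliding_map(scene, (20, 20), 32, stride=2, min_mantle_side=32)
        np.testing.assert_array_equal(a.slope_similarity, b.slope_similarity)
        np.testing.assert_array_equal(a.gate_mask, b.gate_mask)


class TestThresholdOverlay:
    def test_all_below_threshold_leaves_grayscale(self):
        scene = make_fractal_texture(96, 96, 2.0, seed=3)
        m = sliding_map(scene, (20, 20), 32, min_mantle_side=32)
        m.slope_similarity[:] = 0.5
        rgb = threshold_overlay(m, scene)
        gray = (scene - scene.min()) / (scene.max() - scene.min())
        np.testing.assert_allclose(rgb[..., 0], gray, atol=1e-12)
        np.testing.assert_allclose(rgb[..., 0], rgb[..., 1], atol=1e-12)

    def test_full_similarity_tints_analyzable_area(self):
        scene = make_fractal_texture(96, 96, 2.0, seed=3)
        m = sliding_map(scene, (20, 20), 32, min_mantle_side=32)
        m.slope_similarity[m.edge_mask] = 1.0
        rgb = threshold_overlay(m, scene)
        tinted = rgb[..., 0] != rgb[..., 1]
        assert tinted[m.edge_mask].all()
        assert not tinted[~m.edge_mask].any()

    def test_default_threshold_is_90_percent(self):
        scene = make_fractal_texture(96, 96, 2.0, seed=3)
        m = sliding_map(scene, (20, 20), 32, min_mantle_side=32)
        assert m.threshold == 0.90


def test_gate_result_reports_both_subconditions(beta2_texture):
    ref = ra_stats(beta2_texture, (30, 30), 128)
    win = ra_stats(beta2_texture, (60, 60), 128)
    gate = mean_gate(ref, win)
    assert isinstance(gate, GateResult)
    assert 0.0 <= gate.mean_similarity <= 1.0
    assert 0.0 <= gate.mw_p <= 1.0
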