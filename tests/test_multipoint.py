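"""Multi-point method: square sampling, rank tests vs independent references."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from backmatch import (
    compare_groups,
    kruskal_wallis,
    mann_whitney_u,
    regions_from_truth,
    sample_squares,
)
from backmatch.errors import ConfigError, RegionSizeError
from backmatch.regions import Region, RegionSet


class TestSampleSquares:
    def test_forced_single_position(self):
        mask = np.zeros((120, 120), dtype=bool)
        mask[10:110, 10:110] = True  # exactly one 100x100 position
        origins = sample_squares(mask, n=30, side=100, seed=1)
        assert origins.shape == (30, 2)
        assert np.all(origins == [10, 10])

    def test_reproducible_and_contained(self):
        mask = np.zeros((400, 400), dtype=bool)
        mask[50:350, 50:350] = True
        a = sample_squares(mask, n=30, side=100, seed=9)
        b = sample_squares(mask, n=30, side=100, seed=9)
        np.testing.assert_array_equal(a, b)
        for r, c in a:
            assert mask[r : r + 100, c : c + 100].all()

    def test_distinct_origins_when_room_allows(self):
        mask = np.zeros((400, 400), dtype=bool)
        mask[0:300, 0:300] = True
        origins = sample_squares(mask, n=30, side=100, seed=3)
        assert len({tuple(o) for o in origins}) == 30

    def test_too_small_region_raises_with_label(self):
        mask = np.zeros((120, 120), dtype=bool)
        mask[0:50, 0:50] = True
        with pytest.raises(RegionSizeError, match="octopus_mantle"):
            sample_squares(mask, n=5, side=100, label="octopus_mantle")

    def test_polygon_region_containment(self):
        # squares sampled inside a triangular region stay inside it
        reg = Region("general_substrate",
                     polygon=[[0, 0], [0, 299], [299, 0]])
        mask = reg.to_mask((300, 300))
        origins = sample_squares(mask, n=10, side=60, seed=4)
        for r, c in origins:
            assert mask[r : r + 60, c : c + 60].all()


class TestMannWhitney:
    def test_tiny_exact_case(self):
        res = mann_whitney_u([1, 2], [3, 4])
        assert res.U == 0
        assert res.p == pytest.approx(1 / 3)
        assert res.method == "exact"

    def test_exact_matches_full_enumeration(self):
        # enumerate all C(7,3) rank splits for a 3-vs-4 comparison
        x = [1.0, 5.0, 9.0]
        y = [2.0, 3.0, 7.0, 11.0]
        res = mann_whitney_u(x, y)
        pooled = np.array(x + y)
        u_obs = res.U
        us = []
        for idx in itertools.combinations(range(7), 3):
            ranks = sps.rankdata(pooled)
            u = ranks[list(idx)].sum() - 3 * 4 / 2.0
            us.append(u)
        us = np.array(us)
        p_enum = min(1.0, 2 * min((us <= u_obs).mean(), (us >= u_obs).mean()))
        assert res.p == pytest.approx(p_enum, abs=1e-12)

    def test_identical_samples_near_one(self, rng):
        x = rng.normal(size=30)
        res = mann_whitney_u(x, x.copy())
        assert res.U == pytest.approx(30 * 30 / 2)
        assert res.p > 0.9

    def test_degenerate_all_ties(self):
        res = mann_whitney_u([2.0, 2.0, 2.0], [2.0, 2.0])
        assert res.p == 1.0 and res.degenerate

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_agrees_with_scipy_reference(self, seed):
        r = np.random.default_rng(seed)
        n1, n2 = r.integers(5, 40, 2)
        x = r.normal(0, 1, n1)
        y = r.normal(r.uniform(-1, 1), 1, n2)
        if seed % 3 == 0:
            x, y = np.round(x, 1), np.round(y, 1)
        ours = mann_whitney_u(x, y)
        method = "exact" if ours.method == "exact" else "asymptotic"
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
        assert ours.p == pytest.approx(ref.pvalue, abs=1e-6)
        assert ours.U == pytest.approx(ref.statistic)

    def test_type_one_error_near_nominal(self):
        r = np.random.default_rng(77)
        rejections = sum(
            mann_whitney_u(r.normal(size=30), r.normal(size=30)).p < 0.05
            for _ in range(1000)
        )
        assert rejections / 1000 == pytest.approx(0.05, abs=0.02)


class TestKruskalWallis:
    def test_identical_groups_give_zero_h(self):
        res = kruskal_wallis([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert res.H == pytest.approx(0.0, abs=1e-12)

    def test_textbook_oracle_three_groups(self):
        # rank sums 6, 15, 24 of ranks 1..9:
        # H = 12/(9*10) * (36+225+576)/3 - 3*10 = 7.2
        res = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert res.H == pytest.approx(7.2)
        assert res.p == pytest.approx(sps.chi2.sf(7.2, 2))

    def test_all_observations_identical_degenerate(self):
        res = kruskal_wallis([[5.0, 5.0], [5.0], [5.0, 5.0]])
        assert res.H == 0.0 and res.p == 1.0 and res.degenerate

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_agrees_with_scipy_reference(self, seed):
        r = np.random.default_rng(seed)
        groups = [r.normal(r.uniform(-1, 1), 1, r.integers(5, 30))
                  for _ in range(r.integers(2, 5))]
        if seed % 4 == 0:
            groups = [np.round(g, 1) for g in groups]
        ours = kruskal_wallis(groups)
        ref = sps.kruskal(*groups)
        assert ours.H == pytest.approx(ref.statistic, abs=1e-9)
        assert ours.p == pytest.approx(ref.pvalue, abs=1e-6)

    def test_type_one_error_near_nominal(self):
        r = np.random.default_rng(88)
        rejections = sum(
            kruskal_wallis([r.normal(size=30) for _ in range(3)]).p < 0.05
            for _ in range(1000)
        )
        assert rejections / 1000 == pytest.approx(0.05, abs=0.02)


class TestCompareGroups:
    def test_exchangeable_null_keeps_nominal_level(self):
        # under the exchangeable null (group labels assigned at random to
        # slopes from one homogeneous texture) Kruskal-Wallis holds its
        # nominal level; clustered ROIs at separated sites do not form a
        # valid null because local slope realisations differ spatially
        from backmatch import make_fractal_texture, null_kw_rejection_rate, ra_stats

        scene = make_fractal_texture(420, 420, 2.0, seed=123)
        rng = np.random.default_rng(5)
        origins = rng.integers(0, 420 - 100, size=(400, 2))
        pool = np.array([ra_stats(scene, tuple(o), 100).slope for o in origins])
        rate = null_kw_rejection_rate(pool, n_reps=300, seed=9)
        assert rate == pytest.approx(0.05, abs=0.04)

    def test_ninety_squares_and_group_shapes(self, reference_scene):
        _, truth, gray = reference_scene
        rois = regions_from_truth(truth, object_labels=(1,))
        comp = compare_groups(gray, rois, seed=0)
        assert sum(len(v) for v in comp.group_slopes.values()) == 90
        assert comp.n_samples == 30 and comp.sample_side == 100
        for lab in ("octopus_mantle", "distinct_object", "general_substrate"):
            assert len(comp.group_slopes[lab]) == 30
            assert comp.group_sd[lab] >= 0
        assert 0 <= comp.kw_p <= 1
        assert comp.conclusions  # structured conclusion strings present

    def test_missing_label_raises(self, beta2_texture):
        rois = RegionSet([Region("octopus_mantle", rect=(0, 0, 150, 150))])
        with pytest.raises(ConfigError, match="distinct_object"):
            compare_groups(beta2_texture, rois, seed=0)

    def test_small_mantle_region_raises(self, beta2_texture):
        rois = RegionSet([
            Region("octopus_mantle", rect=(0, 0, 80, 80)),
            Region("distinct_object", rect=(0, 100, 150, 150)),
            Region("general_substrate", rect=(100, 0, 150, 150)),
        ])
        with pytest.raises(RegionSizeError, match="octopus_mantle"):
            compare_groups(beta2_texture, rois, seed=0)


class TestRegionSetIO:
    def test_json_roundtrip_all_geometries(self, tmp_path):
        mask = np.zeros((50, 60), dtype=bool)
        mask[5:20, 10:30] = True
        rs = RegionSet(
            [
                Region("octopus_mantle", rect=(1, 2, 30, 40)),
                Region("hidden_zone", polygon=[[0, 0], [0, 10], [10, 0]]),
                Region("general_substrate", mask=mask),
            ],
            image_ref="scene.png",
        )
        rs.to_json(tmp_path / "roi.json")
        back = RegionSet.from_json(tmp_path / "roi.json")
        assert back.image_ref == "scene.png"
        for orig, load in zip(rs.regions, back.regions):
            assert orig.label == load.label
            np.testing.assert_array_equal(
                orig.to_mask((50, 60)), load.to_mask((50, 60))
            )

    def test_invalid_label_rejected(self):
        with pytest.raises(ConfigError):
            Region("not_a_label", rect=(0, 0, 10, 10))
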