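"""Synthetic scene generator and sensor sampler behaviour."""

import numpy as np
import numpy.testing as npt
import pytest

import canopyheight as ch
from canopyheight.scene import POST_HARVEST, PRE_HARVEST


class TestLayout:
    def test_study_geometry(self, study_layout):
        lay = study_layout
        assert lay.n_subplots == 25
        # subplot (0,0): 0.5 m square with a centered 0.3 m crop
        assert lay.crop_window(0) == pytest.approx((0.1, 0.1, 0.4, 0.4))
        # row-major enumeration without overlap
        origins = {lay.subplot_origin(i) for i in range(25)}
        assert len(origins) == 25
        assert lay.subplot_origin(1) == pytest.approx((0.5, 0.0))
        assert lay.subplot_origin(5) == pytest.approx((0.0, 0.5))

    def test_single_subplot_crop_equals_subplot(self):
        lay = ch.make_layout(1.0, 1, 1.0, 1.0)
        assert lay.n_subplots == 1
        assert lay.crop_window(0) == pytest.approx((0.0, 0.0, 1.0, 1.0))

    @pytest.mark.parametrize("args", [
        (-1.0, 5, 0.5, 0.3),      # negative plot
        (2.5, 5, 0.5, 0.6),       # crop larger than subplot
        (2.0, 5, 0.5, 0.3),       # grid does not fit
        (2.5, 0, 0.5, 0.3),       # no subplots
    ])
    def test_rejects_bad_geometry(self, args):
        with pytest.raises(ValueError):
            ch.make_layout(*args)

    def test_subplot_of_maps_points_row_major(self, study_layout):
        ids = study_layout.subplot_of(np.array([0.25, 0.75, 0.25]),
                                      np.array([0.25, 0.25, 0.75]))
        npt.assert_array_equal(ids, [0, 1, 5])


class TestGround:
    def test_zero_relief_is_flat(self, study_layout):
        g = ch.generate_ground(study_layout, 0.0, 0.5, seed=1)
        xs = np.linspace(0, 2.5, 40)
        npt.assert_array_equal(g.elevation(xs, xs), np.zeros(40))

    def test_deterministic_given_seed(self, study_layout):
        rng = np.random.default_rng(0)
        x, y = rng.uniform(0, 2.5, 100), rng.uniform(0, 2.5, 100)
        a = ch.generate_ground(study_layout, 0.01, 0.5, seed=7).elevation(x, y)
        b = ch.generate_ground(study_layout, 0.01, 0.5, seed=7).elevation(x, y)
        npt.assert_array_equal(a, b)

    def test_empirical_sd_matches_parameter(self, study_layout):
        g = ch.generate_ground(study_layout, 0.01, 0.5, seed=3)
        rng = np.random.default_rng(1)
        z = g.elevation(rng.uniform(0, 2.5, 10_000), rng.uniform(0, 2.5, 10_000))
        assert abs(z.std() - 0.01) < 0.002  # within 20 %
        assert abs(z.mean()) < 0.005
        assert np.all(np.abs(z) <= 4 * 0.01 + 1e-12)  # "almost flat" bound

    def test_rejects_negative_relief(self, study_layout):
        with pytest.raises(ValueError):
            ch.generate_ground(study_layout, -0.01, 0.5, seed=0)


class TestCanopy:
    def test_zero_cv_gives_exact_heights(self, flat_constant_scene):
        npt.assert_array_equal(flat_constant_scene.tip_height,
                               np.full(flat_constant_scene.n_blades, 0.4))
        # default leaf width is the 10 mm of the target sward
        npt.assert_array_equal(flat_constant_scene.width,
                               np.full(flat_constant_scene.n_blades, 0.010))

    def test_mean_tip_height_matches_parameter(self):
        lay = ch.make_layout(1.0, 1, 1.0, 1.0)
        ground = ch.generate_ground(lay, 0.0, 0.5, seed=0)
        scene = ch.generate_canopy(ground, lay, [400.0], height_cv=0.1,
                                   blades_per_m2=10_000, seed=2)
        assert scene.n_blades == 10_000
        assert abs(scene.tip_height.mean() * 1000 - 400.0) < 8.0  # within 2 %

    def test_blades_stay_inside_their_subplot(self, study_layout):
        ground = ch.generate_ground(study_layout, 0.0, 0.5, seed=0)
        scene = ch.generate_canopy(ground, study_layout, [400.0] * 25, 0.05,
                                   blades_per_m2=200, seed=3)
        expected = study_layout.subplot_of(scene.base_xy[:, 0], scene.base_xy[:, 1])
        npt.assert_array_equal(scene.subplot_idx, expected)

    def test_rejects_height_list_mismatch(self, study_layout):
        ground = ch.generate_ground(study_layout, 0.0, 0.5, seed=0)
        with pytest.raises(ValueError):
            ch.generate_canopy(ground, study_layout, [400.0] * 24, 0.1, 100, seed=0)


class TestHarvest:
    def test_cuts_to_stubble_and_conserves_blades(self, flat_constant_scene):
        post = ch.harvest(flat_constant_scene, 0.03)
        assert post.state == POST_HARVEST
        npt.assert_array_equal(post.tip_height, np.full(post.n_blades, 0.03))
        assert post.n_blades == flat_constant_scene.n_blades
        npt.assert_array_equal(post.base_xy, flat_constant_scene.base_xy)
        # a 0.40 m sward cut to 3 cm loses 0.37 m at the tallest tip
        assert flat_constant_scene.tip_height.max() - post.tip_height.max() \
            == pytest.approx(0.37)
        # the input scene is untouched
        assert flat_constant_scene.state == PRE_HARVEST

    def test_rejects_double_harvest(self, flat_constant_scene):
        post = ch.harvest(flat_constant_scene, 0.03)
        with pytest.raises(ValueError, match="already harvested"):
            ch.harvest(post, 0.02)

    def test_rejects_stubble_taller_than_sward(self, flat_constant_scene):
        with pytest.raises(ValueError, match="not below"):
            ch.harvest(flat_constant_scene, 0.5)


class TestRulerTruth:
    def test_constant_field_measured_exactly(self, flat_constant_scene):
        truth = ch.ruler_truth(flat_constant_scene, seed=0)
        assert truth.n_probes == 5  # protocol default: 5 probes per subplot
        npt.assert_allclose(truth.heights_mm, 400.0)

    def test_exhaustive_probing_equals_subplot_mean(self):
        lay = ch.make_layout(1.0, 2, 0.5, 0.3)
        ground = ch.generate_ground(lay, 0.0, 0.5, seed=0)
        scene = ch.generate_canopy(ground, lay, [300, 350, 400, 450], 0.1,
                                   blades_per_m2=400, seed=4)
        n_blades = int(np.sum(scene.subplot_idx == 0))
        truth = ch.ruler_truth(scene, n_probes=n_blades, seed=1)
        expected = [scene.tip_height[scene.subplot_idx == i].mean() * 1000
                    for i in range(4)]
        npt.assert_allclose(truth.heights_mm, expected, rtol=1e-12)

    def test_fewer_blades_than_probes_warns(self):
        lay = ch.make_layout(1.0, 1, 1.0, 1.0)
        ground = ch.generate_ground(lay, 0.0, 0.5, seed=0)
        scene = ch.generate_canopy(ground, lay, [400.0], 0.0, blades_per_m2=3, seed=0)
        truth = ch.ruler_truth(scene, n_probes=5, seed=0)
        npt.assert_allclose(truth.heights_mm, 400.0)


class TestSfMSampler:
    def test_point_count_matches_density(self, flat_constant_scene):
        s = ch.uav_sfm_sensor(seed=0, scale=0.01)
        cloud = ch.sample_sfm(flat_constant_scene, s)
        area_cm2 = flat_constant_scene.layout.area_m2 * 1e4
        expected = 789.0 * 0.01 * area_cm2
        assert abs(len(cloud) - expected) <= 0.01 * expected
        assert abs(ch.point_density(cloud, area_cm2) - 789.0 * 0.01) < 0.01 * 789 * 0.01

    def test_noiseless_envelope(self, flat_constant_scene):
        s = ch.SensorModel(kind="sfm", name="s", density=50.0, scale=1.0,
                           vertical_jitter_sd=0.0, point_noise_sd=0.0,
                           ground_visible_fraction=0.0, seed=1)
        cloud = ch.sample_sfm(flat_constant_scene, s)
        npt.assert_allclose(cloud.z, 0.4, atol=1e-12)

    def test_full_ground_visibility_returns_ground(self, flat_constant_scene):
        s = ch.SensorModel(kind="sfm", name="s", density=50.0, scale=1.0,
                           vertical_jitter_sd=0.0, point_noise_sd=0.0,
                           ground_visible_fraction=1.0, seed=1)
        cloud = ch.sample_sfm(flat_constant_scene, s)
        npt.assert_allclose(cloud.z, 0.0, atol=1e-12)

    def test_rejects_lidar_sensor(self, flat_constant_scene):
        with pytest.raises(ValueError, match="sfm"):
            ch.sample_sfm(flat_constant_scene, ch.lidar_sensor())


class TestLidarSampler:
    def test_bare_scene_returns_flat_ground(self):
        lay = ch.make_layout(1.0, 1, 1.0, 1.0)
        ground = ch.generate_ground(lay, 0.0, 0.5, seed=0)
        scene = ch.CanopyScene(ground=ground, layout=lay,
                               base_xy=np.empty((0, 2)), tip_height=np.empty(0),
                               width=np.empty(0), azimuth=np.empty(0),
                               subplot_idx=np.empty(0, dtype=np.int64))
        s = ch.lidar_sensor(seed=0, scale=1.0, vertical_jitter_sd=0.0,
                            point_noise_sd=0.0, ground_noise_sd=0.0)
        cloud = ch.sample_lidar(scene, s)
        assert len(cloud) == int(round(9 * lay.area_m2 * 1e4))
        npt.assert_array_equal(cloud.z, np.zeros(len(cloud)))

    def test_point_count_matches_density(self, study_layout):
        ground = ch.generate_ground(study_layout, 0.0, 0.5, seed=0)
        scene = ch.generate_canopy(ground, study_layout, [400.0] * 25, 0.0,
                                   blades_per_m2=100, seed=0)
        cloud = ch.sample_lidar(scene, ch.lidar_sensor(seed=0, scale=1.0))
        # 9 pts/cm^2 over 6.25 m^2 -> 562,500 points, within 1 %
        assert abs(len(cloud) - 562_500) <= 5625

    def test_cover_override_controls_ground_fraction(self, flat_constant_scene):
        # binomial expectation: cover 0.5 -> half the beams reach the ground
        s = ch.lidar_sensor(seed=5, scale=1.0, cover_override=0.5,
                            vertical_jitter_sd=0.0, point_noise_sd=0.0,
                            ground_noise_sd=0.0, footprint_xy=(0.0, 0.0),
                            density=10.0)  # 1e5 beams over the 1 m^2 scene
        cloud = ch.sample_lidar(flat_constant_scene, s)
        assert len(cloud) == 100_000
        ground_frac = float((cloud.z < 0.2).mean())
        assert abs(ground_frac - 0.5) < 0.01

    def test_postharvest_penetration_reaches_ground(self, flat_constant_scene):
        post = ch.harvest(flat_constant_scene, 0.03)
        cloud = ch.sample_lidar(post, ch.lidar_sensor(seed=2, scale=1.0))
        below_stubble = float((cloud.z < 0.028).mean())
        assert below_stubble > 0.2  # gaps between stubble leaves expose ground

    def test_rejects_sfm_sensor(self, flat_constant_scene):
        with pytest.raises(ValueError, match="lidar"):
            ch.sample_lidar(flat_constant_scene, ch.uav_sfm_sensor())


class TestDeterminism:
    @pytest.mark.parametrize("factory", [ch.uav_sfm_sensor, ch.lidar_sensor])
    def test_same_seed_bit_identical_clouds(self, flat_constant_scene, factory):
        a = ch.sample_cloud(flat_constant_scene, factory(seed=9, scale=0.05))
        b = ch.sample_cloud(flat_constant_scene, factory(seed=9, scale=0.05))
        npt.assert_array_equal(a.xyz, b.xyz)

    def test_epochs_use_distinct_streams(self, flat_constant_scene):
        post = ch.harvest(flat_constant_scene, 0.03)
        s = ch.lidar_sensor(seed=9, scale=0.05)
        pre_cloud = ch.sample_cloud(flat_constant_scene, s)
        post_cloud = ch.sample_cloud(post, s)
        assert not np.array_equal(pre_cloud.xyz[:, :2], post_cloud.xyz[:, :2])
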