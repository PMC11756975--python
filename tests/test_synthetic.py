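"""Synthetic scene generator: determinism, geometric contracts, oracles."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from conftest import quick_scene_params
from quadvol.synthetic import (AllometryModel, SceneParams, TRUE_GROUND,
                               TRUE_LITTER, TRUE_STEM, draw_biomass,
                               generate_scene, sample_cloud,
                               true_vegetation_volume)


class TestGenerateScene:
    def test_same_seed_identical_scene_and_cloud(self):
        p = quick_scene_params(seed=21)
        a, b = generate_scene(p), generate_scene(p)
        assert np.array_equal(a.litter_mask, b.litter_mask)
        assert np.array_equal(a.stem_base, b.stem_base)
        ca, cb = sample_cloud(a), sample_cloud(b)
        assert np.array_equal(ca.cloud.coords, cb.cloud.coords)
        assert np.array_equal(ca.true_labels, cb.true_labels)

    def test_litter_cover_within_two_percent(self):
        for seed in (1, 2, 3):
            scene = generate_scene(SceneParams(seed=seed, litter_cover_fraction=0.6))
            assert 0.58 <= scene.litter_cover_measured <= 0.62

    def test_bare_scene_has_only_ground_points(self):
        scene = generate_scene(quick_scene_params(
            seed=22, stem_count=0, litter_cover_fraction=0.0))
        sampled = sample_cloud(scene)
        assert (sampled.true_labels == TRUE_GROUND).all()

    def test_stems_root_on_terrain(self):
        scene = generate_scene(quick_scene_params(seed=23))
        base = scene.stem_axis(0, np.array([0.0]))[0]
        assert np.isclose(base[2], scene.terrain_z(base[0], base[1]))

    def test_reference_ground_matches_analytic_terrain(self):
        scene = generate_scene(quick_scene_params(seed=24))
        grid = scene.reference_ground()
        cx, cy = grid.cell_centers()
        gx, gy = np.meshgrid(cx, cy, indexing="ij")
        assert np.abs(grid.z - scene.terrain_z(gx, gy)).max() < 1e-12


class TestSampleCloud:
    def test_minimum_spacing_contract(self):
        scene = generate_scene(quick_scene_params(seed=25))
        sampled = sample_cloud(scene)
        tree = cKDTree(sampled.cloud.coords)
        d, _ = tree.query(sampled.cloud.coords, k=2)
        assert d[:, 1].min() >= scene.params.min_spacing_m * (1 - 1e-9)

    def test_realized_density_on_bare_terrain(self):
        p = quick_scene_params(seed=26, stem_count=0, litter_cover_fraction=0.0)
        sampled = sample_cloud(generate_scene(p))
        realized = len(sampled.cloud) / 0.2
        assert abs(realized - p.point_density_per_m2) / p.point_density_per_m2 < 0.2

    def test_full_occlusion_leaves_no_ground_under_litter(self):
        p = quick_scene_params(seed=27, litter_cover_fraction=0.97,
                               occlusion_strength=1.0)
        scene = generate_scene(p)
        sampled = sample_cloud(scene)
        ground = sampled.true_labels == TRUE_GROUND
        under = scene.litter_at(sampled.cloud.coords[:, :2])
        assert not (ground & under).any()

    def test_too_sparse_scene_rejected(self):
        with pytest.raises(ValueError, match="sparse"):
            sample_cloud(generate_scene(quick_scene_params(
                seed=28, point_density_per_m2=100.0)))

    def test_litter_points_sit_above_terrain(self):
        scene = generate_scene(quick_scene_params(seed=29))
        sampled = sample_cloud(scene)
        lit = sampled.true_labels == TRUE_LITTER
        xyz = sampled.cloud.coords[lit]
        dz = xyz[:, 2] - scene.terrain_z(xyz[:, 0], xyz[:, 1])
        assert dz.min() > 0.01  # thickness minus roughness tail


class TestTrueVegetationVolume:
    def test_single_cylinder_against_rasterization_oracle(self):
        scene = generate_scene(SceneParams(seed=30, stem_count=1,
                                           litter_cover_fraction=0.0))
        # force a straight vertical stem with known geometry
        scene.stem_base[0] = [0.2, 0.25]
        scene.stem_height[0] = 0.10
        scene.stem_radius[0] = 0.002
        scene.stem_lean[0] = 0.0
        scene.stem_bow[0] = 0.0
        edge = 0.005
        ours = true_vegetation_volume(scene, edge)
        # independent fine rasterization of the cylinder surface
        z0 = float(scene.terrain_z(0.2, 0.25))
        origin_z = float(scene.reference_ground().z.min())
        occupied = set()
        for z in np.arange(z0, z0 + 0.10, edge / 20):
            for theta in np.arange(0, 2 * np.pi, 0.02):
                x = 0.2 + 0.002 * np.cos(theta)
                y = 0.25 + 0.002 * np.sin(theta)
                occupied.add((int(np.floor(x / edge)), int(np.floor(y / edge)),
                              int(np.floor((z - origin_z) / edge))))
        oracle = len(occupied) * edge**3
        assert abs(ours - oracle) / oracle < 0.05

    def test_empty_scene_zero(self):
        scene = generate_scene(SceneParams(seed=31, stem_count=0,
                                           litter_cover_fraction=0.0))
        assert true_vegetation_volume(scene, 0.005) == 0.0

    def test_nondecreasing_under_edge_doubling(self):
        scene = generate_scene(quick_scene_params(seed=32))
        v1 = true_vegetation_volume(scene, 0.005)
        v2 = true_vegetation_volume(scene, 0.01)
        assert v2 >= v1 > 0


class TestDrawBiomass:
    def test_noise_free_draw_is_exact_power_law(self):
        model = AllometryModel(noise_sd_log=0.0, exponent=1.4)
        rec = draw_biomass(model.reference_volume_m3 * 2, model, seed=0)
        assert np.isclose(rec.total, model.coefficient_g * 2**1.4)

    def test_component_split_arithmetic(self):
        model = AllometryModel(noise_sd_log=0.0, litter_fraction_of_total=0.6)
        rec = draw_biomass(model.reference_volume_m3 * (1000 / 800), model, seed=0)
        assert np.isclose(rec.total, 1000)
        assert np.isclose(rec.litter_g, 600)
        assert np.isclose(rec.vegetation_total, 400)

    def test_cohort_mean_near_study_scale(self, rng):
        """288 draws with volumes spread around the reference land within a
        factor of two of the ~894 g cohort mean the generator emulates."""
        model = AllometryModel()
        volumes = model.reference_volume_m3 * np.exp(rng.normal(0, 1.0, 288))
        totals = [draw_biomass(v, model, seed=i).total
                  for i, v in enumerate(volumes)]
        assert 894 / 2 <= np.mean(totals) <= 894 * 2

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            draw_biomass(0.0, AllometryModel(), seed=0)
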