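"""LV models, signed distances, rigid motion, seeding, valve interpolation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lvflow.geometry import (
    DistanceMap,
    RigidTransform,
    ValvePlane,
    apply_rigid_transform,
    build_lv_model,
    seed_positions,
    static_valve_plane,
)


def cube_mask(n_grid, lo, hi):
    m = np.zeros((n_grid,) * 3, bool)
    m[lo:hi, lo:hi, lo:hi] = True
    return m


def brute_force_signed_distance(mask, spacing, point):
    """Distance to the nearest centre of an opposite-label voxel, shifted
    half a voxel toward the boundary (independent oracle)."""
    idx = np.indices(mask.shape).reshape(3, -1).T * spacing
    p = np.asarray(point, float)
    d_all = np.linalg.norm(idx - p, axis=1)
    i = int(np.clip(np.round(p[0] / spacing), 0, mask.shape[0] - 1))
    j = int(np.clip(np.round(p[1] / spacing), 0, mask.shape[1] - 1))
    k = int(np.clip(np.round(p[2] / spacing), 0, mask.shape[2] - 1))
    inside = mask[i, j, k]
    opposite = ~mask if inside else mask
    d = d_all[opposite.ravel()].min()
    return (-d if inside else d) + (0.5 * spacing if inside else -0.5 * spacing)


class TestLVModel:
    def test_volume_from_voxel_count(self):
        mask = np.zeros((10, 10, 10), bool)
        mask.ravel()[:1000] = True
        m = build_lv_model(mask, mask, [1, 1, 1], [0, 0, 0])
        assert m.edv == pytest.approx(1.0)

    def test_solid_cube_2mm(self):
        mask = cube_mask(14, 2, 12)  # 10^3 voxels
        m = build_lv_model(mask, mask, [2, 2, 2], [0, 0, 0])
        assert m.edv == pytest.approx(8.0)  # 1000 * 8 mm^3

    def test_empty_es_mask_warns(self):
        mask = cube_mask(6, 1, 5)
        with pytest.warns(UserWarning, match="end-systolic"):
            m = build_lv_model(mask, np.zeros_like(mask), [1, 1, 1], [0, 0, 0])
        assert m.esv == 0.0

    def test_empty_ed_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_lv_model(np.zeros((4, 4, 4), bool), np.zeros((4, 4, 4), bool),
                           [1, 1, 1], [0, 0, 0])


class TestSignedDistance:
    def test_cube_centre(self):
        mask = cube_mask(15, 2, 13)  # 11^3 cube, surface planes at 1.5 / 12.5
        dm = DistanceMap(mask, [1, 1, 1], [0, 0, 0])
        d = dm.at(np.array([[7.0, 7.0, 7.0]]))[0]
        assert d == pytest.approx(-5.0, abs=0.5)

    def test_outside_flat_face(self):
        mask = cube_mask(20, 2, 13)
        dm = DistanceMap(mask, [1, 1, 1], [0, 0, 0])
        # surface at z = 12.5; query 3 mm beyond
        d = dm.at(np.array([[7.0, 7.0, 15.5]]))[0]
        assert d == pytest.approx(3.0, abs=0.75)

    def test_on_surface(self):
        mask = cube_mask(15, 2, 13)
        dm = DistanceMap(mask, [1, 1, 1], [0, 0, 0])
        d = dm.at(np.array([[7.0, 7.0, 12.5]]))[0]
        assert abs(d) <= 0.5

    def test_outside_grid_is_infinite(self):
        mask = cube_mask(6, 1, 5)
        dm = DistanceMap(mask, [1, 1, 1], [0, 0, 0])
        assert np.isinf(dm.at(np.array([[50.0, 0.0, 0.0]]))[0])

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_brute_force_on_random_blobs(self, seed):
        rng = np.random.default_rng(seed)
        from scipy.ndimage import binary_dilation

        mask = np.zeros((12, 12, 12), bool)
        mask[tuple(rng.integers(3, 9, 3))] = True
        for _ in range(rng.integers(1, 4)):
            mask = binary_dilation(mask)
        dm = DistanceMap(mask, [1, 1, 1], [0, 0, 0])
        p = rng.uniform(0, 11, 3)
        got = dm.at(p[None, :])[0]
        want = brute_force_signed_distance(mask, 1.0, p)
        assert got == pytest.approx(want, abs=0.75)


class TestRigidTransform:
    def test_identity_leaves_geometry_unchanged(self):
        t = RigidTransform(np.eye(3), np.zeros(3))
        pts = np.array([[1.0, 2.0, 3.0], [-1.0, 0.0, 4.0]])
        assert np.allclose(apply_rigid_transform(t, pts), pts)

    def test_translation_moves_plane_centre_not_normal(self):
        t = RigidTransform(np.eye(3), [5.0, 0.0, 0.0])
        v = static_valve_plane("mitral", [1.0, 2.0, 3.0], [0.0, 0.0, 1.0], 12.0,
                               np.array([0.0, 500.0]), 1000.0)
        v2 = apply_rigid_transform(t, v)
        assert np.allclose(v2.centres, v.centres + [5.0, 0.0, 0.0])
        assert np.allclose(v2.normals, v.normals)
        assert np.allclose(v2.radii, v.radii)

    def test_rotation_90deg_about_z(self):
        rot = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        t = RigidTransform(rot, np.zeros(3))
        got = apply_rigid_transform(t, np.array([[1.0, 0.0, 0.0]]))
        assert np.allclose(got, [[0.0, 1.0, 0.0]], atol=1e-12)

    def test_non_orthonormal_rejected(self):
        with pytest.raises(ValueError, match="orthonormal"):
            RigidTransform(np.eye(3) * 1.1, np.zeros(3))

    def test_reflection_rejected(self):
        refl = np.diag([-1.0, 1.0, 1.0])
        with pytest.raises(ValueError, match="determinant"):
            RigidTransform(refl, np.zeros(3))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_pairwise_distances_preserved(self, seed):
        rng = np.random.default_rng(seed)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = rng.uniform(0, 2 * np.pi)
        K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
        rot = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * K @ K
        t = RigidTransform(rot, rng.normal(0, 10, 3))
        pts = rng.normal(0, 20, (8, 3))
        out = apply_rigid_transform(t, pts)
        d_in = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        d_out = np.linalg.norm(out[:, None] - out[None, :], axis=-1)
        assert np.allclose(d_in, d_out, atol=1e-6)

    def test_mask_resample_preserves_volume_roughly(self):
        mask = cube_mask(20, 5, 15)
        model = build_lv_model(mask, mask, [1, 1, 1], [0, 0, 0])
        rot = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        # rotate about the cube centre
        centre = np.full(3, 9.5)
        t = RigidTransform(rot, centre - rot @ centre)
        m2 = apply_rigid_transform(t, model)
        assert m2.edv == pytest.approx(model.edv, rel=0.05)
        assert m2.ed_mask.dtype == bool


class TestSeeding:
    def test_zero_margin_seeds_every_voxel(self):
        mask = cube_mask(8, 2, 6)
        model = build_lv_model(mask, mask, [1, 1, 1], [0, 0, 0])
        seeds = seed_positions(model, margin=0.0)
        assert seeds.shape[0] == mask.sum()

    def test_margin_matches_erosion_oracle(self):
        mask = cube_mask(26, 3, 23)  # 20^3 cube, 1 mm spacing
        model = build_lv_model(mask, mask, [1, 1, 1], [0, 0, 0])
        seeds = seed_positions(model, margin=2.5)
        # surface planes at 2.5 / 22.5; centres >= 2.5 mm inside: [5, 20]
        assert seeds.shape[0] == 16**3
        assert seeds[:, 0].min() == 5.0 and seeds[:, 0].max() == 20.0

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_count_matches_brute_force_on_random_masks(self, seed):
        rng = np.random.default_rng(seed)
        from scipy.ndimage import binary_closing, binary_dilation

        mask = np.zeros((14, 14, 14), bool)
        mask[tuple(rng.integers(4, 10, 3))] = True
        for _ in range(3):
            mask = binary_dilation(mask)
        mask = binary_closing(mask)
        model = build_lv_model(mask, mask, [1, 1, 1], [0, 0, 0])
        margin = 1.5
        dm = model.ed_distance()
        expected = int(np.count_nonzero(mask & (dm.grid <= -margin)))
        if expected == 0:
            with pytest.raises(ValueError, match="no seeds"):
                seed_positions(model, margin)
        else:
            assert seed_positions(model, margin).shape[0] == expected

    def test_excessive_margin_rejected(self):
        mask = cube_mask(8, 3, 6)
        model = build_lv_model(mask, mask, [1, 1, 1], [0, 0, 0])
        with pytest.raises(ValueError, match="no seeds"):
            seed_positions(model, margin=10.0)


class TestValvePlane:
    def test_static_plane_any_time(self):
        v = static_valve_plane("aortic", [1.0, 2.0, 3.0], [0.0, 1.0, 0.0], 10.0,
                               np.array([0.0, 300.0, 600.0]), 900.0)
        for t in (0.0, 123.4, 599.0, 899.9):
            p = v.at_time(t)
            assert np.allclose(p.centre, [1.0, 2.0, 3.0])
            assert p.radius == 10.0

    def test_linear_centre_midpoint(self):
        v = ValvePlane(
            label="mitral", phase_times=np.array([0.0, 400.0]),
            centres=np.array([[0.0, 0.0, 0.0], [10.0, 0.0, 0.0]]),
            normals=np.array([[0.0, 0.0, 1.0], [0.0, 0.0, 1.0]]),
            radii=np.array([10.0, 14.0]), cycle_length=800.0,
        )
        p = v.at_time(200.0)
        assert np.allclose(p.centre, [5.0, 0.0, 0.0])
        assert p.radius == pytest.approx(12.0)

    def test_interpolated_normal_unit_length(self):
        n0 = np.array([1.0, 0.0, 0.0])
        n1 = np.array([0.0, 1.0, 0.0])
        v = ValvePlane(
            label="mitral", phase_times=np.array([0.0, 400.0]),
            centres=np.zeros((2, 3)), normals=np.stack([n0, n1]),
            radii=np.array([10.0, 10.0]), cycle_length=800.0,
        )
        for t in np.linspace(0, 799, 13):
            assert np.linalg.norm(v.at_time(t).normal) == pytest.approx(1.0, abs=1e-9)
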