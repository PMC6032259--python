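"""Maximal-sphere pore profiling against analytic and grid-search oracles."""

import numpy as np
import pytest

from aquadefect.geometry import rotation_about_axis
from aquadefect.pore_profiler import (PoreAxis, ProfilerParams,
                                      compare_profiles, compute_profile,
                                      estimate_axis, max_sphere_in_slice)
from aquadefect.mutator import MutationSpec, mutate_residue
from aquadefect.synthetic import make_bundle_channel

from conftest import single_atom_structure

PARAMS = ProfilerParams(seed=11)


def ring_structure(n=8, ring_radius=5.0, z=0.0, vdw=1.7):
    angles = 2 * np.pi * np.arange(n) / n
    coords = np.column_stack([ring_radius * np.cos(angles),
                              ring_radius * np.sin(angles),
                              np.full(n, z)])
    return single_atom_structure(coords, vdw=vdw)


def default_axis(z_min=-5.0, z_max=5.0):
    return PoreAxis(origin=np.zeros(3), direction=[0.0, 0.0, 1.0],
                    z_min=z_min, z_max=z_max)


class TestMaxSphereInSlice:
    def test_symmetric_ring_forces_center_and_radius(self):
        st = ring_structure()
        coords, vdw, _ = st.flat_atoms()
        center, radius, open_flag = max_sphere_in_slice(
            coords, vdw, default_axis(), 0.0, PARAMS)
        assert not open_flag
        assert radius == pytest.approx(5.0 - 1.7, abs=1e-3)
        assert np.linalg.norm(center[:2]) < 1e-2

    def test_empty_slice_is_open_at_start_center(self):
        st = ring_structure(z=0.0)
        coords, vdw, _ = st.flat_atoms()
        start = np.array([0.3, -0.2, 0.0])
        center, radius, open_flag = max_sphere_in_slice(
            coords, vdw, default_axis(), 50.0, PARAMS, start_center=start)
        assert open_flag
        assert radius == PARAMS.r_max
        assert np.allclose(center[:2], start[:2])

    def test_irregular_enclosing_slice_matches_grid_search(self):
        # irregular pentagon of wall atoms enclosing the slice origin
        angles = np.radians([0, 65, 150, 210, 290])
        radii = np.array([4.0, 5.5, 4.5, 6.0, 5.0])
        pts = np.column_stack([radii * np.cos(angles), radii * np.sin(angles),
                               [0.0, 0.3, -0.2, 0.1, -0.4]])
        st = single_atom_structure(pts, vdw=1.6)
        coords, vdw, _ = st.flat_atoms()
        _, radius, open_flag = max_sphere_in_slice(coords, vdw, default_axis(),
                                                   0.0, PARAMS)
        # exhaustive 0.01 Å grid over the enclosed region
        g = np.arange(-4.0, 4.0, 0.01)
        gx, gy = np.meshgrid(g, g)
        grid_pts = np.column_stack([gx.ravel(), gy.ravel(),
                                    np.zeros(gx.size)])
        clear = np.min(
            np.linalg.norm(grid_pts[:, None, :] - pts[None, :, :], axis=2) - 1.6,
            axis=1)
        best = float(np.minimum(clear, PARAMS.r_max).max())
        assert not open_flag
        assert radius == pytest.approx(best, abs=0.05)

    def test_nonpositive_r_max_rejected(self):
        st = ring_structure()
        coords, vdw, _ = st.flat_atoms()
        with pytest.raises(ValueError):
            max_sphere_in_slice(coords, vdw, default_axis(), 0.0,
                                ProfilerParams(r_max=0.0))


class TestComputeProfile:
    def test_cylinder_matches_analytic_wall(self, cylinder_wall):
        st, truth = cylinder_wall
        axis = default_axis(-8.0, 8.0)
        profile = compute_profile(st, axis, PARAMS)
        interior = profile.interior()
        assert np.abs(profile.radius[interior] - 2.5).max() <= 0.15
        assert profile.radius[interior].var() < 0.05

    def test_cone_recovers_linear_profile(self, cone_wall):
        st, truth = cone_wall
        axis = default_axis(-8.0, 8.0)
        profile = compute_profile(st, axis, PARAMS)
        interior = profile.interior()
        expected = 2.5 + 0.1 * profile.z[interior]
        assert np.abs(profile.radius[interior] - expected).max() <= 0.15

    def test_radius_is_true_clearance_lower_bound(self, cylinder_wall):
        st, _ = cylinder_wall
        coords, vdw, _ = st.flat_atoms()
        profile = compute_profile(st, default_axis(-8, 8), PARAMS)
        for center, radius, open_flag in zip(profile.centers, profile.radius,
                                             profile.open_flag):
            if open_flag:
                continue
            clearance = float((np.linalg.norm(coords - center, axis=1) - vdw).min())
            assert clearance == pytest.approx(radius, abs=1e-6)

    def test_monotone_wall_vdw_shift(self, cylinder_wall):
        st, _ = cylinder_wall
        axis = default_axis(-8, 8)
        base = compute_profile(st, axis, PARAMS)
        fat = st.copy()
        delta = 0.2
        for r in fat.residues():
            for a in r.atoms:
                a.vdw += delta
        shifted = compute_profile(fat, axis, PARAMS)
        sel = base.interior() & shifted.interior()
        assert np.allclose(shifted.radius[sel], base.radius[sel] - delta,
                           atol=5e-3)

    def test_rigid_transform_invariance(self, cylinder_wall):
        st, _ = cylinder_wall
        axis = default_axis(-8, 8)
        base = compute_profile(st, axis, PARAMS)
        rot = rotation_about_axis([1.0, 2.0, 0.5], 37.0)
        trans = np.array([5.0, -3.0, 11.0])
        moved = st.copy()
        moved.transform(rot, trans)
        moved_axis = PoreAxis(origin=rot @ axis.origin + trans,
                              direction=rot @ axis.direction,
                              z_min=axis.z_min, z_max=axis.z_max)
        again = compute_profile(moved, moved_axis, PARAMS)
        assert np.allclose(again.radius, base.radius, atol=0.02)
        assert np.array_equal(again.open_flag, base.open_flag)

    def test_fixed_seed_reproducible(self, cylinder_wall):
        st, _ = cylinder_wall
        axis = default_axis(-8, 8)
        a = compute_profile(st, axis, PARAMS)
        b = compute_profile(st, axis, PARAMS)
        assert np.array_equal(a.radius, b.radius)
        assert np.array_equal(a.centers, b.centers)

    def test_no_channel_raises(self):
        st = ring_structure(ring_radius=40.0)
        with pytest.raises(ValueError, match="no channel"):
            compute_profile(st, default_axis(-2, 2), ProfilerParams(seed=1))


class TestEstimateAxis:
    def test_bundle_axis_along_z(self, bundle6):
        axis = estimate_axis(bundle6)
        angle = np.degrees(np.arccos(abs(axis.direction[2])))
        assert angle < 5.0

    def test_helix_axis_within_two_degrees(self, helix18):
        axis = estimate_axis(helix18)
        angle = np.degrees(np.arccos(abs(axis.direction[2])))
        assert angle < 2.0

    def test_spherical_cloud_is_degenerate(self, rng):
        st = single_atom_structure(rng.standard_normal((200, 3)) * 10)
        with pytest.raises(ValueError, match="degenerate"):
            estimate_axis(st)

    def test_too_few_atoms_rejected(self):
        st = ring_structure(n=8)
        with pytest.raises(ValueError, match="50"):
            estimate_axis(st)


class TestCompareProfiles:
    def test_identical_profiles_give_empty_delta(self, cylinder_wall):
        st, _ = cylinder_wall
        p = compute_profile(st, default_axis(-8, 8), PARAMS)
        delta = compare_profiles(p, p)
        assert delta.narrowing_regions == []
        assert np.allclose(delta.delta, 0.0)

    def test_planted_bulky_residue_narrows_at_its_height(self):
        wt = make_bundle_channel(6, 9.0, 18, facing_residue=(0, 9, "G"))
        axis = estimate_axis(wt)
        wt_p = compute_profile(wt, axis, PARAMS)
        mut = mutate_residue(wt, MutationSpec("A", 10, "G", "W"))
        mut_p = compute_profile(mut, axis, PARAMS)
        delta = compare_profiles(wt_p, mut_p, threshold=0.3, min_run=3)
        assert delta.narrowing_regions
        site_z = float(axis.to_frame(wt.residue("A", 10).atom("CA").xyz)[2])
        worst = max(delta.narrowing_regions, key=lambda r: r.max_reduction)
        assert worst.z_start - 6.0 <= site_z <= worst.z_end + 6.0

    def test_disjoint_ranges_error(self, cylinder_wall):
        st, _ = cylinder_wall
        a = compute_profile(st, default_axis(-8.0, -1.0), PARAMS)
        b = compute_profile(st, default_axis(1.0, 8.0), PARAMS)
        with pytest.raises(ValueError, match="disjoint"):
            compare_profiles(a, b)
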