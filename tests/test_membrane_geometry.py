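"""Alignment, patch extraction, circle fitting, curvature and displacement."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import pdist
from scipy.spatial.transform import Rotation

import barbend as bb
from barbend.errors import FitError


def _circle_points(radius, center, angles):
    return np.column_stack([center[0] + radius * np.cos(angles),
                            center[1] + radius * np.sin(angles)])


def _circumcircle(p1, p2, p3):
    """Brute-force 3-point circumcircle (perpendicular-bisector oracle)."""
    ax, ay = p1
    bx, by = p2
    cx, cy = p3
    d = 2 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    ux = ((ax**2 + ay**2) * (by - cy) + (bx**2 + by**2) * (cy - ay)
          + (cx**2 + cy**2) * (ay - by)) / d
    uy = ((ax**2 + ay**2) * (cx - bx) + (bx**2 + by**2) * (ax - cx)
          + (cx**2 + cy**2) * (bx - ax)) / d
    return np.hypot(ax - ux, ay - uy)


class TestAlignFrames:
    MEM = bb.Selection(atom_names=frozenset({"P"}))
    DIM = bb.Selection(atom_names=frozenset({"CA"}))

    def test_already_aligned_flat_fixture_is_identity(self, flat_bundle):
        aligned = bb.align_frames(flat_bundle, self.MEM, self.DIM)
        for a, b in zip(flat_bundle.frames, aligned.frames):
            np.testing.assert_allclose(a.coords, b.coords, atol=1e-6)

    def test_rotation_about_x_is_undone(self, flat_bundle):
        rot = Rotation.from_euler("x", 90, degrees=True)
        rotated = bb.Trajectory(
            topology=flat_bundle.topology,
            frames=[bb.Frame(f.time, rot.apply(f.coords))
                    for f in flat_bundle.frames])
        back = bb.align_frames(rotated, self.MEM, self.DIM)
        ref = bb.align_frames(flat_bundle, self.MEM, self.DIM)
        for a, b in zip(ref.frames, back.frames):
            np.testing.assert_allclose(a.coords, b.coords, atol=1e-6)

    def test_rigidity_of_internal_distances(self, flat_bundle):
        aligned = bb.align_frames(flat_bundle, self.MEM, self.DIM)
        sub = np.arange(0, flat_bundle.n_atoms, 31)
        before = pdist(flat_bundle.frames[0].coords[sub])
        after = pdist(aligned.frames[0].coords[sub])
        np.testing.assert_allclose(before, after, atol=1e-9)


class TestExtractPatch:
    def test_default_lattice_patch_count(self, flat_membrane):
        traj, _ = flat_membrane
        patch = bb.extract_patch(traj.frames[0], np.arange(traj.n_atoms),
                                 bb.FitRegion(anchor="absolute"))
        assert len(patch) == 42  # 21 x-columns x 2 y-rows at 8 Å spacing

    def test_region_larger_than_membrane_takes_all(self, flat_membrane):
        traj, _ = flat_membrane
        region = bb.FitRegion(length_x=1e4, width_y=1e4, anchor="absolute")
        patch = bb.extract_patch(traj.frames[0], np.arange(traj.n_atoms), region)
        assert len(patch) == traj.n_atoms

    def test_off_membrane_dimer_yields_empty_patch(self, flat_membrane):
        traj, _ = flat_membrane
        region = bb.FitRegion(anchor="absolute", absolute_origin=(1000.0, 0.0))
        patch = bb.extract_patch(traj.frames[0], np.arange(traj.n_atoms), region)
        assert len(patch) == 0  # caller flags the frame as fit-infeasible


class TestFitCircle:
    def test_exact_points_recover_radius(self):
        pts = _circle_points(500.0, (3.0, -7.0),
                             np.linspace(0.1, 0.5, 5))
        fit = bb.fit_circle(pts)
        assert fit.radius == pytest.approx(500.0, rel=1e-9)
        assert fit.curvature_nm == pytest.approx(0.02, rel=1e-9)

    def test_collinear_points_mean_flat(self):
        pts = np.column_stack([np.linspace(-50, 50, 9), np.zeros(9)])
        fit = bb.fit_circle(pts)
        assert fit.curvature_nm == 0.0 and np.isinf(fit.radius)
        assert fit.sign == +1

    def test_curvature_radius_reciprocity(self):
        """κ = 0.0581 nm⁻¹ corresponds to a 17.2 nm fitting circle."""
        radius_A = 1.0 / 0.0581 * 10.0  # nm -> Å
        pts = _circle_points(radius_A, (0.0, 0.0), np.linspace(0, 0.6, 12))
        fit = bb.fit_circle(pts)
        assert fit.curvature_nm == pytest.approx(0.0581, rel=1e-9)
        assert fit.radius_nm == pytest.approx(17.2, abs=0.05)

    def test_too_few_points_rejected(self):
        with pytest.raises(FitError):
            bb.fit_circle(np.array([[0.0, 0.0], [1.0, 1.0]]))

    def test_matches_triple_circumcircle_oracle(self):
        angles = np.linspace(0.2, 1.1, 8)
        pts = _circle_points(347.0, (12.0, 5.0), angles)
        fit = bb.fit_circle(pts)
        triples = [_circumcircle(pts[i], pts[j], pts[k])
                   for i, j, k in itertools.combinations(range(len(pts)), 3)]
        assert fit.radius == pytest.approx(np.median(triples), rel=1e-6)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(min_value=0, max_value=10**6))
    def test_rigid_motion_invariance(self, seed):
        rng = np.random.default_rng(seed)
        pts = _circle_points(200.0, (0.0, 0.0),
                             rng.uniform(0.0, 1.2, size=8))
        angle = rng.uniform(0, 2 * np.pi)
        c, s = np.cos(angle), np.sin(angle)
        moved = pts @ np.array([[c, -s], [s, c]]).T + rng.uniform(-50, 50, 2)
        k0 = bb.fit_circle(pts).curvature_nm
        k1 = bb.fit_circle(moved).curvature_nm
        assert k1 == pytest.approx(k0, abs=1e-9)


class TestCurvatureSeries:
    def test_noiseless_bend_recovers_exactly(self, bent_membrane_500):
        traj, _ = bent_membrane_500
        cs = bb.curvature_series(traj, region=bb.FitRegion(anchor="absolute"),
                                 window_fraction=1.0)
        assert cs.window_mean == pytest.approx(0.02, rel=1e-9)
        assert all(f.sign == +1 for f in cs.fits)

    def test_noisy_bend_within_tolerance(self):
        spec = bb.MembraneSpec(radius_series=[500.0] * 500, noise_sd=1.0,
                               seed=21)
        traj, _ = bb.generate_membrane_trajectory(spec)
        cs = bb.curvature_series(traj, region=bb.FitRegion(anchor="absolute"),
                                 window_fraction=1 / 3)
        assert abs(cs.window_mean - 0.02) < 0.002

    def test_flat_noisy_membrane_is_nearly_flat(self):
        spec = bb.MembraneSpec(radius_series=[np.inf] * 200, noise_sd=0.5,
                               seed=2)
        traj, _ = bb.generate_membrane_trajectory(spec)
        cs = bb.curvature_series(traj, region=bb.FitRegion(anchor="absolute"),
                                 window_fraction=1 / 3)
        assert cs.window_mean < 0.002

    def test_infeasible_frames_flagged_not_fatal(self, flat_membrane):
        traj, _ = flat_membrane
        region = bb.FitRegion(anchor="absolute", absolute_origin=(1000.0, 0.0))
        with pytest.raises(FitError, match="window"):
            bb.curvature_series(traj, region=region, window_fraction=1.0)


class TestHorizontalDisplacement:
    def test_z_is_ignored(self):
        topo = [bb.Atom(1, "CA", "C", "GLY", 69, "A"),
                bb.Atom(2, "CA", "C", "GLY", 69, "B"),
                bb.Atom(3, "P", "P", "POP", 1, "M")]
        frames = [bb.Frame(0.0, np.array([[0, 0, 0], [0, 0, 10],
                                          [80.0, 0, z]]))
                  for z in (0.0, 55.0)]
        traj = bb.Trajectory(topo, frames)
        df = bb.horizontal_displacement_series(traj)
        np.testing.assert_allclose(df["mean_distance_A"], [80.0, 80.0])

    def test_bending_contracts_distances(self):
        n = 6
        mem, _ = bb.generate_membrane_trajectory(
            bb.MembraneSpec(radius_series=np.linspace(2000, 500, n),
                            noise_sd=0.0))
        dim, _ = bb.generate_dimer_trajectory(
            bb.DimerSpec(arm_angle_series=np.zeros(n)))
        bundle = bb.place_dimer_on_membrane(mem, dim)
        df = bb.horizontal_displacement_series(bundle)
        v = df["mean_distance_A"].to_numpy()
        assert np.all(np.diff(v) <= 1e-9)

    def test_static_run_constant(self, flat_bundle):
        df = bb.horizontal_displacement_series(flat_bundle)
        assert np.ptp(df["mean_distance_A"]) < 1e-9


class TestParameterRecoveryGrid:
    @pytest.mark.parametrize("radius", [250.0, 500.0, 1000.0])
    @pytest.mark.parametrize("noise", [0.0, 0.5, 1.0])
    def test_window_mean_within_ten_percent(self, radius, noise):
        spec = bb.MembraneSpec(radius_series=[radius] * 150, noise_sd=noise,
                               seed=17)
        traj, _ = bb.generate_membrane_trajectory(spec)
        cs = bb.curvature_series(traj, region=bb.FitRegion(anchor="absolute"),
                                 window_fraction=1 / 3)
        true = 10.0 / radius
        if noise == 0.0:
            assert cs.window_mean == pytest.approx(true, rel=1e-6)
        else:
            assert cs.window_mean == pytest.approx(true, rel=0.10)
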