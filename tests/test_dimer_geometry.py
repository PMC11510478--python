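"""Segment axes, kink calling, angle/span series, correlations, RMSD/RMSF."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

import barbend as bb
from barbend.errors import ConfigurationError, ConstantSeriesError, FitError
from barbend.dimer import SegmentDef


def _rigidly_move(traj, seed=0):
    rng = np.random.default_rng(seed)
    rot = Rotation.from_rotvec(rng.normal(size=3))
    shift = rng.uniform(-40, 40, 3)
    frames = [bb.Frame(f.time, rot.apply(f.coords) + shift)
              for f in traj.frames]
    return bb.Trajectory(traj.topology, frames)


class TestSegmentAxis:
    def test_straight_helix_axis(self):
        helix = bb.generate_kinked_helix(1, 40)
        seg = SegmentDef("A", "helix", (1, 40))
        fit = bb.fit_segment_axis(helix.topology, helix.frames[0], seg)
        angle = np.degrees(np.arccos(abs(fit.direction @ [1.0, 0, 0])))
        assert angle < 1.0
        assert fit.direction[0] > 0  # oriented N -> C

    def test_three_collinear_points(self):
        topo = [bb.Atom(i + 1, "CA", "C", "ALA", i + 1, "A") for i in range(3)]
        fr = bb.Frame(0.0, np.array([[0, 0, 0], [1, 1, 1], [2, 2, 2]], float))
        fit = bb.fit_segment_axis(topo, fr, SegmentDef("A", "seg", (1, 3)))
        np.testing.assert_allclose(fit.direction, np.ones(3) / np.sqrt(3),
                                   atol=1e-12)
        assert fit.rms_perp == pytest.approx(0.0, abs=1e-12)

    def test_rotation_equivariance(self):
        helix = bb.generate_kinked_helix(1, 30)
        seg = SegmentDef("A", "helix", (1, 30))
        fit0 = bb.fit_segment_axis(helix.topology, helix.frames[0], seg)
        rot = Rotation.from_euler("zyx", [31, -12, 77], degrees=True)
        moved = bb.Frame(0.0, rot.apply(helix.frames[0].coords))
        fit1 = bb.fit_segment_axis(helix.topology, moved, seg)
        np.testing.assert_allclose(fit1.direction, rot.apply(fit0.direction),
                                   atol=1e-6)

    def test_unresolved_residues_reported(self, static_dimer):
        traj, _ = static_dimer
        seg = SegmentDef("A", "bad", (230, 260))  # chain ends at 239
        with pytest.raises(ConfigurationError, match="240"):
            bb.fit_segment_axis(traj.topology, traj.frames[0], seg)


class TestDetectKinks:
    @pytest.mark.parametrize("window", [5, 6, 7])
    def test_no_false_calls_on_ideal_helix(self, window):
        helix = bb.generate_kinked_helix(60, 170)
        calls = bb.detect_kinks(helix.topology, helix.frames[0], "A",
                                (60, 170), window=window)
        assert calls == []

    def test_planted_kink_recovered(self):
        helix = bb.generate_kinked_helix(60, 170, kinks=[(114, 40.0)])
        calls = bb.detect_kinks(helix.topology, helix.frames[0], "A", (60, 170))
        assert len(calls) == 1
        assert abs(calls[0].center_residue - 114) <= 1
        assert calls[0].bend_angle == pytest.approx(40.0, abs=3.0)

    def test_two_planted_kinks(self):
        helix = bb.generate_kinked_helix(60, 170,
                                         kinks=[(114, 40.0), (128, 30.0)])
        calls = bb.detect_kinks(helix.topology, helix.frames[0], "A", (60, 170))
        assert len(calls) == 2
        assert abs(calls[0].center_residue - 114) <= 1
        assert abs(calls[1].center_residue - 128) <= 1
        assert calls[0].bend_angle == pytest.approx(40.0, abs=3.0)
        assert calls[1].bend_angle == pytest.approx(30.0, abs=3.0)

    def test_short_range_rejected(self):
        helix = bb.generate_kinked_helix(1, 10)
        with pytest.raises(FitError):
            bb.detect_kinks(helix.topology, helix.frames[0], "A", (1, 10),
                            window=6)


class TestAngleSpanSeries:
    def test_static_dimer_constant(self, static_dimer):
        traj, _ = static_dimer
        s = bb.angle_span_series(traj)
        for arr in (s.alpha_deg, s.beta_deg, s.gamma_deg, s.d_A):
            assert np.ptp(arr) < 1e-9

    def test_invariant_under_global_rigid_motion(self, static_dimer):
        traj, _ = static_dimer
        s0 = bb.angle_span_series(traj)
        s1 = bb.angle_span_series(_rigidly_move(traj, seed=5))
        np.testing.assert_allclose(s1.alpha_deg, s0.alpha_deg, atol=1e-6)
        np.testing.assert_allclose(s1.beta_deg, s0.beta_deg, atol=1e-6)
        np.testing.assert_allclose(s1.gamma_deg, s0.gamma_deg, atol=1e-6)
        np.testing.assert_allclose(s1.d_A, s0.d_A, atol=1e-6)

    def test_alpha_tracks_planted_swing(self):
        thetas = np.arange(0.0, 31.0, 5.0)
        spec = bb.DimerSpec(arm_angle_series=thetas)
        traj, truth = bb.generate_dimer_trajectory(spec)
        s = bb.angle_span_series(traj)
        assert np.all(np.abs(s.alpha_deg - truth.alpha_deg) < 2.0)

    def test_missing_anchor_is_config_error(self, static_dimer):
        traj, _ = static_dimer
        with pytest.raises(ConfigurationError, match="999"):
            bb.angle_span_series(traj, span_anchors=(("A", 999, "CA"),
                                                     ("B", 157, "CA")))


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert bb.pearson(x, x) == pytest.approx(1.0)
        assert bb.pearson(x, -2 * x + 5) == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 1, 4, 3, 6])
        # definitional two-pass oracle
        xd, yd = x - x.mean(), y - y.mean()
        expected = (xd @ yd) / np.sqrt((xd @ xd) * (yd @ yd))
        assert bb.pearson(x, y) == pytest.approx(expected, abs=1e-12)
        assert bb.pearson(x, y) == pytest.approx(0.82, abs=0.01)

    def test_constant_series_is_undefined_not_zero(self):
        with pytest.raises(ConstantSeriesError):
            bb.pearson(np.ones(5), np.arange(5.0))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(min_value=0, max_value=10**6))
    def test_matches_definitional_formula(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        xd, yd = x - x.mean(), y - y.mean()
        expected = (xd @ yd) / np.sqrt((xd @ xd) * (yd @ yd))
        assert bb.pearson(x, y) == pytest.approx(expected, abs=1e-12)


class TestCorrelationSummary:
    def test_planted_correlation_recovered(self):
        traj, _ = bb.generate_dimer_trajectory(
            bb.DimerSpec(seed=1),
            bb.MotionSpec(n_frames=3000, correlation_alpha_d=0.65, seed=11))
        s = bb.angle_span_series(traj)
        table = bb.correlation_summary(s, pairs=[("alpha", "d"), ("beta", "d")])
        r = dict(zip(zip(table["x"], table["y"]), table["pearson_r"]))
        assert r[("alpha", "d")] == pytest.approx(0.65, abs=0.10)
        assert abs(r[("beta", "d")]) < 0.15

    def test_self_pair_is_unity(self, static_dimer):
        traj, _ = static_dimer
        spec = bb.DimerSpec(seed=1)
        motion = bb.MotionSpec(n_frames=50, seed=2)
        moving, _ = bb.generate_dimer_trajectory(spec, motion)
        s = bb.angle_span_series(moving)
        table = bb.correlation_summary(s, pairs=[("d", "d")])
        assert table["pearson_r"].iloc[0] == pytest.approx(1.0)

    def test_pooling_mode_recorded(self, static_dimer):
        moving, _ = bb.generate_dimer_trajectory(
            bb.DimerSpec(seed=1), bb.MotionSpec(n_frames=50, seed=2))
        s = bb.angle_span_series(moving)
        t = bb.correlation_summary([s, s], pairs=[("alpha", "d")],
                                   pooling="per_trajectory")
        assert set(t["pooling"]) == {"per_trajectory"}


class TestRmsd:
    def test_identical_frames_zero(self, static_dimer):
        traj, _ = static_dimer
        df = bb.rmsd_series(traj, bb.Selection(atom_names={"CA"}))
        np.testing.assert_allclose(df["rmsd_A"], 0.0, atol=1e-6)

    def test_rigid_rotation_removed_by_superposition(self, static_dimer):
        traj, _ = static_dimer
        moved = _rigidly_move(traj, seed=9)
        df = bb.rmsd_series(moved, bb.Selection(atom_names={"CA"}))
        np.testing.assert_allclose(df["rmsd_A"], 0.0, atol=1e-6)

    def test_isotropic_jitter_recovered(self):
        rng = np.random.default_rng(31)
        n = 150
        base = rng.normal(0, 20, (n, 3))
        noisy = base + rng.normal(0, 1.0 / np.sqrt(3), (n, 3))  # 1 Å RMS
        topo = [bb.Atom(i + 1, "CA", "C", "ALA", i + 1, "A") for i in range(n)]
        traj = bb.Trajectory(topo, [bb.Frame(0.0, base), bb.Frame(1.0, noisy)])
        df = bb.rmsd_series(traj, bb.Selection(atom_names={"CA"}))
        assert df["rmsd_A"].iloc[1] == pytest.approx(1.0, rel=0.10)


class TestRmsf:
    def test_static_trajectory_zero(self, static_dimer):
        traj, _ = static_dimer
        df = bb.rmsf(traj, bb.Selection(atom_names={"CA"}))
        np.testing.assert_allclose(df["rmsf_A"], 0.0, atol=1e-9)

    def test_isotropic_jitter_closed_form(self):
        """Per-axis σ = 2 Å on one residue gives RMSF = σ√3 ≈ 3.46 Å."""
        rng = np.random.default_rng(7)
        n_at, n_fr = 100, 2000
        base = rng.normal(0, 15, (n_at, 3))
        X = np.tile(base, (n_fr, 1, 1))
        X[:, 5, :] += rng.normal(0, 2.0, (n_fr, 3))
        topo = [bb.Atom(i + 1, "CA", "C", "ALA", i + 1, "A")
                for i in range(n_at)]
        traj = bb.Trajectory(topo, [bb.Frame(float(t), X[t])
                                    for t in range(n_fr)])
        df = bb.rmsf(traj, bb.Selection(atom_names={"CA"}))
        got = df.loc[df.residue_number == 6, "rmsf_A"].item()
        assert got == pytest.approx(2.0 * np.sqrt(3), rel=0.05)
        assert df.loc[df.residue_number != 6, "rmsf_A"].max() < 0.3

    def test_rigid_drift_removed(self):
        rng = np.random.default_rng(3)
        base = rng.normal(0, 10, (30, 3))
        topo = [bb.Atom(i + 1, "CA", "C", "ALA", i + 1, "A") for i in range(30)]
        frames = [bb.Frame(float(t), base + np.array([3.0 * t, 0, 0]))
                  for t in range(20)]
        df = bb.rmsf(bb.Trajectory(topo, frames),
                     bb.Selection(atom_names={"CA"}))
        assert df["rmsf_A"].max() < 1e-6

    def test_single_frame_rejected(self):
        topo = [bb.Atom(1, "CA", "C", "ALA", 1, "A")]
        traj = bb.Trajectory(topo, [bb.Frame(0.0, np.zeros((1, 3)))])
        with pytest.raises(FitError):
            bb.rmsf(traj, bb.Selection(atom_names={"CA"}))
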