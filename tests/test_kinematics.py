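"""3-D kinematics: geometry primitives, signals, and simulator round-trips."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import swimlab as sl
from swimlab import kinematics as kin

coords = st.floats(min_value=-10, max_value=10)
points = st.tuples(coords, coords, coords)


class TestDist3d:
    def test_zero_and_pythagoras(self):
        assert kin.dist3d((1, 2, 3), (1, 2, 3)) == 0.0
        assert kin.dist3d((0, 0, 0), (1, 2, 2)) == pytest.approx(3.0)

    @settings(derandomize=True, max_examples=50)
    @given(p=points, q=points)
    def test_symmetry_and_nonnegativity(self, p, q):
        assert kin.dist3d(p, q) == pytest.approx(kin.dist3d(q, p))
        assert kin.dist3d(p, q) >= 0


class TestBodyAngle:
    def test_collinear_zero(self):
        assert kin.body_angle_3d((2, 0, 0), (0, 0, 0), (1, 0, 0)) == pytest.approx(0.0)

    def test_orthogonal_and_45(self):
        # vectors (crosshair-ped)=(1,0,0) vs (nose-ped)=(0,1,0) and (1,1,0)
        assert kin.body_angle_3d((0, 1, 0), (0, 0, 0), (1, 0, 0)) == pytest.approx(90.0)
        assert kin.body_angle_3d((1, 1, 0), (0, 0, 0), (1, 0, 0)) == pytest.approx(45.0)

    def test_degenerate_vector_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            kin.body_angle_3d((1, 0, 0), (0, 0, 0), (0, 0, 0))

    @settings(derandomize=True, max_examples=30)
    @given(angle=st.floats(5, 175))
    def test_rigid_motion_invariance(self, angle):
        nose = np.array([np.cos(np.radians(angle)), np.sin(np.radians(angle)), 0.0])
        ped = np.zeros(3)
        cross = np.array([1.0, 0.0, 0.0])
        base = kin.body_angle_3d(nose, ped, cross)
        # Rotate about Z by 30 deg and translate.
        c, s = np.cos(0.5236), np.sin(0.5236)
        rot = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
        shift = np.array([3.0, -2.0, 1.5])
        moved = kin.body_angle_3d(rot @ nose + shift, rot @ ped + shift,
                                  rot @ cross + shift)
        assert moved == pytest.approx(base, abs=1e-6)
        assert base == pytest.approx(angle, abs=1e-6)


class TestAngleToFlow:
    def test_upstream_is_zero(self):
        assert kin.angle_to_flow((-1, 0, 0), (0, 0, 0)) == pytest.approx(0.0)

    def test_perpendicular(self):
        assert abs(kin.angle_to_flow((0, 1, 0), (0, 0, 0))) == pytest.approx(90.0)

    def test_45_off_upstream(self):
        assert abs(kin.angle_to_flow((-1, 1, 0), (0, 0, 0))) == pytest.approx(45.0)

    def test_ventral_projection_ignores_pitch(self):
        a3d = kin.angle_to_flow((-1, 1, 1), (0, 0, 0))
        av = kin.angle_to_flow((-1, 1, 1), (0, 0, 0), projection="ventral")
        assert abs(av) == pytest.approx(45.0)
        assert abs(a3d) > abs(av)


class TestSchoolMetrics:
    def _two_fish_track(self, gap_m=0.06):
        coords = np.zeros((4, 2, 3, 3))
        for f in range(4):
            for i, x in enumerate((0.0, gap_m)):
                nose = np.array([x, 0.0, 0.0])
                ped = nose + np.array([0.05, 0.0, 0.0])  # facing upstream
                coords[f, i, 0] = nose
                coords[f, i, 1] = ped
                coords[f, i, 2] = nose
        return kin.Track3D(coords, fps=125.0)

    def test_two_fish_pairwise(self):
        track = self._two_fish_track()
        m = kin.school_metrics(track, body_length_m=0.05)
        assert m.mean_pairwise_bl == pytest.approx(1.2)
        assert m.sd_pairwise_bl == pytest.approx(0.0)

    def test_line_of_four_school_length(self):
        # Fish on the X axis at 1 BL spacing, peduncle 1 BL behind the nose:
        # first nose at 0, last nose at 3 BL, last peduncle at 4 BL.
        bl = 0.05
        coords = np.zeros((2, 4, 3, 3))
        for i in range(4):
            nose = np.array([i * bl, 0.0, 0.0])
            coords[:, i, 0] = nose
            coords[:, i, 1] = nose + np.array([bl, 0.0, 0.0])
            coords[:, i, 2] = nose
        m = kin.school_metrics(kin.Track3D(coords), body_length_m=bl)
        assert m.school_length_bl == pytest.approx(4.0)

    def test_translation_invariance(self):
        track = self._two_fish_track()
        shifted = kin.Track3D(track.coords + np.array([1.0, -2.0, 0.5]), fps=125.0)
        a = kin.school_metrics(track, 0.05)
        b = kin.school_metrics(shifted, 0.05)
        assert b.mean_pairwise_bl == pytest.approx(a.mean_pairwise_bl)
        assert b.sd_pairwise_bl == pytest.approx(a.sd_pairwise_bl)

    def test_simulator_nnd_roundtrip(self):
        track = sl.simulate_school_tracks(n_fish=4, nnd_bl=1.2, seed=3)
        m = kin.school_metrics(track, body_length_m=0.06)
        assert m.mean_pairwise_bl == pytest.approx(1.2, rel=0.05)


class TestTailBeat:
    def test_pure_sinusoid(self):
        t = np.arange(0, 10, 1 / 125)
        sig = 0.006 * np.sin(2 * np.pi * 5.0 * t)
        assert kin.tail_beat_frequency(sig, 125.0) == pytest.approx(5.0, abs=0.01)
        assert kin.tail_beat_amplitude(sig) == pytest.approx(0.012, rel=0.01)

    def test_noisy_sinusoid(self):
        rng = np.random.default_rng(7)
        t = np.arange(0, 10, 1 / 125)
        sig = 0.006 * np.sin(2 * np.pi * 5.0 * t) + rng.normal(0, 0.0006, t.size)
        assert kin.tail_beat_frequency(sig, 125.0) == pytest.approx(5.0, abs=0.1)

    def test_flat_signal_rejected(self):
        with pytest.raises(ValueError, match="flat|peaks"):
            kin.tail_beat_frequency(np.zeros(1000), 125.0)

    def test_simulator_ftb_roundtrip(self, clean_track):
        sig = kin.lateral_excursion(clean_track)
        assert kin.tail_beat_frequency(sig, 125.0) == pytest.approx(5.0, abs=0.05)


class TestTurning:
    def test_straight_trajectories_zero(self):
        headings = np.zeros((1250, 3))
        assert kin.turning_frequency(headings, 125.0) == 0.0

    def test_division_rule(self):
        # 12 synthetic step events over 8 fish -> 1.5 per fish.
        fps, n_frames, n_fish = 125.0, 1250, 8
        headings = np.zeros((n_frames, n_fish))
        count = 0
        for j in range(n_fish):
            for k in range(2 if j < 4 else 1):  # 4*2 + 4*1 = 12 events
                t0 = 200 + 400 * k + 13 * j
                headings[t0:, j] += 95.0 * (-1.0) ** k
                count += 1
        assert count == 12
        assert kin.turning_frequency(headings, fps) == pytest.approx(1.5)

    def test_simulator_turn_roundtrip(self):
        track = sl.simulate_school_tracks(
            n_fish=4, n_turns=3, heading_sd_deg=5.0, seed=11
        )
        headings = kin.headings_from_track(track)
        assert kin.turning_frequency(headings, track.fps) == pytest.approx(3.0)

    def test_short_recording_rejected(self):
        with pytest.raises(ValueError, match="span"):
            kin.turning_frequency(np.zeros((50, 2)), 125.0)


class TestDimensionless:
    def test_strouhal(self):
        assert kin.strouhal(10.0, 0.01, 0.5) == pytest.approx(0.2)
        assert kin.strouhal(10.0, 0.01, 0.25) == pytest.approx(0.4)
        with pytest.raises(ValueError):
            kin.strouhal(10.0, 0.01, 0.0)

    def test_reynolds(self):
        re = kin.reynolds(0.1, 0.05, density_kg_m3=996.2, viscosity_pa_s=8.33e-4)
        assert re == pytest.approx(5980, rel=0.001)
        assert kin.reynolds(0.2, 0.05, 996.2, 8.33e-4) == pytest.approx(2 * re, rel=1e-9)
        assert kin.reynolds(1.0, 1.0, 1.0, 1.0) == 1.0

    def test_simulator_strouhal_roundtrip(self, clean_track):
        sig = kin.lateral_excursion(clean_track)
        ftb = kin.tail_beat_frequency(sig, 125.0)
        amp = kin.tail_beat_amplitude(sig)
        st_est = kin.strouhal(ftb, amp, 1.0 * 0.06)
        assert st_est == pytest.approx(5.0 * 0.012 / 0.06, rel=0.02)


def test_track_csv_roundtrip(tmp_path):
    track = sl.simulate_school_tracks(n_fish=2, duration_s=1.0, seed=5)
    path = tmp_path / "track.csv"
    track.to_csv(path)
    back = kin.Track3D.from_csv(path, fps=track.fps)
    assert back.coords.shape == track.coords.shape
    assert np.allclose(back.coords, track.coords, atol=1e-6)


def test_frame_subsampling_agrees_with_all_frames():
    """Metrics at a few sampled frames match all-frame averages on a
    stationary track (the 1st/5th/10th-second sampling convention)."""
    track = sl.simulate_school_tracks(n_fish=4, nnd_bl=1.2, seed=9)
    all_frames = kin.school_metrics(track, 0.06)
    sampled = kin.school_metrics(
        track, 0.06, frames=np.array([125 - 1, 625 - 1, 1250 - 1])
    )
    assert sampled.mean_pairwise_bl == pytest.approx(
        all_frames.mean_pairwise_bl, rel=0.02
    )
    assert sampled.school_length_bl == pytest.approx(
        all_frames.school_length_bl, rel=0.05
    )
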