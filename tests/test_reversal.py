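"""Reversal detector: worked examples, oracle equivalence, equivariance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cletools import TooShortError, motility, reversal
from cletools.reversal import DetectorConfig
from cletools.trajectory_io import Trajectory

from conftest import oracle_detect, random_trajectory, traj_from_headings


class TestKinematics:
    def test_straight_line_has_zero_angles(self):
        traj = traj_from_headings([0.0] * 10)
        kin = reversal.compute_kinematics(traj)
        assert np.allclose(kin.theta, 0.0)
        assert np.allclose(kin.dtheta, 0.0)
        assert np.allclose(kin.speed, 1.0)

    def test_signed_angle_is_ccw_positive(self):
        # v = (1,0) then (0,1): a left (counter-clockwise) turn of +90°
        traj = traj_from_headings([0.0, 90.0, 90.0, 90.0])
        kin = reversal.compute_kinematics(traj)
        assert kin.theta[0] == pytest.approx(90.0)

    def test_antiparallel_maps_to_plus_180(self):
        traj = traj_from_headings([0.0, 180.0, 180.0, 180.0])
        kin = reversal.compute_kinematics(traj)
        assert kin.theta[0] == 180.0

    def test_too_short_trajectory_rejected(self):
        traj = traj_from_headings([0.0, 0.0, 0.0])  # 4 samples
        with pytest.raises(TooShortError):
            reversal.compute_kinematics(traj)

    def test_slow_steps_mark_angles_undefined(self):
        xy = np.array([[0, 0], [2.5, 0], [2.51, 0], [5.0, 0], [7.5, 0], [10.0, 0]])
        traj = Trajectory(cell_id="s", times=np.arange(6) / 16, xy=xy)
        kin = reversal.compute_kinematics(traj, DetectorConfig(min_step_speed=1.0))
        assert not kin.theta_defined[0]  # touches the 0.16 µm/s step
        assert not kin.theta_defined[1]
        assert kin.theta_defined[3]

    @given(st.integers(0, 2**32 - 1), st.integers(6, 40))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_theta_always_in_half_open_range(self, seed, n):
        traj = random_trajectory(np.random.default_rng(seed), n)
        kin = reversal.compute_kinematics(traj)
        assert np.all(kin.theta > -180.0) and np.all(kin.theta <= 180.0)
        assert np.all(np.abs(kin.dtheta) <= 360.0)


class TestWorkedExamples:
    """Hand-derived detector cases pinned exactly."""

    def test_single_reversal_12_frame_path(self):
        """East 5 steps then west 6 steps: one 180° flip, Δθ pair (+180, −180)."""
        x = np.array([0, 1, 2, 3, 4, 5, 4, 3, 2, 1, 0, -1], dtype=float)
        traj = Trajectory(
            cell_id="c", times=np.arange(12, dtype=float),
            xy=np.column_stack([x, np.zeros_like(x)]),
        )
        kin = reversal.compute_kinematics(traj)
        assert list(kin.theta) == [0, 0, 0, 0, 180, 0, 0, 0, 0, 0]
        events = reversal.detect_reversals(kin)
        assert len(events) == 1
        (ev,) = events
        assert ev.magnitudes == (180.0, 180.0)
        assert ev.turn_frame == 4  # the large turn θ between v_4 and v_5

        summary = reversal.summarize_cell(traj, events, kin)
        assert summary.duration == pytest.approx(11.0)
        assert summary.reversal_frequency == pytest.approx(1.0 / 11.0)
        assert summary.n_excluded_steps == 2  # the flip steps v_4, v_5
        assert summary.mean_run_speed == pytest.approx(1.0)

    def test_constant_curvature_arc_is_a_null_case(self):
        """θ ≡ +30° has zero angular acceleration: no events."""
        traj = traj_from_headings(np.arange(12) * 30.0)
        kin = reversal.compute_kinematics(traj)
        assert np.allclose(kin.theta, 30.0)
        assert reversal.detect_reversals(kin) == []

    def test_single_frame_90_degree_flick_is_detected(self):
        """A flick above threshold triggers the same criterion as a reversal."""
        xy = np.zeros((11, 2))
        xy[:7, 0] = np.arange(7)          # east 6 steps
        xy[7:, 0] = 6.0
        xy[7:, 1] = np.arange(1, 5)       # north 4 steps
        traj = Trajectory(cell_id="f", times=np.arange(11, dtype=float), xy=xy)
        kin = reversal.compute_kinematics(traj)
        events = reversal.detect_reversals(kin)
        assert len(events) == 1
        assert events[0].magnitudes == (90.0, 90.0)

    @pytest.mark.parametrize("mag,expected", [(45.0, 0), (45.000001, 1)])
    def test_threshold_tie_is_a_non_event(self, mag, expected):
        """|Δθ| exactly 45 fails the strict 'larger than 45' rule."""
        theta = np.array([0.0, 0.0, mag, 0.0, 0.0, 0.0])
        kin = reversal.Kinematics(
            dt=1.0,
            speed=np.ones(7),
            theta=theta,
            dtheta=np.diff(theta),
            theta_defined=np.ones(6, dtype=bool),
        )
        assert len(reversal.detect_reversals(kin)) == expected

    def test_symmetric_two_frame_reversal_is_missed(self):
        """90°+90° over two frames: Δθ products are 0, not < 0."""
        xy = np.zeros((12, 2))
        xy[:6, 0] = np.arange(6)              # east
        xy[6] = [5.0, 1.0]                    # one step north (90° turn)
        xy[7:, 0] = np.arange(4, -1, -1)      # then west (another 90°)
        xy[7:, 1] = 1.0
        traj = Trajectory(cell_id="s", times=np.arange(12, dtype=float), xy=xy)
        kin = reversal.compute_kinematics(traj)
        assert reversal.detect_reversals(kin) == []


class TestOracleEquivalence:
    @given(st.integers(0, 2**32 - 1), st.integers(7, 30))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_brute_force_on_random_short_trajectories(self, seed, n):
        traj = random_trajectory(np.random.default_rng(seed), n)
        kin = reversal.compute_kinematics(traj)
        events = reversal.detect_reversals(kin)
        assert [ev.index for ev in events] == oracle_detect(traj)


class TestEquivariance:
    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_rigid_motions_and_scaling_preserve_events(self, seed):
        rng = np.random.default_rng(seed)
        traj = random_trajectory(rng, 40)
        ref = [ev.index for ev in reversal.detect_reversals(reversal.compute_kinematics(traj))]
        phi = rng.uniform(0, 2 * np.pi)
        R = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
        # the speed gate is dimensionful, so spatial scaling must scale it too
        for transform, scale in (
            (lambda xy: xy @ R.T + rng.uniform(-50, 50, 2), 1.0),   # rotation+translation
            (lambda xy: xy * [1.0, -1.0], 1.0),                     # reflection
            (lambda xy: xy * 3.7, 3.7),                             # uniform scaling
        ):
            moved = Trajectory(cell_id="m", times=traj.times, xy=transform(traj.xy))
            cfg = DetectorConfig(min_step_speed=DetectorConfig().min_step_speed * scale)
            got = [ev.index for ev in reversal.detect_reversals(reversal.compute_kinematics(moved, cfg))]
            assert got == ref


class TestSummaries:
    def test_no_events_constant_speed(self):
        traj = traj_from_headings([0.0] * 480, dt=1 / 16, speed=40.0)
        summary, events = reversal.analyze_trajectory(traj)
        assert events == []
        assert summary.reversal_frequency == 0.0
        assert summary.mean_run_speed == pytest.approx(40.0, rel=1e-9)

    def test_run_speed_excludes_reversal_steps(self):
        """Speed during the flip frames must not bias the run speed."""
        # 2.0 µm/s cruising, but the two steps forming the 180° turn run at
        # 0.5 µm/s; excluding them restores the programmed run speed exactly.
        step_lengths = [2.0] * 4 + [0.5, -0.5] + [-2.0] * 5
        x = np.concatenate([[0.0], np.cumsum(step_lengths)])
        traj = Trajectory(
            cell_id="v", times=np.arange(x.size, dtype=float), xy=np.column_stack([x, np.zeros_like(x)])
        )
        summary, events = reversal.analyze_trajectory(
            traj, DetectorConfig(min_step_speed=0.4)
        )
        assert len(events) == 1
        assert summary.n_excluded_steps == 2
        assert summary.mean_run_speed == pytest.approx(2.0)

    def test_cohort_distribution_binning(self):
        def s(freq):
            return reversal.CellSummary("c", 30.0, 0, freq, 40.0, 0)

        dist = reversal.summarize_cohort(
            [s(0.1), s(0.3)], "reversal_frequency", np.array([0.0, 0.2, 0.4])
        )
        assert dist.fraction_of_cells == pytest.approx([0.5, 0.5])
        assert dist.n_overflow == 0
        single = reversal.summarize_cohort([s(0.1)], "reversal_frequency")
        assert single.fraction_of_cells.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.count_nonzero(single.fraction_of_cells) == 1

    @given(st.lists(st.floats(0.0, 0.999), min_size=1, max_size=40))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_fractions_sum_to_one_for_in_range_values(self, freqs):
        summaries = [reversal.CellSummary("c", 30.0, 0, f, 40.0, 0) for f in freqs]
        dist = reversal.summarize_cohort(summaries, "reversal_frequency")
        assert dist.fraction_of_cells.sum() == pytest.approx(1.0, abs=1e-12)


class TestCompareCohorts:
    def test_identical_cohorts_give_p_one(self):
        a = [reversal.CellSummary("c", 30.0, 3, 0.1, 40.0, 0) for _ in range(5)]
        cmp = reversal.compare_cohorts(a, list(a), "reversal_frequency")
        assert cmp.difference == 0.0
        assert cmp.p_value == 1.0
        assert cmp.degenerate

    def test_degenerate_variance_flagged(self):
        a = [reversal.CellSummary("c", 30.0, 0, 0.0, 40.0, 0)] * 2
        b = [reversal.CellSummary("c", 30.0, 3, 1.0, 40.0, 0)] * 2
        cmp = reversal.compare_cohorts(a, b, "reversal_frequency")
        assert cmp.degenerate and cmp.p_value == 0.0

    def test_separated_cohorts_agree_with_permutation_oracle(self, rng):
        """Welch p for clearly separated simulated cohorts matches a
        permutation test in calling a highly significant difference."""
        pa = motility.MotilityParams(k_fr=0.1, k_rf=0.1)
        pb = motility.MotilityParams(k_fr=0.4, k_rf=0.4)
        sa = [reversal.analyze_trajectory(t)[0] for t in motility.simulate_cohort(pa, 60, 21)]
        sb = [reversal.analyze_trajectory(t)[0] for t in motility.simulate_cohort(pb, 60, 22)]
        cmp = reversal.compare_cohorts(sa, sb, "reversal_frequency")
        assert cmp.p_value < 1e-6

        va = np.array([s.reversal_frequency for s in sa])
        vb = np.array([s.reversal_frequency for s in sb])
        pooled = np.concatenate([va, vb])
        obs = abs(va.mean() - vb.mean())
        hits = 0
        n_perm = 2000
        for _ in range(n_perm):
            rng.shuffle(pooled)
            if abs(pooled[: len(va)].mean() - pooled[len(va):].mean()) >= obs:
                hits += 1
        assert hits / n_perm < 0.005  # permutation oracle agrees: extreme
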