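"""Optical reference step-width methods."""

import numpy as np
import pytest

from magstep import references as R
from magstep.containers import (
    FORWARD_CROSSING,
    GaitEvent,
    INITIAL_CONTACT,
    LEFT,
    RIGHT,
    StepWidthSeries,
    TrajectorySet,
)
from magstep.errors import ValidationError
from magstep.simulate import GaitParams, simulate_standing


def oracle_point_line(p1, p2, q):
    """Independent projection-based point-to-line distance."""
    p1, p2, q = (np.asarray(v, float) for v in (p1, p2, q))
    u = (p2 - p1) / np.linalg.norm(p2 - p1)
    r = q - p1
    return float(np.linalg.norm(r - (r @ u) * u))


def _traj(markers, fs=100.0, belt_speed=0.0):
    return TrajectorySet(fs=fs, markers=markers, belt_speed=belt_speed)


class TestRigidBodyCentroid:
    def test_single_point_identity(self):
        pts = np.random.default_rng(0).normal(size=(50, 3))
        assert np.array_equal(R.rigid_body_centroid([pts]), pts)

    def test_two_point_offset(self):
        a = np.zeros((10, 3))
        b = np.tile([0.0, 0.0, 0.02], (10, 1))
        assert np.allclose(R.rigid_body_centroid([a, b]), [0, 0, 0.01])

    def test_rigid_translation_recovered_exactly(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(4, 3))  # 4 cluster points
        path = np.cumsum(rng.normal(size=(200, 3)), axis=0) * 0.01
        cluster = [path + b for b in base]
        expected = path + base.mean(axis=0)
        assert np.allclose(R.rigid_body_centroid(cluster), expected, atol=1e-12)

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValidationError):
            R.rigid_body_centroid([])


class TestOmcDistances:
    def test_constant_offset(self):
        n = 20
        s0 = np.zeros((n, 3))
        markers = {
            "S0": s0,
            "S1": s0 + [0, 0, 0.10],
            "A0": s0 + [0, 0.2, 0],
        }
        ds = R.omc_distances(_traj(markers), da=0.10)
        assert np.allclose(ds.d_lower, 0.2)

    def test_missing_device_markers(self):
        with pytest.raises(ValidationError, match="S1"):
            R.omc_distances(_traj({"A0": np.ones((9, 3)), "S0": np.ones((9, 3))}), da=0.1)

    def test_matches_simulator_truth_exactly(self, noise_free_walk):
        p, traj, truth, ds = noise_free_walk
        omc = R.omc_distances(traj, da=p.geometry.da)
        assert np.max(np.abs(omc.d_lower - ds.d_lower)) < 1e-12
        assert np.max(np.abs(omc.d_upper - ds.d_upper)) < 1e-12


class TestDetectInitialContacts:
    def test_cosine_valleys(self):
        """Point minima of a raised-cosine heel height; the boundary minimum
        at n=0 has no descending flank and is excluded."""
        n = np.arange(360)
        z = 0.03 * (1 - np.cos(2 * np.pi * n / 120))
        heel = np.column_stack([np.zeros(360), np.zeros(360), z])
        traj = _traj({"heel_L": heel})
        events = R.detect_initial_contacts(traj, "left")
        assert [ev.k for ev in events] == [120, 240]
        assert all(ev.side == LEFT for ev in events)

    def test_monotone_height_has_no_contacts(self):
        heel = np.column_stack([np.zeros(300), np.zeros(300), np.linspace(0, 1, 300)])
        assert R.detect_initial_contacts(_traj({"heel_R": heel}), "right") == []

    def test_simulated_walk_contacts_align_with_truth(self, noise_free_walk):
        """Each full stance in the record carries exactly one detected event,
        at the stance plateau centre."""
        p, traj, truth, _ = noise_free_walk
        ts = p.stance_time
        for foot in (LEFT, RIGHT):
            detected = np.array([ev.time for ev in R.detect_initial_contacts(traj, foot)])
            ics = [s.ic_time for s in truth.steps
                   if s.side == foot and s.ic_time + ts < p.duration]
            assert len(ics) > 70
            for ic in ics:
                inside = detected[(detected >= ic) & (detected <= ic + ts)]
                assert len(inside) == 1
                assert inside[0] == pytest.approx(ic + ts / 2, abs=2 / p.fs)


def _ic(k, time, side):
    return GaitEvent(kind=INITIAL_CONTACT, k=k, time=time, side=side)


class TestStepWidthInitialContact:
    def _make(self, p1, p2, q):
        """Left ICs at samples 0 and 2 (positions p1, p2), right IC at 1 (q)."""
        n = 3
        heel_l = np.zeros((n, 3))
        heel_r = np.zeros((n, 3))
        heel_l[0, :2] = p1
        heel_l[2, :2] = p2
        heel_r[1, :2] = q
        traj = _traj({"heel_L": heel_l, "heel_R": heel_r}, fs=1.0)
        ic_l = [_ic(0, 0.0, LEFT), _ic(2, 2.0, LEFT)]
        ic_r = [_ic(1, 1.0, RIGHT)]
        return traj, ic_l, ic_r

    def test_axis_aligned(self):
        traj, ic_l, ic_r = self._make((0, 0), (1.0, 0), (0.5, 0.12))
        sw = R.step_width_initial_contact(traj, ic_l, ic_r)
        assert len(sw) == 1
        assert sw.widths[0] == pytest.approx(0.12, abs=1e-12)
        assert sw.events[0].side == RIGHT

    def test_oblique_line_of_progression(self):
        p1, p2, q = (0, 0), (1.0, 0.10), (0.5, 0.15)
        traj, ic_l, ic_r = self._make(p1, p2, q)
        sw = R.step_width_initial_contact(traj, ic_l, ic_r)
        assert sw.widths[0] == pytest.approx(oracle_point_line(p1, p2, q), abs=1e-12)
        assert sw.widths[0] == pytest.approx(0.09950371902099893, abs=1e-9)

    def test_simplified_forward_progression(self):
        traj, ic_l, ic_r = self._make((0, 0), (1.0, 0), (0.5, 0.12))
        sw = R.step_width_initial_contact(traj, ic_l, ic_r, simplified=True)
        assert sw.widths[0] == pytest.approx(0.12, abs=1e-12)

    def test_degenerate_stride_skipped(self):
        traj, ic_l, ic_r = self._make((0, 0), (0, 0), (0.5, 0.12))
        sw = R.step_width_initial_contact(traj, ic_l, ic_r)
        assert len(sw) == 0

    def test_pairs_without_single_intermediate_skipped(self):
        traj, ic_l, _ = self._make((0, 0), (1.0, 0), (0.5, 0.12))
        sw = R.step_width_initial_contact(traj, ic_l, [])
        assert len(sw) == 0

    def test_point_line_oracle_bulk(self):
        rng = np.random.default_rng(3)
        for _ in range(300):
            p1, p2, q = rng.normal(size=(3, 2))
            if np.linalg.norm(p2 - p1) < 1e-6:
                continue
            assert R.point_line_distance(p1, p2, q) == pytest.approx(
                oracle_point_line(p1, p2, q), abs=1e-12
            )


class TestForwardCrossings:
    def test_antisymmetric_sinusoids(self):
        n = np.arange(300)
        x_l = 0.1 * np.sin(2 * np.pi * n / 100)
        heel_l = np.column_stack([x_l, np.full(300, 0.06), np.zeros(300)])
        heel_r = np.column_stack([-x_l, np.full(300, -0.06), np.zeros(300)])
        traj = _traj({"heel_L": heel_l, "heel_R": heel_r})
        events = R.detect_forward_crossings(traj)
        ks = np.array([ev.k for ev in events])
        expected = np.array([0, 50, 100, 150, 200, 250])
        assert len(ks) == len(expected)
        assert np.max(np.abs(ks - expected)) < 1e-6
        sides = [ev.side for ev in events]
        assert all(a != b for a, b in zip(sides, sides[1:]))

    def test_linear_interpolation_of_crossing(self):
        g = np.full(30, -0.04)
        g[:10] = -0.04
        g = np.linspace(-0.04, -0.01, 11)  # reaches -0.01 at sample 10
        g = np.concatenate([g, [0.03] * 10])
        heel_l = np.column_stack([g, np.zeros(21), np.zeros(21)])
        heel_r = np.zeros((21, 3))
        traj = _traj({"heel_L": heel_l, "heel_R": heel_r})
        events = R.detect_forward_crossings(traj)
        assert len(events) == 1
        assert events[0].k == pytest.approx(10.25, abs=1e-12)

    def test_parallel_components_no_crossing(self):
        x = np.linspace(0, 1, 100)
        heel_l = np.column_stack([x + 0.2, np.zeros(100), np.zeros(100)])
        heel_r = np.column_stack([x, np.zeros(100), np.zeros(100)])
        assert R.detect_forward_crossings(_traj({"heel_L": heel_l, "heel_R": heel_r})) == []

    def test_simulated_walk_crossings_match_truth(self, noise_free_walk):
        p, traj, truth, _ = noise_free_walk
        events = R.detect_forward_crossings(traj)
        assert len(events) == len(truth)
        for ev, step in zip(events, truth.steps):
            assert ev.side == step.side
            assert ev.time == pytest.approx(step.crossing_time, abs=1.5 / p.fs)


class TestStepWidthMidSwing:
    def test_constant_lateral_positions(self):
        n = 40
        heel_l = np.column_stack([np.linspace(-1, 1, n), np.full(n, 0.06), np.zeros(n)])
        heel_r = np.column_stack([np.linspace(1, -1, n), np.full(n, -0.06), np.zeros(n)])
        traj = _traj({"heel_L": heel_l, "heel_R": heel_r})
        crossings = R.detect_forward_crossings(traj)
        sw = R.step_width_mid_swing(traj, crossings)
        assert np.allclose(sw.widths, 0.12, atol=1e-12)

    def test_interpolated_width(self):
        heel_l = np.zeros((21, 3))
        heel_r = np.zeros((21, 3))
        heel_l[10, 1] = 0.05
        heel_l[11, 1] = 0.07
        heel_r[:, 1] = -0.05
        traj = _traj({"heel_L": heel_l, "heel_R": heel_r})
        ev = GaitEvent(kind=FORWARD_CROSSING, k=10.5, time=0.105)
        sw = R.step_width_mid_swing(traj, [ev])
        assert sw.widths[0] == pytest.approx(0.11, abs=1e-12)

    def test_simulated_walk_matches_heel_separation_truth(self, noise_free_walk):
        p, traj, truth, _ = noise_free_walk
        sw = R.step_width_mid_swing(traj, R.detect_forward_crossings(traj))
        assert len(sw) == len(truth)
        assert np.max(np.abs(sw.widths - truth.heel_separation)) < 1e-3


class TestStepWidthShankClearance:
    def test_noise_free_walk_recovers_device_truth(self, noise_free_walk):
        p, traj, truth, _ = noise_free_walk
        sw = R.step_width_shank_clearance(traj, p.geometry)
        assert len(sw) == len(truth)
        assert np.max(np.abs(sw.widths - truth.device_dy)) < 1e-6
        # events coincide with the magnetic-channel events (identical inputs)
        assert np.max(np.abs(sw.times - truth.midswing_times)) < 1.01 / p.fs

    def test_standing_trial_is_empty(self):
        traj, _ = simulate_standing(20.0, GaitParams())
        sw = R.step_width_shank_clearance(traj)
        assert len(sw) == 0


def _series(sides):
    events = [
        GaitEvent(kind=FORWARD_CROSSING, k=i, time=float(i), side=s)
        for i, s in enumerate(sides)
    ]
    return StepWidthSeries(method="magnetic", events=events,
                           widths=np.arange(len(sides), dtype=float))


class TestTrimToEqualSides:
    def test_trailing_surplus_removed(self):
        sw = R.trim_to_equal_sides(_series([LEFT, RIGHT, LEFT, RIGHT, LEFT]))
        assert sw.sides == [LEFT, RIGHT, LEFT, RIGHT]
        assert list(sw.widths) == [0, 1, 2, 3]

    def test_balanced_series_unchanged(self):
        sw = R.trim_to_equal_sides(_series([RIGHT, LEFT, LEFT, RIGHT]))
        assert len(sw) == 4

    def test_pathological_sequence_reduces_to_empty(self):
        sw = R.trim_to_equal_sides(_series([RIGHT, RIGHT, LEFT]))
        assert len(sw) == 0
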