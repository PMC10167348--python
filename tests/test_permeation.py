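"""Trajectory analysis: alignment, permeation counting, conductance,
rotamers and hydrogen bonds."""

import numpy as np
import pytest

from channelgate._geometry import place_atom
from channelgate.permeation import (AlignmentRef, PermeationRule,
                                    align_frames, chi1_series,
                                    count_permeation_events,
                                    estimate_conductance, hbond_occupancy,
                                    permeation_rates, water_occupancy_grid)
from channelgate.structures import Atom, Structure
from channelgate.synthetic import BrownianSimSpec, simulate_brownian_pore
from channelgate.trajectories import Trajectory


def scripted_trajectory(z_series, dt_ps=10.0):
    """Single-particle trajectory following a prescribed z path."""
    z = np.asarray(z_series, float)
    frames = np.zeros((z.size, 1, 3))
    frames[:, 0, 2] = z
    return Trajectory(frames, np.arange(z.size) * dt_ps)


def replay_oracle(z, entry, exit_, wrap=None):
    """Naive frame-by-frame replay of the counting rule (test oracle).

    Walks the raw z series step by step, keeping an explicit armed flag,
    fully independent of the library's implementation.
    """
    events = []
    armed = False
    down = exit_ < entry
    for i in range(1, len(z)):
        a, b = z[i - 1], z[i]
        if wrap is not None and abs(b - a) > wrap:
            armed = False
            continue
        crossed_exit = (a > exit_ >= b) if down else (a < exit_ <= b)
        crossed_in = (a > entry >= b) if down else (a < entry <= b)
        crossed_out = (a <= entry < b) if down else (a >= entry > b)
        if armed and crossed_exit:
            events.append(i)
            armed = False
        if crossed_in:
            armed = True
        elif armed and crossed_out:
            armed = False
    return events


class TestAlignment:
    def test_reference_com_at_origin(self):
        rng = np.random.default_rng(0)
        traj = Trajectory(rng.normal(size=(10, 6, 3)) * 5, np.arange(10.0))
        ref = AlignmentRef((0, 1, 2, 3))
        out = align_frames(traj, ref)
        com = out.frames[:, :4, :].mean(axis=1)
        np.testing.assert_allclose(com, 0.0, atol=1e-9)

    def test_constant_shift_removed(self):
        rng = np.random.default_rng(1)
        traj = Trajectory(rng.normal(size=(8, 5, 3)), np.arange(8.0))
        shifted = traj.translated(np.tile([3.0, -7.0, 11.0], (8, 1)))
        ref = AlignmentRef((0, 1, 4))
        np.testing.assert_allclose(align_frames(traj, ref).frames,
                                   align_frames(shifted, ref).frames,
                                   atol=1e-9)

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            AlignmentRef(())


class TestPermeationCounting:
    def test_monotone_descent_one_downward_event(self):
        traj = scripted_trajectory(np.linspace(-1.0, -19.0, 30))
        rule = PermeationRule(-2.0, -18.0, "downward")
        events = count_permeation_events(traj, rule)
        assert len(events) == 1
        assert events[0].direction == "downward"

    def test_turnback_before_exit_no_event(self):
        z = np.concatenate([np.linspace(-1, -10, 10), np.linspace(-10, -1, 10)])
        traj = scripted_trajectory(z)
        assert count_permeation_events(
            traj, PermeationRule(-2.0, -18.0, "downward")) == []

    def test_ion_full_pore_upward_event(self):
        traj = scripted_trajectory(np.linspace(-19.0, 19.0, 50))
        rule = PermeationRule(-18.0, 18.0, "upward")
        events = count_permeation_events(traj, rule)
        assert len(events) == 1
        assert events[0].direction == "upward"

    def test_recrossing_disarms_then_rearms(self):
        # dips below the entry plane, retreats, then completes a passage
        z = np.array([-1.0, -4.0, -1.0, -3.0, -8.0, -14.0, -19.0])
        traj = scripted_trajectory(z)
        events = count_permeation_events(
            traj, PermeationRule(-2.0, -18.0, "downward"))
        assert len(events) == 1
        assert events[0].entry_frame == 3    # the second arming

    def test_both_directions_use_mirrored_planes(self):
        down = np.linspace(-1.0, -19.0, 20)
        up = np.linspace(-19.0, -1.0, 20)
        traj = scripted_trajectory(np.concatenate([down, up]))
        events = count_permeation_events(
            traj, PermeationRule(-2.0, -18.0, "both"))
        assert sorted(e.direction for e in events) == ["downward", "upward"]

    def test_unsorted_frames_rejected(self):
        traj = scripted_trajectory(np.linspace(-1, -19, 5))
        traj.times_ps[2] = 0.0    # corrupt after construction
        with pytest.raises(ValueError, match="sorted"):
            count_permeation_events(
                traj, PermeationRule(-2.0, -18.0, "downward"))

    @pytest.mark.parametrize("seed", range(20))
    def test_oracle_equivalence_on_brownian_ensembles(self, seed):
        spec = BrownianSimSpec(n_particles=20, n_frames=800,
                               drift_velocity_z=-0.05, seed=seed)
        traj = simulate_brownian_pore(spec)
        wrap = 0.5 * float(traj.box[2])
        rule = PermeationRule(-2.0, -18.0, "both", wrap_jump=wrap)
        got = {}
        for e in count_permeation_events(traj, rule):
            got.setdefault((e.particle, e.direction), []).append(e.exit_frame)
        expected = {}
        for p in range(traj.n_atoms):
            z = traj.frames[:, p, 2]
            for entry, exit_, direction in ((-2.0, -18.0, "downward"),
                                            (-18.0, -2.0, "upward")):
                ev = replay_oracle(z, entry, exit_, wrap)
                if ev:
                    expected[(p, direction)] = ev
        assert got == expected

    def test_invalid_plane_direction_combinations(self):
        with pytest.raises(ValueError):
            PermeationRule(-2.0, -2.0, "downward")
        with pytest.raises(ValueError):
            PermeationRule(-18.0, -2.0, "downward")
        with pytest.raises(ValueError):
            PermeationRule(-2.0, -18.0, "upward")


class TestAnionExclusion:
    def test_excluded_anions_never_permeate(self):
        # anions repelled at the mouth: their z never reaches the pore
        # interior, so the ion rule must count exactly zero events
        spec = BrownianSimSpec(n_particles=30, n_frames=1500,
                               z_bounds=(-1.5, 20.0), seed=12,
                               drift_velocity_z=-0.05)
        traj = simulate_brownian_pore(spec)
        rule = PermeationRule(-18.0, 18.0, "upward",
                              wrap_jump=0.5 * float(traj.box[2]))
        assert count_permeation_events(traj, rule) == []
        down = PermeationRule(-2.0, -18.0, "downward",
                              wrap_jump=0.5 * float(traj.box[2]))
        assert count_permeation_events(traj, down) == []


class TestRatesAndBlocks:
    def test_block_arithmetic(self):
        events = [type("E", (), {"exit_time_ps": t})()
                  for t in [1e3, 2e3, 10e3, 30e3, 59e3, 70e3, 90e3, 100e3,
                            110e3]]
        # 120 ns, 60-ns blocks, counts {5, 4}
        s = permeation_rates(events, total_time_ns=120.0, block_ns=60.0)
        np.testing.assert_array_equal(s.events_per_block, [5, 4])
        np.testing.assert_allclose(s.rates_per_ns, [5 / 60, 4 / 60])
        assert s.mean_rate_per_ns == pytest.approx((5 / 60 + 4 / 60) / 2)
        assert not s.partial_last_block

    def test_zero_events(self):
        s = permeation_rates([], total_time_ns=120.0, block_ns=60.0)
        assert s.total_events == 0
        np.testing.assert_array_equal(s.rates_per_ns, [0.0, 0.0])

    def test_discard_initial_window(self):
        events = [type("E", (), {"exit_time_ps": t})()
                  for t in [10e3, 40e3, 60e3, 80e3]]
        s = permeation_rates(events, total_time_ns=110.0, block_ns=60.0,
                             discard_initial_ns=50.0)
        assert s.total_events == 2          # the 10-ns and 40-ns events drop
        assert s.events_per_block.tolist() == [2]

    def test_short_trajectory_partial_block_flagged(self):
        s = permeation_rates([], total_time_ns=30.0, block_ns=60.0)
        assert s.partial_last_block


class TestOccupancyGrid:
    def test_immobile_particle_single_voxel(self):
        frames = np.zeros((100, 1, 3))
        frames[:, 0] = [1.3, -2.2, 5.7]
        traj = Trajectory(frames, np.arange(100.0))
        grid = water_occupancy_grid(traj)
        assert grid.counts.max() == 100
        assert (grid.counts > 0).sum() == 1

    def test_grid_sum_equals_in_region_samples(self):
        spec = BrownianSimSpec(n_particles=10, n_frames=200, seed=4)
        traj = simulate_brownian_pore(spec)
        region = ((-5.0, 5.0), (-5.0, 5.0), (-20.0, 20.0))
        grid = water_occupancy_grid(traj, region=region)
        pts = traj.frames.reshape(-1, 3)
        inside = np.all((pts >= [r[0] for r in region]) &
                        (pts < [r[1] for r in region]), axis=1)
        # histogramdd includes the right edge of the last bin; allow for
        # the few points landing exactly there
        assert abs(grid.counts.sum() - inside.sum()) <= 3

    def test_fraction_mode_and_validation(self):
        frames = np.zeros((10, 1, 3))
        traj = Trajectory(frames, np.arange(10.0))
        grid = water_occupancy_grid(traj, normalization="fraction")
        assert grid.values.max() == pytest.approx(1.0)
        with pytest.raises(ValueError):
            water_occupancy_grid(traj, voxel_angstrom=0.0)


class TestConductance:
    def test_hand_checked_value(self):
        est = estimate_conductance(37, 100.0, 600.0)
        assert est.current_pA == pytest.approx(59.28, abs=0.01)
        assert est.conductance_pS == pytest.approx(98.8, abs=0.1)

    def test_zero_events_zero_conductance(self):
        assert estimate_conductance(0, 50.0, 600.0).conductance_pS == 0.0

    def test_negative_voltage_positive_conductance(self):
        est = estimate_conductance(10, 100.0, -600.0)
        assert est.conductance_pS > 0

    def test_zero_voltage_rejected(self):
        with pytest.raises(ValueError):
            estimate_conductance(10, 100.0, 0.0)

    def test_matches_brownian_drift_flux_prediction(self):
        # conductance of the charged-particle surrogate agrees with the
        # analytic drift-flux prediction within 3 SE over 5 seeds
        g = []
        for seed in range(5):
            spec = BrownianSimSpec(n_particles=50, diffusion_coeff=0.05,
                                   drift_velocity_z=0.1, n_frames=3000,
                                   seed=seed)
            traj = simulate_brownian_pore(spec)
            rule = PermeationRule(-18.0, 18.0, "upward",
                                  wrap_jump=0.5 * float(traj.box[2]))
            events = count_permeation_events(traj, rule)
            total_ns = float(traj.times_ps[-1]) * 1e-3
            s = permeation_rates(events, total_ns, block_ns=total_ns - 1.0,
                                 discard_initial_ns=1.0)
            n_eff = s.total_events
            g.append(estimate_conductance(
                n_eff, total_ns - 1.0, 600.0).conductance_pS)
        g = np.array(g)
        L = spec.z_bounds[1] - spec.z_bounds[0]
        expected_rate = spec.n_particles * spec.drift_velocity_z / L  # per ps
        expected_g = estimate_conductance(
            int(round(expected_rate * 1000 * 100)), 100.0, 600.0).conductance_pS
        se = g.std(ddof=1) / np.sqrt(len(g))
        assert abs(g.mean() - expected_g) <= 3 * se


class TestChi1:
    def _residue(self, chi1_deg):
        n = np.array([0.0, 0.0, 0.0])
        ca = np.array([1.458, 0.0, 0.0])
        cb = place_atom(np.array([0.0, 1.0, 0.0]), n, ca, 1.53, 110.0, 0.0)
        cg = place_atom(n, ca, cb, 1.52, 114.0, chi1_deg)
        atoms = [Atom("A", 1085, "TYR", nm, el, p) for nm, el, p in
                 [("N", "N", n), ("CA", "C", ca), ("CB", "C", cb),
                  ("CG", "C", cg)]]
        return Structure(atoms)

    @staticmethod
    def _circdiff(a, b):
        return abs((a - b + 180.0) % 360.0 - 180.0)

    def test_exact_dihedral_recovered(self):
        st = self._residue(-180.0)
        frames = np.repeat(st.coords[None], 3, axis=0)
        ts = chi1_series(st, Trajectory(frames, np.arange(3.0)), "A", 1085)
        assert self._circdiff(ts.angles_deg[0], -180.0) <= 1e-6

    def test_two_well_series_labelled_fluctuating(self):
        st = self._residue(-180.0)
        alt = self._residue(-80.0)
        frames = np.concatenate([
            np.repeat(st.coords[None], 5, axis=0),
            np.repeat(alt.coords[None], 5, axis=0)] * 2)
        ts = chi1_series(st, Trajectory(frames, np.arange(20.0)), "A", 1085)
        assert ts.label == "fluctuating"

    def test_jittered_single_well_labelled_stable(self):
        rng = np.random.default_rng(5)
        frames = np.stack([self._residue(-178.0 + 3.0 * rng.standard_normal())
                           .coords for _ in range(50)])
        st = self._residue(-178.0)
        ts = chi1_series(st, Trajectory(frames, np.arange(50.0)), "A", 1085)
        assert ts.label == "stable"
        assert ts.circular_sd_deg <= 20.0

    def test_missing_atoms_raise(self):
        st = Structure([Atom("A", 7, "TYR", "CA", "C", [0, 0, 0])])
        frames = np.zeros((2, 1, 3))
        with pytest.raises(KeyError):
            chi1_series(st, Trajectory(frames, np.arange(2.0)), "A", 7)


class TestHbond:
    def _amide_pair(self, da_distance, collinear=True):
        from channelgate._geometry import sp2_amide_hydrogens

        cb = np.array([0.0, 0.0, 0.0])
        cg = np.array([1.52, 0.0, 0.0])
        od1 = place_atom(np.array([0.0, 1.0, 0.0]), cb, cg, 1.23, 121.0, 0.0)
        nd2 = place_atom(np.array([0.0, 1.0, 0.0]), cb, cg, 1.33, 116.0, 180.0)
        h = sp2_amide_hydrogens(nd2, cg, od1)[0]
        direction = (h - nd2) / np.linalg.norm(h - nd2)
        if not collinear:  # put the acceptor ~90 degrees off the N-H axis
            direction = np.cross(direction, [0.0, 0.0, 1.0])
        acc = nd2 + da_distance * direction
        atoms = [Atom("A", 1098, "ASN", nm, el, p) for nm, el, p in
                 [("CB", "C", cb), ("CG", "C", cg), ("OD1", "O", od1),
                  ("ND2", "N", nd2)]]
        atoms.append(Atom("A", 1094, "ALA", "O", "O", acc))
        return Structure(atoms)

    def test_good_geometry_bonded(self):
        st = self._amide_pair(2.9)
        frames = np.repeat(st.coords[None], 4, axis=0)
        hb = hbond_occupancy(st, Trajectory(frames, np.arange(4.0)),
                             ("A", 1098, "ND2"), ("A", 1094, "O"))
        assert hb.occupancy == pytest.approx(1.0)

    def test_long_distance_not_bonded(self):
        st = self._amide_pair(5.0)
        frames = np.repeat(st.coords[None], 4, axis=0)
        hb = hbond_occupancy(st, Trajectory(frames, np.arange(4.0)),
                             ("A", 1098, "ND2"), ("A", 1094, "O"))
        assert hb.occupancy == 0.0

    def test_bad_angle_not_bonded(self):
        st = self._amide_pair(2.9, collinear=False)
        frames = np.repeat(st.coords[None], 4, axis=0)
        hb = hbond_occupancy(st, Trajectory(frames, np.arange(4.0)),
                             ("A", 1098, "ND2"), ("A", 1094, "O"))
        assert hb.occupancy == 0.0

    def test_partial_occupancy_fraction(self):
        st = self._amide_pair(2.9)
        frames = np.repeat(st.coords[None], 10, axis=0)
        frames[4:10, -1, 2] += 5.0       # break the bond in 6 of 10 frames
        hb = hbond_occupancy(st, Trajectory(frames, np.arange(10.0)),
                             ("A", 1098, "ND2"), ("A", 1094, "O"))
        assert hb.occupancy == pytest.approx(0.4)

    def test_unresolvable_donor_spec(self):
        st = self._amide_pair(2.9)
        frames = np.repeat(st.coords[None], 2, axis=0)
        with pytest.raises(KeyError):
            hbond_occupancy(st, Trajectory(frames, np.arange(2.0)),
                            ("A", 9999, "ND2"), ("A", 1094, "O"))
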