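"""Generators: self-certifying geometry, seeded reproducibility, ground truth."""

import numpy as np
import pytest

from channelgate.flux import calibrate_calcium
from channelgate.synthetic import (BrownianSimSpec, DoseResponseSpec,
                                   LuminescenceSpec, MarkovTraceSpec,
                                   PoreFixtureSpec, build_peptide_backbone,
                                   generate_pore_fixture,
                                   simulate_brownian_pore,
                                   simulate_dose_response,
                                   simulate_luminescence,
                                   simulate_markov_trace)


class TestPoreFixture:
    def test_cylinder_ring_geometry_exact(self):
        spec = PoreFixtureSpec(shape="cylinder", inner_radius_angstrom=3.0,
                               length_angstrom=40.0)
        st = generate_pore_fixture(spec)
        xy = st.coords[:, :2]
        ring_r = np.linalg.norm(xy, axis=1)
        # atom centre distance to axis minus vdw equals the free radius
        np.testing.assert_allclose(ring_r - spec.atom_vdw_radius_angstrom,
                                   3.0, atol=1e-12)

    def test_hourglass_throat_by_construction(self):
        spec = PoreFixtureSpec(shape="hourglass", inner_radius_angstrom=0.4,
                               mouth_radius_angstrom=4.0, length_angstrom=40.0)
        st = generate_pore_fixture(spec)
        coords = st.coords
        throat = coords[np.abs(coords[:, 2]) < 1e-9]
        ring_r = np.linalg.norm(throat[:, :2], axis=1)
        np.testing.assert_allclose(ring_r - spec.atom_vdw_radius_angstrom,
                                   0.4, atol=1e-12)
        # linear interpolation of the analytic profile
        np.testing.assert_allclose(spec.radius_at([0.0, 10.0, 20.0]),
                                   [0.4, 2.2, 4.0])

    @pytest.mark.parametrize("bad", [
        dict(inner_radius_angstrom=-1.0),
        dict(length_angstrom=0.0),
        dict(atoms_per_ring=4),
        dict(shape="hourglass", mouth_radius_angstrom=None),
    ])
    def test_validation_errors(self, bad):
        with pytest.raises(ValueError):
            generate_pore_fixture(PoreFixtureSpec(**bad))


class TestBrownian:
    def test_single_frame_equals_initial_configuration(self):
        spec = BrownianSimSpec(n_particles=10, n_frames=1, seed=3)
        traj = simulate_brownian_pore(spec)
        assert traj.n_frames == 1
        r = np.linalg.norm(traj.frames[0, :, :2], axis=1)
        assert np.all(r <= spec.pore_radius_angstrom)

    def test_deterministic_drift_limit(self):
        spec = BrownianSimSpec(n_particles=5, diffusion_coeff=0.0,
                               drift_velocity_z=-0.1, dt_ps=1.0,
                               n_frames=20, seed=0)
        traj = simulate_brownian_pore(spec)
        dz = np.diff(traj.frames[:, :, 2], axis=0)
        dz = dz[np.abs(dz) < 20]    # exclude recycling jumps
        np.testing.assert_allclose(dz, -0.1, atol=1e-12)

    def test_radial_wall_invariant(self):
        spec = BrownianSimSpec(n_particles=40, n_frames=500, seed=11,
                               diffusion_coeff=0.5)
        traj = simulate_brownian_pore(spec)
        r = np.linalg.norm(traj.frames[:, :, :2], axis=2)
        assert r.max() <= spec.pore_radius_angstrom + 1e-9

    def test_z_stays_in_bounds(self):
        spec = BrownianSimSpec(n_particles=40, n_frames=500, seed=5,
                               drift_velocity_z=-0.2)
        traj = simulate_brownian_pore(spec)
        z = traj.frames[:, :, 2]
        assert z.min() >= spec.z_bounds[0] - 1e-9
        assert z.max() <= spec.z_bounds[1] + 1e-9

    def test_same_seed_reproducible(self):
        a = simulate_brownian_pore(BrownianSimSpec(seed=9, n_frames=50))
        b = simulate_brownian_pore(BrownianSimSpec(seed=9, n_frames=50))
        np.testing.assert_array_equal(a.frames, b.frames)
        c = simulate_brownian_pore(BrownianSimSpec(seed=10, n_frames=50))
        assert not np.array_equal(a.frames, c.frames)

    def test_dt_validation(self):
        with pytest.raises(ValueError):
            simulate_brownian_pore(BrownianSimSpec(dt_ps=0.0))


class TestMarkovTrace:
    def test_open_fraction_matches_stationary_half(self):
        # symmetric rates: stationary open fraction 1/2; the empirical
        # open fraction of a 200-s record must sit within 3 SE, with the
        # correlation time tau = 1/(k_open + k_close) setting the SE
        spec = MarkovTraceSpec(open_rate=25.0, close_rate=25.0,
                               duration_s=200.0, seed=21)
        sim = simulate_markov_trace(spec)
        tau = 1.0 / (spec.open_rate + spec.close_rate)
        se = np.sqrt(2 * 0.5 * 0.5 * tau / spec.duration_s)
        assert abs(sim.po_empirical - 0.5) < 3 * se

    def test_noiseless_samples_take_exactly_two_levels(self):
        spec = MarkovTraceSpec(noise_sd_pA=0.0, duration_s=5.0, seed=2)
        sim = simulate_markov_trace(spec)
        assert set(np.unique(sim.trace.samples_pA)) <= {spec.i_open_pA,
                                                        spec.i_closed_pA}

    def test_same_seed_byte_identical(self):
        a = simulate_markov_trace(MarkovTraceSpec(seed=7, duration_s=10.0))
        b = simulate_markov_trace(MarkovTraceSpec(seed=7, duration_s=10.0))
        assert a.trace.samples_pA.tobytes() == b.trace.samples_pA.tobytes()

    def test_dwells_cover_duration(self):
        sim = simulate_markov_trace(MarkovTraceSpec(seed=4, duration_s=20.0))
        assert sim.true_dwells.duration_s == pytest.approx(20.0, abs=1e-9)

    def test_zero_rate_rejected(self):
        with pytest.raises(ValueError):
            simulate_markov_trace(MarkovTraceSpec(open_rate=0.0))


class TestLuminescence:
    def test_constant_pca_at_intercept_gives_unit_rate(self):
        # pCa = 5.5593 makes the log term vanish: k = 1/s regardless of base
        for base in (10.0, np.e):
            spec = LuminescenceSpec(pca_trajectory=(5.5593,), total_counts=1e6,
                                    log_base=base)
            series = simulate_luminescence(spec)
            assert series.counts_per_s[0] / series.total_counts == \
                pytest.approx(1.0, abs=1e-12)

    def test_counts_conservation_with_lysis(self):
        spec = LuminescenceSpec(pca_trajectory=(7.0, 6.8, 6.6),
                                total_counts=5e5)
        s = simulate_luminescence(spec)
        assert s.counts_per_s.sum() + s.lysis_counts == pytest.approx(5e5)

    def test_round_trip_through_calibration(self):
        pca = (7.2, 7.0, 6.8, 6.9, 7.1)
        s = simulate_luminescence(LuminescenceSpec(pca_trajectory=pca,
                                                   total_counts=2e6))
        cal = calibrate_calcium(s)
        np.testing.assert_allclose(cal.pca, pca, atol=1e-9)

    def test_nonfinite_pca_rejected(self):
        with pytest.raises(ValueError):
            simulate_luminescence(LuminescenceSpec(pca_trajectory=(np.nan,)))

    def test_overconsumption_rejected(self):
        # pCa far below the intercept implies k >> 1/s: impossible
        with pytest.raises(ValueError, match="consume"):
            simulate_luminescence(LuminescenceSpec(pca_trajectory=(4.0, 4.0)))


class TestDoseResponse:
    def test_midpoint_and_limits_noiseless(self):
        spec = DoseResponseSpec(e_min=10.0, e_max=90.0, ic50_uM=1.0,
                                hill=1.5, noise_sd=0.0, n_replicates=1,
                                concentrations_uM=(1e-6, 1.0, 1e6, 2.0))
        ds = simulate_dose_response(spec)
        eff = dict(zip(ds.data["conc_uM"], ds.data["effect"]))
        assert eff[1.0] == pytest.approx(50.0)          # (E_max + E_min) / 2
        assert eff[1e-6] == pytest.approx(90.0, abs=1e-3)   # c -> 0: E_max
        assert eff[1e6] == pytest.approx(10.0, abs=1e-3)    # c -> inf: E_min

    def test_same_seed_identical(self):
        a = simulate_dose_response(DoseResponseSpec(seed=3))
        b = simulate_dose_response(DoseResponseSpec(seed=3))
        assert a.data.equals(b.data)

    def test_validation(self):
        with pytest.raises(ValueError):
            simulate_dose_response(DoseResponseSpec(ic50_uM=-0.5))
        with pytest.raises(ValueError):
            simulate_dose_response(DoseResponseSpec(concentrations_uM=(0.0, 1.0)))


class TestPeptideBuilder:
    def test_alpha_helix_backbone_geometry(self):
        st = build_peptide_backbone([(-57.0, -47.0)] * 10)
        # realised phi/psi must equal the requested dihedrals
        from channelgate._geometry import dihedral_deg

        tab = {}
        for a in st.atoms:
            tab.setdefault(a.resnum, {})[a.name] = a.pos
        for i in range(2, 9):
            phi = dihedral_deg(tab[i - 1]["C"], tab[i]["N"], tab[i]["CA"],
                               tab[i]["C"])
            psi = dihedral_deg(tab[i]["N"], tab[i]["CA"], tab[i]["C"],
                               tab[i + 1]["N"])
            assert phi == pytest.approx(-57.0, abs=1e-6)
            assert psi == pytest.approx(-47.0, abs=1e-6)
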