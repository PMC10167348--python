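"""Synthetic fixtures with known ground truth for every pipeline stage.

Each generator emulates one experimental data stream at desk scale:

* pseudo-atom pores with an analytically known radius profile (for the
  HOLE-style profiler);
* Brownian particles drifting through a cylindrical pore — a counting
  surrogate for applied-voltage MD, with known steady-state flux;
* two-state Markov gating currents with Gaussian noise (bilayer
  recordings, open probabilities spanning ~0.02-0.63);
* aequorin luminescence series consistent with the pCa calibration line;
* logistic dose-response datasets.

All randomness flows through a single numpy ``default_rng`` seeded
explicitly (default seed 0), so identical specs give byte-identical
output on any platform.  Peptide-backbone fixtures for secondary-
structure tests are built from ideal internal coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._geometry import place_atom
from .ephys import CurrentTrace, Dwell, IdealizedTrace
from .flux import (DoseResponseDataset, LuminescenceSeries, logistic_effect,
                   pca_to_rate)
from .structures import Atom, Structure
from .trajectories import Trajectory

__all__ = [
    "PoreFixtureSpec",
    "BrownianSimSpec",
    "MarkovTraceSpec",
    "LuminescenceSpec",
    "DoseResponseSpec",
    "generate_pore_fixture",
    "simulate_brownian_pore",
    "simulate_markov_trace",
    "simulate_luminescence",
    "simulate_dose_response",
    "build_peptide_backbone",
]

# ideal trans-peptide internal coordinates (angstrom / degrees)
_BOND_N_CA = 1.458
_BOND_CA_C = 1.525
_BOND_C_N = 1.329
_BOND_C_O = 1.231
_ANGLE_N_CA_C = 111.2
_ANGLE_CA_C_N = 116.2
_ANGLE_C_N_CA = 121.7
_ANGLE_CA_C_O = 120.5
_OMEGA = 180.0


@dataclass(frozen=True)
class PoreFixtureSpec:
    """Geometry of a pseudo-atom pore with a known free-radius profile.

    ``cylinder`` has constant inner radius; ``hourglass`` interpolates
    linearly in z from the mouth radius at both ends to the throat
    radius at z = 0.
    """

    shape: str = "cylinder"                # "cylinder" | "hourglass"
    inner_radius_angstrom: float = 3.0     # cylinder radius / hourglass throat
    mouth_radius_angstrom: float | None = None  # hourglass only
    length_angstrom: float = 40.0
    atom_vdw_radius_angstrom: float = 1.7
    axial_step_angstrom: float = 0.5
    atoms_per_ring: int = 48

    def validate(self) -> None:
        if self.shape not in ("cylinder", "hourglass"):
            raise ValueError(f"unknown pore shape {self.shape!r}")
        if self.inner_radius_angstrom <= 0:
            raise ValueError("inner radius must be positive")
        if self.shape == "hourglass":
            if self.mouth_radius_angstrom is None or self.mouth_radius_angstrom <= 0:
                raise ValueError("hourglass needs a positive mouth radius")
        if self.length_angstrom <= 0:
            raise ValueError("length must be positive")
        if self.atom_vdw_radius_angstrom <= 0:
            raise ValueError("vdw radius must be positive")
        if self.axial_step_angstrom <= 0:
            raise ValueError("axial step must be positive")
        if self.atoms_per_ring < 8:
            raise ValueError("need at least 8 atoms per ring")

    def radius_at(self, z) -> np.ndarray:
        """Analytic free (maximal-sphere) radius of the fixture at z."""
        z = np.asarray(z, dtype=float)
        if self.shape == "cylinder":
            return np.full_like(z, self.inner_radius_angstrom)
        half = self.length_angstrom / 2.0
        frac = np.clip(np.abs(z) / half, 0.0, 1.0)
        return (self.inner_radius_angstrom
                + (self.mouth_radius_angstrom - self.inner_radius_angstrom) * frac)


def generate_pore_fixture(spec: PoreFixtureSpec) -> Structure:
    """Rings of pseudo-atoms whose maximal free sphere matches the spec.

    Atom centers sit at ring radius = target free radius + vdw radius, so
    the free radius on the axis equals the spec profile by construction.
    Each ring is one residue (resname PSE, element C), which gives the
    profiler meaningful nearest-residue labels.
    """
    spec.validate()
    half = spec.length_angstrom / 2.0
    zs = np.arange(-half, half + 0.5 * spec.axial_step_angstrom,
                   spec.axial_step_angstrom)
    angles = np.linspace(0.0, 2.0 * np.pi, spec.atoms_per_ring, endpoint=False)
    atoms: list[Atom] = []
    for ires, z in enumerate(zs, start=1):
        ring_r = float(spec.radius_at(z)) + spec.atom_vdw_radius_angstrom
        for j, th in enumerate(angles):
            atoms.append(Atom(
                chain="A", resnum=ires, resname="PSE", name=f"C{j}",
                element="C",
                pos=np.array([ring_r * np.cos(th), ring_r * np.sin(th), z]),
            ))
    return Structure(atoms, name=f"{spec.shape}-pore-fixture")


@dataclass(frozen=True)
class BrownianSimSpec:
    """Brownian particles in a cylindrical pore with optional axial drift.

    The drift velocity stands in for the electrophoretic velocity under
    an applied membrane voltage; defaults give diffusion comparable to
    bulk water (0.2 A^2/ps) over a 40-A pore, with drift chosen so on
    the order of a hundred crossings occur within a desk-scale run.
    The 1-ps snapshot stride keeps the per-frame diffusive step (~0.6 A)
    small against the 2-A gap between the exit plane and the recycling
    bound, so plane crossings are resolved frame by frame.
    """

    n_particles: int = 50
    diffusion_coeff: float = 0.2       # A^2/ps
    dt_ps: float = 1.0
    n_frames: int = 2000
    drift_velocity_z: float = 0.0      # A/ps (negative = downward field)
    pore_radius_angstrom: float = 4.0
    z_bounds: tuple[float, float] = (-20.0, 20.0)
    reflecting_walls: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_particles < 1:
            raise ValueError("need at least one particle")
        if self.diffusion_coeff < 0:
            raise ValueError("diffusion coefficient must be non-negative")
        if self.dt_ps <= 0:
            raise ValueError("dt must be positive")
        if self.n_frames < 1:
            raise ValueError("need at least one frame")
        if self.pore_radius_angstrom <= 0:
            raise ValueError("pore radius must be positive")
        if self.z_bounds[1] <= self.z_bounds[0]:
            raise ValueError("z bounds must be increasing")

    @property
    def expected_crossing_rate_per_ps(self) -> float:
        """Steady-state drift flux: line density times drift speed.

        Particles are recycled at the z bounds, so the mean number of
        complete passes per unit time is n * |v| / L.
        """
        L = self.z_bounds[1] - self.z_bounds[0]
        return self.n_particles * abs(self.drift_velocity_z) / L


def _uniform_disk(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    r = radius * np.sqrt(rng.uniform(size=n))
    th = rng.uniform(0.0, 2.0 * np.pi, size=n)
    return np.column_stack([r * np.cos(th), r * np.sin(th)])


def simulate_brownian_pore(spec: BrownianSimSpec) -> Trajectory:
    """Overdamped Brownian dynamics in a cylinder.

    Radial wall: specular fold (r -> 2R - r) when a step leaves the
    cylinder.  Axial recycling: a particle crossing a z bound teleports
    to the opposite bound with a freshly drawn radial position — this
    keeps the steady-state flux well defined and is intentionally a jump
    discontinuity so permeation counters can recognise (and must not
    count) the recycling move.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    zlo, zhi = spec.z_bounds
    L = zhi - zlo
    n = spec.n_particles

    xy = _uniform_disk(rng, n, spec.pore_radius_angstrom)
    z = rng.uniform(zlo, zhi, size=n)
    pos = np.column_stack([xy, z])

    frames = np.empty((spec.n_frames, n, 3))
    frames[0] = pos
    sigma = np.sqrt(2.0 * spec.diffusion_coeff * spec.dt_ps)
    for i in range(1, spec.n_frames):
        step = sigma * rng.standard_normal((n, 3)) if sigma > 0 else np.zeros((n, 3))
        step[:, 2] += spec.drift_velocity_z * spec.dt_ps
        pos = pos + step
        if spec.reflecting_walls:
            r = np.hypot(pos[:, 0], pos[:, 1])
            out = r > spec.pore_radius_angstrom
            if np.any(out):
                # specular fold, repeated in the rare multi-bounce case
                rr = r[out]
                R = spec.pore_radius_angstrom
                while np.any(rr > R):
                    rr = np.where(rr > R, 2.0 * R - rr, rr)
                rr = np.abs(rr)
                scale = rr / r[out]
                pos[out, 0] *= scale
                pos[out, 1] *= scale
        # periodic wrap in z ("teleport to the opposite bound"), with a
        # fresh radial position so the recycled particle is uncorrelated
        for mask, shift in ((pos[:, 2] < zlo, L), (pos[:, 2] > zhi, -L)):
            if np.any(mask):
                k = int(mask.sum())
                pos[mask, 2] = np.clip(pos[mask, 2] + shift,
                                       zlo + 1e-9 * L, zhi - 1e-9 * L)
                pos[mask, :2] = _uniform_disk(rng, k, spec.pore_radius_angstrom)
        frames[i] = pos
    times = np.arange(spec.n_frames) * spec.dt_ps
    return Trajectory(frames, times, [f"P{i}" for i in range(n)],
                      box=np.array([2 * spec.pore_radius_angstrom,
                                    2 * spec.pore_radius_angstrom, L]))


@dataclass(frozen=True)
class MarkovTraceSpec:
    """Two-state (closed <-> open) continuous-time Markov gating current.

    The stationary open probability is open_rate / (open_rate +
    close_rate) — the generator's ground truth.  Defaults mirror a
    bilayer recording: ~-5 pA unitary current at the holding potential,
    noise giving SNR 10, 2 kHz digitisation, 200-s records.
    """

    open_rate: float = 10.0        # closed -> open, 1/s
    close_rate: float = 40.0       # open -> closed, 1/s
    i_open_pA: float = -5.0
    i_closed_pA: float = 0.0
    noise_sd_pA: float = 0.5
    sampling_rate_Hz: float = 2000.0
    duration_s: float = 200.0
    seed: int = 0

    def validate(self) -> None:
        if self.open_rate <= 0 or self.close_rate <= 0:
            raise ValueError("transition rates must be positive")
        if self.sampling_rate_Hz <= 0:
            raise ValueError("sampling rate must be positive")
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")
        if self.noise_sd_pA < 0:
            raise ValueError("noise SD must be non-negative")

    @property
    def po_true(self) -> float:
        return self.open_rate / (self.open_rate + self.close_rate)


@dataclass
class SimulatedTrace:
    """A gating current plus its ground-truth dwell segmentation."""

    trace: CurrentTrace
    true_dwells: IdealizedTrace
    po_true: float                 # analytic stationary open probability

    @property
    def po_empirical(self) -> float:
        """Open fraction actually realised in this finite record."""
        return self.true_dwells.po


def simulate_markov_trace(spec: MarkovTraceSpec) -> SimulatedTrace:
    """Exact CTMC dwell sampling, then uniform digitisation plus noise."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    p_open = spec.po_true
    state = bool(rng.uniform() < p_open)   # stationary initial state

    # alternate exponential dwells until the record is covered
    bounds = [0.0]
    states: list[bool] = []
    t = 0.0
    s = state
    while t < spec.duration_s:
        rate = spec.close_rate if s else spec.open_rate
        dwell = rng.exponential(1.0 / rate)
        t += dwell
        states.append(s)
        bounds.append(min(t, spec.duration_s))
        s = not s
    bounds_arr = np.array(bounds)

    n = int(round(spec.duration_s * spec.sampling_rate_Hz))
    ts = (np.arange(n) + 0.5) / spec.sampling_rate_Hz
    idx = np.clip(np.searchsorted(bounds_arr, ts, side="right") - 1,
                  0, len(states) - 1)
    open_mask = np.array(states, dtype=bool)[idx]
    samples = np.where(open_mask, spec.i_open_pA, spec.i_closed_pA).astype(float)
    if spec.noise_sd_pA > 0:
        samples += spec.noise_sd_pA * rng.standard_normal(n)

    trace = CurrentTrace(samples, spec.sampling_rate_Hz,
                         metadata={"generator": "two-state-markov",
                                   "seed": spec.seed})
    dwells = [Dwell("open" if s else "closed", float(e - b))
              for s, b, e in zip(states, bounds_arr[:-1], bounds_arr[1:])
              if e > b]
    return SimulatedTrace(trace, IdealizedTrace(dwells, spec.sampling_rate_Hz),
                          p_open)


@dataclass(frozen=True)
class LuminescenceSpec:
    """Aequorin count series for a prescribed pCa trajectory.

    Each 1-s interval emits counts = k * total_counts where k inverts
    the calibration line for that interval's pCa; whatever photoprotein
    is left emits in the terminal lysis bin.  Optional Gaussian noise on
    the per-interval counts models shot/readout scatter.
    """

    pca_trajectory: tuple[float, ...] = (7.0, 6.9, 6.8, 6.7, 6.6)
    total_counts: float = 1e6
    log_base: float = 10.0
    noise_sd_counts: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        traj = np.asarray(self.pca_trajectory, dtype=float)
        if traj.size == 0 or not np.all(np.isfinite(traj)):
            raise ValueError("pCa trajectory must be non-empty and finite")
        if self.total_counts <= 0:
            raise ValueError("total counts must be positive")
        if self.log_base <= 1:
            raise ValueError("log base must exceed 1")


def simulate_luminescence(spec: LuminescenceSpec) -> LuminescenceSeries:
    spec.validate()
    pca = np.asarray(spec.pca_trajectory, dtype=float)
    k = pca_to_rate(pca, log_base=spec.log_base)
    if k.sum() > 1.0 + 1e-12:
        raise ValueError(
            "pCa trajectory would consume more photoprotein than exists "
            f"(sum of per-second rates {k.sum():.3g} > 1); raise the pCa "
            "values or shorten the trajectory")
    counts = k * spec.total_counts
    if spec.noise_sd_counts > 0:
        rng = np.random.default_rng(spec.seed)
        counts = np.clip(
            counts + spec.noise_sd_counts * rng.standard_normal(counts.size),
            0.0, None)
    lysis = spec.total_counts - counts.sum()
    return LuminescenceSeries(counts, float(lysis), spec.total_counts)


@dataclass(frozen=True)
class DoseResponseSpec:
    """Logistic concentration-response data with replicate noise.

    Defaults mirror a Ca2+-influx inhibition experiment: IC50 a few
    hundred nanomolar, Hill slope near 1, effects on a 0-100 scale,
    eight half-log-spaced concentrations, six replicates, 5% noise.
    """

    e_min: float = 0.0
    e_max: float = 100.0
    ic50_uM: float = 0.23
    hill: float = 1.2
    concentrations_uM: tuple[float, ...] = (
        0.01, 0.03, 0.1, 0.3, 1.0, 3.0, 10.0, 30.0)
    n_replicates: int = 6
    noise_sd: float = 5.0          # assay units (5% of the 0-100 span)
    direction: str = "inhibition"
    seed: int = 0

    def validate(self) -> None:
        if self.ic50_uM <= 0:
            raise ValueError("IC50 must be positive")
        if any(c <= 0 for c in self.concentrations_uM):
            raise ValueError("concentrations must be strictly positive")
        if self.e_max < self.e_min:
            raise ValueError("e_max must be >= e_min")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be non-negative")


def simulate_dose_response(spec: DoseResponseSpec) -> DoseResponseDataset:
    import pandas as pd

    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rows = []
    for rep in range(spec.n_replicates):
        for c in spec.concentrations_uM:
            e = float(logistic_effect(c, spec.e_min, spec.e_max, spec.ic50_uM,
                                      spec.hill, direction=spec.direction))
            if spec.noise_sd > 0:
                e += spec.noise_sd * rng.standard_normal()
            rows.append({"conc_uM": c, "effect": e, "replicate": rep})
    return DoseResponseDataset(pd.DataFrame(rows))


def build_peptide_backbone(phi_psi: list[tuple[float, float]],
                           resname: str = "ALA",
                           chain: str = "A") -> Structure:
    """Poly-peptide backbone (N, CA, C, O) from per-residue (phi, psi).

    Built with ideal trans-peptide internal coordinates; intended as a
    secondary-structure fixture (e.g. an ideal alpha helix at
    phi = -57, psi = -47, or a pi-helical stretch spliced into it).
    phi of the first residue and psi of the last are not realisable and
    are ignored.
    """
    n_res = len(phi_psi)
    if n_res < 2:
        raise ValueError("need at least two residues")
    # seed the first three backbone atoms
    coords: dict[tuple[int, str], np.ndarray] = {}
    coords[(0, "N")] = np.array([0.0, 0.0, 0.0])
    coords[(0, "CA")] = np.array([_BOND_N_CA, 0.0, 0.0])
    ang = np.radians(180.0 - _ANGLE_N_CA_C)
    coords[(0, "C")] = coords[(0, "CA")] + _BOND_CA_C * np.array(
        [np.cos(ang), np.sin(ang), 0.0])

    for i in range(n_res):
        phi, psi = phi_psi[i]
        if i > 0:
            coords[(i, "N")] = place_atom(
                coords[(i - 1, "N")], coords[(i - 1, "CA")], coords[(i - 1, "C")],
                _BOND_C_N, _ANGLE_CA_C_N, phi_psi[i - 1][1])           # psi(i-1)
            coords[(i, "CA")] = place_atom(
                coords[(i - 1, "CA")], coords[(i - 1, "C")], coords[(i, "N")],
                _BOND_N_CA, _ANGLE_C_N_CA, _OMEGA)                     # omega
            coords[(i, "C")] = place_atom(
                coords[(i - 1, "C")], coords[(i, "N")], coords[(i, "CA")],
                _BOND_CA_C, _ANGLE_N_CA_C, phi)                        # phi(i)
        # carbonyl O: anti to the next N along psi
        psi_eff = phi_psi[i][1] if i < n_res - 1 else -47.0
        coords[(i, "O")] = place_atom(
            coords[(i, "N")], coords[(i, "CA")], coords[(i, "C")],
            _BOND_C_O, _ANGLE_CA_C_O, psi_eff + 180.0)

    atoms = []
    for i in range(n_res):
        for name, el in (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")):
            atoms.append(Atom(chain=chain, resnum=i + 1, resname=resname,
                              name=name, element=el, pos=coords[(i, name)]))
    return Structure(atoms, name="peptide-backbone-fixture")
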