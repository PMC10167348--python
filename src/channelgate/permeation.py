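"""MD trajectory post-processing for channel permeation and gating.

The workflow mirrors standard applied-voltage permeation analysis:
frames are aligned so the pore reference (by convention the centre of
mass of the four Y1085 Calpha atoms) sits at the origin; particle z
series are then scanned by a per-particle finite-state machine that
counts complete entry-plane -> exit-plane passages (water: entry
z = -2 A, exit z = -18 A for downward passage; ions: entry -18 A, exit
+18 A upward).  Counts per ~60-ns block give permeation rates; ion
counts under voltage give the conductance g = N e / (T V).  Side-chain
chi1 rotamer series and hydrogen-bond occupancies complete the gating
picture.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._geometry import (amide_hydrogen, dihedral_deg_frames,
                        sp2_amide_hydrogens)
from .structures import Selection, Structure, select_atoms
from .trajectories import Trajectory

__all__ = [
    "AlignmentRef",
    "PermeationRule",
    "PermeationEvent",
    "PermeationSummary",
    "OccupancyGrid",
    "ConductanceEstimate",
    "TorsionSeries",
    "HBondSeries",
    "align_frames",
    "count_permeation_events",
    "permeation_rates",
    "water_occupancy_grid",
    "estimate_conductance",
    "chi1_series",
    "hbond_occupancy",
]

ELEMENTARY_CHARGE_C = 1.602176634e-19

#: chi1 terminal atom by residue type (N-CA-CB-<this>)
CHI1_GAMMA_ATOM = {
    "VAL": "CG1", "ILE": "CG1", "THR": "OG1", "SER": "OG", "CYS": "SG",
}


@dataclass(frozen=True)
class AlignmentRef:
    """Reference for frame alignment.

    Default mode translates every frame so the centre of mass of the
    reference atoms is at the origin; ``superposition`` additionally
    removes rotation against the first frame.
    """

    atom_indices: tuple[int, ...]
    mode: str = "translate"        # "translate" | "superposition"

    def __post_init__(self):
        if not self.atom_indices:
            raise ValueError("alignment reference must be non-empty")
        if self.mode not in ("translate", "superposition"):
            raise ValueError(f"unknown alignment mode {self.mode!r}")

    @classmethod
    def from_selection(cls, structure: Structure, selection: Selection,
                       mode: str = "translate") -> "AlignmentRef":
        """Reference from a selection on the topology structure, assuming
        trajectory atom i corresponds to ``structure.atoms[i]``."""
        wanted = {id(a) for a in select_atoms(structure, selection)}
        idx = tuple(i for i, a in enumerate(structure.atoms) if id(a) in wanted)
        if not idx:
            raise ValueError("alignment selection matched no atoms")
        return cls(idx, mode)


def align_frames(traj: Trajectory, ref: AlignmentRef) -> Trajectory:
    """Align every frame on the reference centre of mass (at the origin)."""
    idx = np.array(ref.atom_indices)
    if idx.max() >= traj.n_atoms:
        raise ValueError("alignment reference index outside the atom roster")
    com = traj.frames[:, idx, :].mean(axis=1)
    out = traj.frames - com[:, None, :]
    if ref.mode == "superposition":
        from ._geometry import kabsch
        ref_coords = out[0][idx]
        aligned = np.empty_like(out)
        aligned[0] = out[0]
        for i in range(1, out.shape[0]):
            R, t, _ = kabsch(out[i][idx], ref_coords)
            aligned[i] = out[i] @ R.T + t
        out = aligned
    return Trajectory(out, traj.times_ps.copy(), list(traj.atom_names), traj.box)


@dataclass(frozen=True)
class PermeationRule:
    """Entry/exit planes along z and the direction(s) to count.

    For ``direction='downward'`` the exit plane must lie below the entry
    plane; 'upward' the reverse.  With ``direction='both'`` the given
    pair defines the downward passage and the mirrored pair (entry at
    the lower plane, exit at the upper) defines the upward one.
    ``wrap_jump`` (angstrom): a z jump larger than this between
    consecutive frames is treated as a periodic/recycling move — it
    resets the particle's state and never counts as a crossing.
    """

    entry_z: float
    exit_z: float
    direction: str = "downward"      # downward | upward | both
    region_z: tuple[float, float] = (-20.0, 20.0)
    wrap_jump: float | None = None

    def __post_init__(self):
        if self.entry_z == self.exit_z:
            raise ValueError("entry and exit planes must differ")
        if self.direction not in ("downward", "upward", "both"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.direction == "downward" and not self.exit_z < self.entry_z:
            raise ValueError("downward passage needs exit below entry")
        if self.direction == "upward" and not self.exit_z > self.entry_z:
            raise ValueError("upward passage needs exit above entry")
        if self.direction == "both" and not self.exit_z < self.entry_z:
            raise ValueError(
                "with direction='both', give the downward pair (exit below "
                "entry); the upward pair is its mirror")

    def plane_pairs(self) -> list[tuple[float, float, str]]:
        """(entry, exit, direction) pairs actually scanned."""
        if self.direction == "downward":
            return [(self.entry_z, self.exit_z, "downward")]
        if self.direction == "upward":
            return [(self.entry_z, self.exit_z, "upward")]
        return [(self.entry_z, self.exit_z, "downward"),
                (self.exit_z, self.entry_z, "upward")]


@dataclass(frozen=True)
class PermeationEvent:
    particle: int
    entry_frame: int
    exit_frame: int
    direction: str
    exit_time_ps: float

    def __post_init__(self):
        if self.exit_frame <= self.entry_frame:
            raise ValueError("exit frame must follow entry frame")


@dataclass
class PermeationSummary:
    events_per_block: np.ndarray
    block_ns: float
    rates_per_ns: np.ndarray
    mean_rate_per_ns: float
    sd_rate_per_ns: float
    total_events: int
    partial_last_block: bool

    def __post_init__(self):
        if int(self.events_per_block.sum()) != self.total_events:
            raise ValueError("block counts must sum to the total")


def _scan_particle(z: np.ndarray, times: np.ndarray, particle: int,
                   entry: float, exit_: float, direction: str,
                   wrap_jump: float | None) -> list[PermeationEvent]:
    """Finite-state machine over one particle's z series.

    idle -> armed on crossing the entry plane toward the exit; an event
    fires on the subsequent exit-plane crossing; re-crossing the entry
    plane first disarms.  Crossings are sign changes between consecutive
    frames (no interpolation); jumps larger than ``wrap_jump`` reset the
    machine without counting.
    """
    down = direction == "downward"
    events: list[PermeationEvent] = []
    armed = False
    entry_frame = -1
    for i in range(1, z.size):
        z0, z1 = z[i - 1], z[i]
        if wrap_jump is not None and abs(z1 - z0) > wrap_jump:
            armed = False
            continue
        if down:
            crossed_entry_fwd = z0 > entry >= z1
            crossed_entry_back = z0 <= entry < z1
            crossed_exit = z0 > exit_ >= z1
        else:
            crossed_entry_fwd = z0 < entry <= z1
            crossed_entry_back = z0 >= entry > z1
            crossed_exit = z0 < exit_ <= z1
        if armed and crossed_exit:
            events.append(PermeationEvent(particle, entry_frame, i, direction,
                                          float(times[i])))
            armed = False
            # the same step may immediately re-cross the entry plane of
            # the opposite sense; state restarts cleanly from idle
        if crossed_entry_fwd:
            armed = True
            entry_frame = i
        elif armed and crossed_entry_back:
            armed = False
    return events


def count_permeation_events(traj: Trajectory, rule: PermeationRule,
                            particles: np.ndarray | None = None
                            ) -> list[PermeationEvent]:
    """Count complete entry -> exit passages for every particle.

    ``particles`` restricts the scan to a subset of roster indices
    (e.g. only the water oxygens, or only anions).  Frames must be time
    sorted; each particle can contribute any number of events.
    """
    if np.any(np.diff(traj.times_ps) < 0):
        raise ValueError("trajectory frames are not time-sorted")
    idx = np.arange(traj.n_atoms) if particles is None else np.asarray(particles)
    wrap = rule.wrap_jump
    if wrap is None and traj.box is not None:
        wrap = 0.5 * float(traj.box[2])
    events: list[PermeationEvent] = []
    zall = traj.frames[:, :, 2]
    for p in idx:
        z = zall[:, p]
        for entry, exit_, direction in rule.plane_pairs():
            events.extend(_scan_particle(z, traj.times_ps, int(p), entry,
                                         exit_, direction, wrap))
    events.sort(key=lambda e: (e.exit_frame, e.particle))
    return events


def permeation_rates(events: list[PermeationEvent], total_time_ns: float,
                     block_ns: float = 60.0,
                     discard_initial_ns: float = 0.0) -> PermeationSummary:
    """Per-block permeation rates from event exit times.

    Events are binned by exit time into consecutive ``block_ns`` blocks
    after discarding the initial ``discard_initial_ns`` (events and time
    both); a trailing partial block is kept and flagged.
    """
    if block_ns <= 0:
        raise ValueError("block length must be positive")
    span = total_time_ns - discard_initial_ns
    if span <= 0:
        raise ValueError("no analysis time left after the discard window")
    n_blocks = max(int(np.ceil(span / block_ns - 1e-9)), 1)
    partial = span / block_ns < n_blocks - 1e-9 or span < block_ns
    counts = np.zeros(n_blocks, dtype=int)
    for ev in events:
        t_ns = ev.exit_time_ps * 1e-3
        if t_ns < discard_initial_ns:
            continue
        b = min(int((t_ns - discard_initial_ns) / block_ns), n_blocks - 1)
        counts[b] += 1
    lengths = np.full(n_blocks, block_ns)
    if span < n_blocks * block_ns:
        lengths[-1] = span - (n_blocks - 1) * block_ns
        partial = True
    rates = counts / lengths
    return PermeationSummary(
        counts, block_ns, rates, float(rates.mean()),
        float(rates.std(ddof=1)) if n_blocks > 1 else 0.0,
        int(counts.sum()), bool(partial))


@dataclass
class OccupancyGrid:
    """Voxelised particle observation counts inside a rectangular region."""

    counts: np.ndarray
    edges: tuple[np.ndarray, np.ndarray, np.ndarray]
    voxel_angstrom: float
    normalization: str            # "counts" | "fraction"
    n_frames: int

    @property
    def values(self) -> np.ndarray:
        if self.normalization == "fraction":
            return self.counts / self.n_frames
        return self.counts

    def to_dx(self, path) -> None:
        """Write the grid as OpenDX (for volumetric viewers)."""
        from gridData import Grid

        origin = [float(e[0] + 0.5 * self.voxel_angstrom) for e in self.edges]
        g = Grid(self.values.astype(float), origin=origin,
                 delta=[self.voxel_angstrom] * 3)
        g.export(str(path), file_format="dx")


def water_occupancy_grid(traj: Trajectory,
                         region: tuple[tuple[float, float], ...] = (
                             (-10.0, 10.0), (-10.0, 10.0), (-20.0, 20.0)),
                         voxel_angstrom: float = 0.5,
                         particles: np.ndarray | None = None,
                         normalization: str = "counts") -> OccupancyGrid:
    """3-D occupancy histogram of particle positions over all frames.

    The grid sum equals the number of (frame, particle) observations
    inside the region; ``fraction`` mode divides by the frame count.
    """
    if voxel_angstrom <= 0:
        raise ValueError("voxel size must be positive")
    if normalization not in ("counts", "fraction"):
        raise ValueError("normalization must be 'counts' or 'fraction'")
    idx = np.arange(traj.n_atoms) if particles is None else np.asarray(particles)
    pts = traj.frames[:, idx, :].reshape(-1, 3)
    edges = tuple(
        np.arange(lo, hi + 0.5 * voxel_angstrom, voxel_angstrom)
        for lo, hi in region)
    counts, _ = np.histogramdd(pts, bins=edges)
    return OccupancyGrid(counts, edges, voxel_angstrom, normalization,
                         traj.n_frames)


@dataclass
class ConductanceEstimate:
    n_events: int
    time_ns: float
    voltage_mV: float
    current_pA: float
    conductance_pS: float

    def __post_init__(self):
        if self.conductance_pS < 0:
            raise ValueError("conductance cannot be negative")


def estimate_conductance(n_events: int, time_ns: float,
                         voltage_mV: float) -> ConductanceEstimate:
    """Single-channel conductance from ion crossings under voltage.

    I (pA) = N e / T and g (pS) = I / V in consistent units.  The sign
    convention: N counts charge moved with the field, so g is reported
    as a magnitude (a negative voltage driving downward events still
    yields positive conductance).
    """
    if voltage_mV == 0:
        raise ValueError("conductance is undefined at zero voltage")
    if time_ns <= 0:
        raise ValueError("simulated time must be positive")
    if n_events < 0:
        raise ValueError("event count cannot be negative")
    current_A = n_events * ELEMENTARY_CHARGE_C / (time_ns * 1e-9)
    current_pA = current_A * 1e12
    conductance_pS = abs(current_pA / (voltage_mV * 1e-3))
    return ConductanceEstimate(n_events, time_ns, voltage_mV,
                               current_pA, conductance_pS)


@dataclass
class TorsionSeries:
    chain: str
    resnum: int
    resname: str
    name: str                    # e.g. "chi1"
    angles_deg: np.ndarray       # per frame, wrapped to (-180, 180]
    circular_mean_deg: float
    circular_sd_deg: float
    label: str                   # "stable" | "fluctuating"


def _atom_index(structure: Structure, chain: str, resnum: int, name: str) -> int:
    for i, a in enumerate(structure.atoms):
        if a.chain == chain and a.resnum == resnum and a.name == name:
            return i
    raise KeyError(f"atom {chain}/{resnum}/{name} not found in topology")


def chi1_series(structure: Structure, traj: Trajectory, chain: str,
                resnum: int, stable_sd_deg: float = 20.0,
                wells_deg: tuple[float, float] = (-80.0, -180.0),
                well_halfwidth_deg: float = 25.0) -> TorsionSeries:
    """Per-frame chi1 (N-CA-CB-CG) rotamer series with circular stats.

    The residue is labelled ``fluctuating`` when the angle visits both
    rotamer wells (default -80 and -180 degrees, +/-25) within the
    series, ``stable`` when it stays in one well with circular SD at or
    below ``stable_sd_deg``.
    """
    res_atoms = [a for a in structure.atoms
                 if a.chain == chain and a.resnum == resnum]
    if not res_atoms:
        raise KeyError(f"residue {chain}/{resnum} not in topology")
    resname = res_atoms[0].resname
    gamma = CHI1_GAMMA_ATOM.get(resname, "CG")
    names = ["N", "CA", "CB", gamma]
    try:
        idx = [_atom_index(structure, chain, resnum, n) for n in names]
    except KeyError as exc:
        raise KeyError(f"chi1 atoms missing for {chain}/{resname} {resnum}: "
                       f"{exc}") from exc
    p = traj.frames[:, idx, :]
    angles = dihedral_deg_frames(p[:, 0], p[:, 1], p[:, 2], p[:, 3])

    from scipy.stats import circmean, circstd

    cm = float(circmean(angles, high=180.0, low=-180.0))
    cs = float(circstd(angles, high=180.0, low=-180.0))

    def in_well(center: float) -> np.ndarray:
        d = np.abs((angles - center + 180.0) % 360.0 - 180.0)
        return d <= well_halfwidth_deg

    visits_both = bool(in_well(wells_deg[0]).any() and in_well(wells_deg[1]).any())
    if visits_both:
        label = "fluctuating"
    elif cs <= stable_sd_deg:
        label = "stable"
    else:
        label = "fluctuating"
    return TorsionSeries(chain, resnum, resname, "chi1", angles, cm, cs, label)


@dataclass
class HBondSeries:
    donor: tuple[str, int, str]
    acceptor: tuple[str, int, str]
    bonded: np.ndarray            # bool per frame
    occupancy: float

    def __post_init__(self):
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must lie in [0, 1]")


#: sp2 side-chain amide donors: donor N -> (stem carbon, plane-defining O)
_SIDECHAIN_AMIDE = {
    ("ASN", "ND2"): ("CG", "OD1"),
    ("GLN", "NE2"): ("CD", "OE1"),
}


def hbond_occupancy(structure: Structure, traj: Trajectory,
                    donor: tuple[str, int, str],
                    acceptor: tuple[str, int, str],
                    max_da_angstrom: float = 3.5,
                    min_dha_deg: float = 150.0) -> HBondSeries:
    """Frame-wise hydrogen-bond occupancy between a donor and an acceptor.

    Criterion: donor-acceptor distance <= 3.5 angstrom and a
    donor-H-acceptor angle >= 150 degrees.  When the model carries no
    hydrogens they are reconstructed geometrically per frame: backbone
    amides from C(prev)/N/CA, side-chain amides (ASN ND2, GLN NE2) from
    the amide plane; all candidate H positions are tried and the best
    angle used.
    """
    d_chain, d_res, d_name = donor
    a_chain, a_res, a_name = acceptor
    di = _atom_index(structure, d_chain, d_res, d_name)
    ai = _atom_index(structure, a_chain, a_res, a_name)
    d_resname = structure.atoms[di].resname

    # indices needed to rebuild the donor hydrogens each frame
    h_index = None
    rebuild = None
    try:
        h_index = _atom_index(structure, d_chain, d_res,
                              "H" if d_name == "N" else f"H{d_name[1:]}1")
    except KeyError:
        if d_name == "N":
            prev_c = _atom_index(structure, d_chain, d_res - 1, "C")
            ca = _atom_index(structure, d_chain, d_res, "CA")
            rebuild = ("backbone", prev_c, ca)
        elif (d_resname, d_name) in _SIDECHAIN_AMIDE:
            stem_name, plane_name = _SIDECHAIN_AMIDE[(d_resname, d_name)]
            stem = _atom_index(structure, d_chain, d_res, stem_name)
            plane = _atom_index(structure, d_chain, d_res, plane_name)
            rebuild = ("sp2", stem, plane)
        else:
            raise KeyError(
                f"cannot place hydrogens on donor {d_resname} {d_name}; "
                "provide a structure with explicit hydrogens")

    bonded = np.zeros(traj.n_frames, dtype=bool)
    for f in range(traj.n_frames):
        dpos = traj.frames[f, di]
        apos = traj.frames[f, ai]
        if np.linalg.norm(dpos - apos) > max_da_angstrom:
            continue
        if h_index is not None:
            hs = [traj.frames[f, h_index]]
        elif rebuild[0] == "backbone":
            hs = [amide_hydrogen(dpos, traj.frames[f, rebuild[1]],
                                 traj.frames[f, rebuild[2]])]
        else:
            hs = sp2_amide_hydrogens(dpos, traj.frames[f, rebuild[1]],
                                     traj.frames[f, rebuild[2]])
        from ._geometry import angle_deg
        best = max(angle_deg(dpos, h, apos) for h in hs)
        bonded[f] = best >= min_dha_deg
    return HBondSeries(donor, acceptor, bonded, float(bonded.mean()))
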