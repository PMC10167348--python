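"""Trajectory container and readers (multi-frame XYZ, DCD/XTC/TRR).

A :class:`Trajectory` is a fixed atom roster with per-frame coordinates
and times in picoseconds.  The plain multi-frame XYZ format is the
package's text fixture format (time carried on the comment line as
``t= <ps>``); binary MD formats are read through MDAnalysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structures import ParseError

__all__ = ["Trajectory", "read_trajectory", "read_xyz", "write_xyz"]


@dataclass
class Trajectory:
    """In-memory trajectory: ``frames`` has shape (n_frames, n_atoms, 3)
    in angstroms, ``times_ps`` shape (n_frames,), non-decreasing."""

    frames: np.ndarray
    times_ps: np.ndarray
    atom_names: list[str] = field(default_factory=list)
    box: np.ndarray | None = None  # optional (3,) orthorhombic box lengths

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        self.times_ps = np.asarray(self.times_ps, dtype=float)
        if self.times_ps.shape != (self.frames.shape[0],):
            raise ValueError("times_ps length must equal the frame count")
        if np.any(np.diff(self.times_ps) < 0):
            raise ValueError("frame times must be non-decreasing")
        if not self.atom_names:
            self.atom_names = ["X"] * self.frames.shape[1]
        if len(self.atom_names) != self.frames.shape[1]:
            raise ValueError("atom_names length must equal the atom count")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def __iter__(self):
        return iter(self.frames)

    def translated(self, shifts: np.ndarray) -> "Trajectory":
        """Apply a per-frame translation; ``shifts`` is (n_frames, 3)."""
        shifts = np.asarray(shifts, float).reshape(self.n_frames, 1, 3)
        return Trajectory(self.frames + shifts, self.times_ps.copy(),
                          list(self.atom_names), self.box)


def write_xyz(traj: Trajectory, path) -> None:
    """Write a multi-frame XYZ file; 1e-6 angstrom round-trip precision."""
    with open(path, "w") as fh:
        for frame, t in zip(traj.frames, traj.times_ps):
            fh.write(f"{traj.n_atoms}\n")
            fh.write(f"t= {t:.6f} ps\n")
            for name, (x, y, z) in zip(traj.atom_names, frame):
                fh.write(f"{name} {x:.6f} {y:.6f} {z:.6f}\n")


def read_xyz(path, dt_ps: float | None = None) -> Trajectory:
    """Read a multi-frame XYZ file.

    Frame times come from ``t= <value> ps`` comment lines when present,
    otherwise from ``dt_ps`` (default 10 ps per frame, the conventional
    trajectory snapshot stride here).
    """
    frames, times, names = [], [], None
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    iframe = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise ParseError(f"{path}: bad atom-count line {i + 1}") from exc
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        t = None
        for tok_i, tok in enumerate(toks := comment.split()):
            if tok in ("t=", "time=") and tok_i + 1 < len(toks):
                t = float(toks[tok_i + 1])
        block = lines[i + 2:i + 2 + n]
        if len(block) < n:
            raise ParseError(f"{path}: truncated frame {iframe} "
                             f"(expected {n} atoms, got {len(block)})")
        fnames, coords = [], []
        for j, ln in enumerate(block):
            parts = ln.split()
            if len(parts) < 4:
                raise ParseError(f"{path}: bad atom record, frame {iframe} "
                                 f"line {i + 3 + j}")
            fnames.append(parts[0])
            coords.append([float(parts[1]), float(parts[2]), float(parts[3])])
        if names is None:
            names = fnames
        elif len(fnames) != len(names):
            raise ParseError(f"{path}: frame {iframe} has {len(fnames)} atoms, "
                             f"expected {len(names)}")
        frames.append(coords)
        if t is None:
            t = iframe * (dt_ps if dt_ps is not None else 10.0)
        times.append(t)
        i += 2 + n
        iframe += 1
    if not frames:
        raise ParseError(f"{path}: no frames found")
    return Trajectory(np.array(frames), np.array(times), list(names))


def read_trajectory(path, fmt: str | None = None, topology=None,
                    dt_ps: float | None = None) -> Trajectory:
    """Read a trajectory in XYZ, DCD, XTC or TRR format.

    ``topology`` (a PDB/GRO/PSF path) is required for the binary formats;
    the atom count in every frame must match it.  Frame times come from
    file metadata, or from ``dt_ps`` when the file carries none.
    """
    path = str(path)
    if fmt is None:
        fmt = path.rsplit(".", 1)[-1].lower()
    fmt = fmt.lower()
    if fmt == "xyz":
        return read_xyz(path, dt_ps=dt_ps)
    if fmt not in ("dcd", "xtc", "trr"):
        raise ValueError(f"unsupported trajectory format {fmt!r}")
    if topology is None:
        raise ValueError(f"{fmt} trajectories need a topology file")

    import MDAnalysis as mda

    try:
        u = mda.Universe(str(topology), path)
    except Exception as exc:  # MDAnalysis raises varied types
        raise ParseError(f"cannot read {path}: {exc}") from exc
    frames, times = [], []
    for iframe, ts in enumerate(u.trajectory):
        if ts.positions.shape[0] != len(u.atoms):
            raise ParseError(f"{path}: frame {iframe} atom-count mismatch")
        frames.append(ts.positions.copy())
        t = ts.time if np.isfinite(ts.time) else None
        times.append(t if t is not None else iframe * (dt_ps or 10.0))
    names = [a.name for a in u.atoms]
    box = None
    if u.dimensions is not None and np.all(u.dimensions[:3] > 0):
        box = np.array(u.dimensions[:3], dtype=float)
    return Trajectory(np.array(frames), np.array(times), names, box)
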