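"""HOLE-style pore radius profiling and open/closed gating calls.

At each position z along the channel axis the profiler finds the
largest sphere centred in that plane that touches no van der Waals
surface: radius(x, y, z) = min over atoms of (|p - atom| - r_vdw),
maximised over the in-plane centre (x, y).  Centres are constrained to
move at most a bounded step between adjacent z slices so the path stays
in the pore rather than jumping into side pockets.  The gate is called
open when the minimum radius strictly exceeds the probe radius — by
default 1.4 angstrom, the radius of a water molecule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .structures import Selection, Structure, VdwTable, select_atoms

__all__ = [
    "AxisSpec",
    "PoreProfile",
    "GatingCall",
    "WATER_PROBE_RADIUS",
    "compute_pore_profile",
    "classify_gating",
]

WATER_PROBE_RADIUS = 1.4  # angstrom


@dataclass(frozen=True)
class AxisSpec:
    """How to determine the channel axis.

    * ``symmetry`` (default): for each residue number present in every
      chain of the selection, take the centroid of the per-chain
      equivalents; the axis is the principal direction through those
      centroids.  For a C4 tetramer this is the symmetry axis.
    * ``principal``: largest-variance principal axis of the selection.
    * ``explicit``: use ``point`` and ``direction`` as given.
    """

    mode: str = "symmetry"
    selection: Selection | None = None
    point: np.ndarray | None = None
    direction: np.ndarray | None = None

    def resolve(self, structure: Structure) -> tuple[np.ndarray, np.ndarray]:
        """Return (point, unit direction) of the axis for ``structure``."""
        if self.mode == "explicit":
            if self.point is None or self.direction is None:
                raise ValueError("explicit axis needs point and direction")
            d = np.asarray(self.direction, float)
            return np.asarray(self.point, float), d / np.linalg.norm(d)
        if self.selection is not None:
            atoms = select_atoms(structure, self.selection)
        else:
            # default: Calpha trace when present, else every atom
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                atoms = select_atoms(structure, Selection(atom_names=("CA",)))
            if not atoms:
                atoms = select_atoms(structure, Selection())
        if len(atoms) < 3:
            raise ValueError("axis selection matched fewer than 3 atoms")
        coords = np.array([a.pos for a in atoms])
        if self.mode == "principal":
            pts = coords
        elif self.mode == "symmetry":
            by_res: dict[int, list[np.ndarray]] = {}
            chains = {a.chain for a in atoms}
            for a in atoms:
                by_res.setdefault(a.resnum, []).append(a.pos)
            centroids = [np.mean(v, axis=0) for r, v in sorted(by_res.items())
                         if len(v) == len(chains)]
            pts = np.array(centroids) if len(centroids) >= 2 else coords
        else:
            raise ValueError(f"unknown axis mode {self.mode!r}")
        center = pts.mean(axis=0)
        _, _, Vt = np.linalg.svd(pts - center)
        d = Vt[0]
        if d[2] < 0:
            d = -d  # +z toward the extracellular side by convention
        return center, d / np.linalg.norm(d)


@dataclass
class PoreProfile:
    """Radius-vs-axial-position profile in the channel frame."""

    z: np.ndarray
    radius: np.ndarray
    centers: np.ndarray            # (n, 2) in-plane centre at each z
    nearest_residue: list[str]     # "chain/resname resnum" labels
    capped: np.ndarray             # True where the radius hit the cap
    cap_radius: float

    def __post_init__(self):
        if np.any(self.radius < 0):
            raise ValueError("pore radius cannot be negative")

    @property
    def min_radius(self) -> float:
        return float(self.radius.min())

    @property
    def z_at_min(self) -> float:
        return float(self.z[int(np.argmin(self.radius))])

    @property
    def limiting_residue(self) -> str:
        return self.nearest_residue[int(np.argmin(self.radius))]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({
            "z": self.z, "radius": self.radius,
            "center_x": self.centers[:, 0], "center_y": self.centers[:, 1],
            "nearest_residue": self.nearest_residue, "capped": self.capped,
        })


@dataclass(frozen=True)
class GatingCall:
    state: str                 # "open" | "closed"
    probe_radius: float
    min_radius: float
    limiting_residue: str


def _free_radius(points_xy: np.ndarray, z: float, atom_xyz: np.ndarray,
                 vdw: np.ndarray, cap: float) -> np.ndarray:
    """Maximal-sphere radius at in-plane points (vectorised)."""
    p = np.column_stack([points_xy, np.full(len(points_xy), z)])
    d = np.sqrt(((p[:, None, :] - atom_xyz[None, :, :]) ** 2).sum(axis=2))
    free = (d - vdw[None, :]).min(axis=1)
    return np.minimum(free, cap)


def compute_pore_profile(structure: Structure,
                         axis: AxisSpec | None = None,
                         z_range: tuple[float, float] = (-20.0, 20.0),
                         z_step: float = 0.25,
                         vdw: VdwTable | None = None,
                         selection: Selection | None = None,
                         cap_radius: float = 10.0,
                         search_radius: float = 1.0,
                         grid_step: float = 0.2) -> PoreProfile:
    """Maximal-free-sphere pore profile along the channel axis.

    The structure is rotated into the channel frame (axis along +z,
    origin at the axis point).  At each z the in-plane centre is found
    by a coarse grid search within ``search_radius`` of the previous
    centre followed by Nelder-Mead refinement; slices with no atoms
    nearby are capped at ``cap_radius`` and flagged.  Hydrogens are
    ignored (the models and the vdW table are heavy-atom).

    ``search_radius`` bounds the in-plane step between adjacent slices.
    Keeping it small (1 angstrom by default, at a 0.25-angstrom z step)
    is what keeps the centre path connected, so the probe sphere tracks
    the pore instead of slipping into side pockets or out through the
    mouth; the first slice is seeded with a wider (3 angstrom) search
    around the axis.
    """
    if z_step <= 0:
        raise ValueError("z_step must be positive")
    vdw = vdw or VdwTable()
    work = structure.resolve_altlocs()
    atoms = (select_atoms(work, selection) if selection is not None
             else list(work.atoms))
    atoms = [a for a in atoms if a.element != "H"]
    if not atoms:
        raise ValueError("no heavy atoms to profile")

    axis = axis or AxisSpec()
    point, direction = axis.resolve(structure)

    # rotate so the axis is +z; any orthonormal completion will do
    w = direction
    seed = np.array([1.0, 0.0, 0.0]) if abs(w[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(seed, w)
    u /= np.linalg.norm(u)
    v = np.cross(w, u)
    R = np.vstack([u, v, w])           # world -> channel frame

    xyz = (np.array([a.pos for a in atoms]) - point) @ R.T
    radii = vdw.radii_for(atoms)
    labels = [f"{a.chain}/{a.resname} {a.resnum}" for a in atoms]
    order = np.argsort(xyz[:, 2])
    xyz = xyz[order]
    radii = radii[order]
    labels = [labels[i] for i in order]
    zcol = xyz[:, 2]
    max_vdw = float(radii.max())

    zs = np.arange(z_range[0], z_range[1] + 0.5 * z_step, z_step)
    n = len(zs)
    out_r = np.empty(n)
    out_c = np.empty((n, 2))
    out_lab: list[str] = []
    out_cap = np.zeros(n, dtype=bool)

    prev_center = np.zeros(2)
    prev_r = cap_radius
    offsets = _disk_grid(search_radius, grid_step)
    first_offsets = _disk_grid(max(search_radius, 3.0), grid_step)
    for i, z in enumerate(zs):
        # adaptive slab: the free sphere cannot grow by more than the
        # in-plane step plus the z step between slices, so atoms beyond
        # that reach are irrelevant; retry with the full cap if the
        # estimate turns out too tight
        allow = min(cap_radius, prev_r + search_radius + z_step + 0.5)
        step_r = search_radius if i else max(search_radius, 3.0)
        while True:
            margin = allow + max_vdw + step_r
            lo = np.searchsorted(zcol, z - margin)
            hi = np.searchsorted(zcol, z + margin)
            slab = xyz[lo:hi]
            slab_r = radii[lo:hi]
            if len(slab) == 0:
                if allow < cap_radius:
                    allow = cap_radius
                    continue
                break
            cand = prev_center[None, :] + (offsets if i else first_offsets)
            vals = _free_radius(cand, z, slab, slab_r, cap=np.inf)
            x0 = cand[int(np.argmax(vals))]

            def neg_free(xy):
                d = np.sqrt(((np.append(xy, z) - slab) ** 2).sum(axis=1))
                return -float((d - slab_r).min())

            res = minimize(neg_free, x0, method="Nelder-Mead",
                           options={"xatol": 1e-3, "fatol": 1e-4,
                                    "maxiter": 200})
            center = res.x
            # keep the path connected: never jump beyond the search radius
            if np.linalg.norm(center - prev_center) > step_r:
                center = x0
            r_here = -neg_free(center)
            if r_here > allow - 0.25 and allow < cap_radius:
                allow = cap_radius   # slab was too tight; redo in full
                continue
            break

        if len(slab) == 0:
            out_r[i] = cap_radius
            out_c[i] = prev_center
            out_cap[i] = True
            out_lab.append("")
            prev_r = cap_radius
            continue
        d = np.sqrt(((np.append(center, z) - slab) ** 2).sum(axis=1))
        nearest = int(np.argmin(d - slab_r))
        out_lab.append(labels[lo + nearest])
        if r_here >= cap_radius:
            out_r[i] = cap_radius
            out_cap[i] = True
        else:
            out_r[i] = max(r_here, 0.0)
        out_c[i] = center
        prev_center = center
        prev_r = min(max(r_here, 0.0), cap_radius)

    return PoreProfile(zs, out_r, out_c, out_lab, out_cap, cap_radius)


def _disk_grid(radius: float, step: float) -> np.ndarray:
    ax = np.arange(-radius, radius + 0.5 * step, step)
    gx, gy = np.meshgrid(ax, ax)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    return pts[(pts**2).sum(axis=1) <= radius**2]


def classify_gating(profile: PoreProfile,
                    probe_radius: float = WATER_PROBE_RADIUS) -> GatingCall:
    """Open/closed call against a probe radius (strict inequality).

    The pore is open only if its narrowest free radius strictly exceeds
    the probe (a minimum equal to the water radius is still closed).
    """
    if profile.z.size == 0:
        raise ValueError("empty profile")
    open_ = profile.min_radius > probe_radius
    return GatingCall("open" if open_ else "closed", probe_radius,
                      profile.min_radius, profile.limiting_residue)
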