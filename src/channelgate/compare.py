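"""Quantitative comparison of channel conformational states.

Implements Kabsch least-squares Calpha superposition and RMSD,
rigid-body domain rotation angles (optionally projected into the
membrane plane), and hydrogen-bond-pattern secondary-structure
assignment distinguishing alpha (i -> i+4), pi (i -> i+5) and 3-10
(i -> i+3) helix, including pi-bulge spans and helical segment lengths
(one alpha turn is 3.6 residues, so a two-turn change is ~7 residues).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._geometry import amide_hydrogen, angle_deg, kabsch, rotation_angle_deg
from .structures import Selection, Structure, select_atoms

__all__ = [
    "SuperpositionResult",
    "DomainRotation",
    "HelixAssignment",
    "superpose_calpha",
    "domain_rotation_angle",
    "assign_helix",
]

HBOND_MAX_ON_DISTANCE = 3.5   # angstrom, O...N
HBOND_MIN_NHO_ANGLE = 120.0   # degrees, at the reconstructed amide H


@dataclass
class SuperpositionResult:
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_pairs: int

    def __post_init__(self):
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-6:
            raise ValueError("rotation must be proper (det +1)")
        if self.rmsd < 0:
            raise ValueError("rmsd cannot be negative")


@dataclass
class DomainRotation:
    angle_deg: float
    axis: np.ndarray
    mode: str                   # "3d" | "in-plane"

    def __post_init__(self):
        if not 0.0 <= self.angle_deg <= 180.0:
            raise ValueError("rotation angle must lie in [0, 180] degrees")


@dataclass
class HelixAssignment:
    """Per-residue secondary-structure states over a contiguous selection."""

    resnums: np.ndarray
    states: list[str]                   # "alpha" | "pi" | "310" | "coil" | "unassigned"
    helical_segments: list[tuple[int, int]]   # inclusive resnum spans (alpha or pi)
    pi_bulges: list[tuple[int, int]]

    @property
    def n_helical(self) -> int:
        return sum(s in ("alpha", "pi") for s in self.states)

    @property
    def n_alpha(self) -> int:
        return sum(s == "alpha" for s in self.states)

    @property
    def n_pi(self) -> int:
        return sum(s == "pi" for s in self.states)


def _calpha_map(structure: Structure, selection: Selection | None):
    sel = selection or Selection()
    atoms = select_atoms(structure, sel)
    out = {}
    for a in atoms:
        if a.name == "CA":
            out[(a.chain, a.resnum)] = a.pos
    return out


def superpose_calpha(mobile: Structure, reference: Structure,
                     selection: Selection | None = None) -> SuperpositionResult:
    """Optimal rigid Calpha superposition of ``mobile`` onto ``reference``.

    Pairs are matched by (chain, residue number) intersection; no
    sequence alignment or gap handling.  The RMSD is evaluated over the
    matched pairs after the transform.
    """
    ma = _calpha_map(mobile.resolve_altlocs(), selection)
    ra = _calpha_map(reference.resolve_altlocs(), selection)
    common = sorted(set(ma) & set(ra))
    if len(common) < 3:
        raise ValueError(
            f"only {len(common)} matched Calpha pairs; need at least 3")
    P = np.array([ma[k] for k in common])
    Q = np.array([ra[k] for k in common])
    R, t, rmsd = kabsch(P, Q)
    return SuperpositionResult(R, t, rmsd, len(common))


def domain_rotation_angle(state_a: Structure, state_b: Structure,
                          frame_selection: Selection,
                          domain_selection: Selection,
                          mode: str = "3d",
                          plane_normal: np.ndarray | None = None) -> DomainRotation:
    """Rigid-body rotation of a domain between two conformational states.

    Both structures are first superposed on ``frame_selection`` (the
    part assumed static, e.g. the S1-S4 helices of all subunits); the
    rigid rotation best mapping the domain Calpha atoms of state A onto
    state B is then fitted and its angle reported.  ``mode='in-plane'``
    projects the domain coordinates onto the plane orthogonal to
    ``plane_normal`` (default: z, the membrane normal in the channel
    frame) and reports the 2-D rotation about that normal — the
    "rotation in the plane of the membrane".
    """
    if mode not in ("3d", "in-plane"):
        raise ValueError("mode must be '3d' or 'in-plane'")
    sup = superpose_calpha(state_a, state_b, frame_selection)
    a_aligned = state_a.transformed(sup.rotation, sup.translation)

    ma = _calpha_map(a_aligned.resolve_altlocs(), domain_selection)
    mb = _calpha_map(state_b.resolve_altlocs(), domain_selection)
    common = sorted(set(ma) & set(mb))
    if len(common) < 3:
        raise ValueError("domain selection matched fewer than 3 Calpha pairs")
    P = np.array([ma[k] for k in common])
    Q = np.array([mb[k] for k in common])

    if mode == "3d":
        spread = np.linalg.svd(P - P.mean(axis=0), compute_uv=False)
        if spread[1] < 1e-6 * max(spread[0], 1.0):
            raise ValueError("degenerate (collinear) domain coordinates")
        R, _, _ = kabsch(P, Q)
        ang = rotation_angle_deg(R)
        w, V = np.linalg.eig(R)
        axis = np.real(V[:, np.argmin(np.abs(w - 1.0))])
        return DomainRotation(ang, axis / np.linalg.norm(axis), mode)

    n = np.array([0.0, 0.0, 1.0]) if plane_normal is None else (
        np.asarray(plane_normal, float) / np.linalg.norm(plane_normal))
    Pp = P - np.outer(P @ n, n)
    Qp = Q - np.outer(Q @ n, n)
    Pp -= Pp.mean(axis=0)
    Qp -= Qp.mean(axis=0)
    if np.linalg.norm(Pp) < 1e-9 or np.linalg.norm(Qp) < 1e-9:
        raise ValueError("domain has no in-plane extent")
    # optimal rotation about n: atan2 of the summed cross/dot products
    cross = (np.cross(Pp, Qp) @ n).sum()
    dot = (Pp * Qp).sum()
    ang = abs(float(np.degrees(np.arctan2(cross, dot))))
    return DomainRotation(ang, n, mode)


def _backbone_table(structure: Structure, selection: Selection | None):
    """Per-residue backbone atoms {resnum: {name: pos}} for one chain."""
    sel = selection or Selection()
    atoms = select_atoms(structure.resolve_altlocs(), sel)
    chains = sorted({a.chain for a in atoms})
    if len(chains) > 1:
        raise ValueError(
            f"helix assignment works on one chain at a time, got {chains}")
    table: dict[int, dict[str, np.ndarray]] = {}
    resnames: dict[int, str] = {}
    for a in atoms:
        if a.name in ("N", "CA", "C", "O", "H"):
            table.setdefault(a.resnum, {})[a.name] = a.pos
            resnames[a.resnum] = a.resname
    return table, resnames


def _nh_hydrogen(table, resnums, i) -> np.ndarray | None:
    """Backbone amide H of residue resnums[i], reconstructed if absent."""
    res = table[resnums[i]]
    if "H" in res:
        return res["H"]
    if i == 0 or resnums[i - 1] != resnums[i] - 1:
        return None  # no preceding carbonyl to define the H
    prev = table[resnums[i - 1]]
    if "C" not in prev or "N" not in res or "CA" not in res:
        return None
    return amide_hydrogen(res["N"], prev["C"], res["CA"])


def assign_helix(structure: Structure,
                 selection: Selection | None = None) -> HelixAssignment:
    """Hydrogen-bond-pattern helix assignment for a contiguous chain span.

    Residue i is alpha-helical when its carbonyl O accepts a bond from
    the amide of residue i+4, pi when bonded to i+5 (pi takes precedence
    where both hold), 3-10 when bonded to i+3 only.  The bond criterion
    is O...N <= 3.5 angstrom with an O...H-N angle >= 120 degrees, with
    the amide H reconstructed geometrically when the model has no
    hydrogens.  Prolines cannot donate and are handled naturally (no H).
    Residues missing backbone atoms are marked 'unassigned'.
    """
    table, resnames = _backbone_table(structure, selection)
    resnums = sorted(table)
    if not resnums:
        raise ValueError("selection contains no backbone atoms")
    index = {r: i for i, r in enumerate(resnums)}

    def bonded(i: int, j: int) -> bool:
        """True if O(res i) accepts an H-bond from N-H(res j)."""
        res_i, res_j = table[resnums[i]], table[resnums[j]]
        if "O" not in res_i or "N" not in res_j:
            return False
        if resnames.get(resnums[j]) == "PRO":
            return False
        o, n = res_i["O"], res_j["N"]
        if np.linalg.norm(o - n) > HBOND_MAX_ON_DISTANCE:
            return False
        h = _nh_hydrogen(table, resnums, j)
        if h is None:
            return False
        return angle_deg(o, h, n) >= HBOND_MIN_NHO_ANGLE

    states: list[str] = []
    for i, r in enumerate(resnums):
        res = table[r]
        if not {"N", "CA", "C", "O"} <= set(res):
            states.append("unassigned")
            continue
        def turn(offset):
            j = index.get(r + offset)
            return j is not None and bonded(i, j)
        if turn(5):
            states.append("pi")
        elif turn(4):
            states.append("alpha")
        elif turn(3):
            states.append("310")
        else:
            states.append("coil")

    def runs(predicate):
        spans, start = [], None
        for i, s in enumerate(states):
            if predicate(s) and start is None:
                start = i
            elif not predicate(s) and start is not None:
                spans.append((resnums[start], resnums[i - 1]))
                start = None
        if start is not None:
            spans.append((resnums[start], resnums[-1]))
        return spans

    return HelixAssignment(
        np.array(resnums), states,
        helical_segments=runs(lambda s: s in ("alpha", "pi")),
        pi_bulges=runs(lambda s: s == "pi"),
    )
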