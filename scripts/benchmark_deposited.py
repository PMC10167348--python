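#!/usr/bin/env python
"""Benchmarks against the deposited TRPM7 coordinate models.

Downloads the closed-state (8SI2), gain-of-function open (8SI4) and
agonist-bound open (8SI5) models from the PDB and reruns the pipeline's
structural analyses on them:

* pore radius profile through the gate, with the open/closed call
  against the 1.4-angstrom water probe (closed gate < 0.5 A at N1097,
  open gate > 2.3 A; selectivity-filter radius at Y1085 ~1.4 A);
* overall Calpha RMSD closed vs open (~1.5 A);
* rigid-body rotation of the N-terminal domain (residues 1-789) between
  closed and agonist-bound states, fitted after superposing on the
  S1-S4 transmembrane frame (~21 deg), and the in-plane rotation of the
  TRP helix between closed and N1098Q-open (~6 deg) — both depend on
  the frame convention, so agreement is approximate;
* modelled lipids per subunit in the closed nanodisc model (18).

Requires network access; run from the repository root:

    python scripts/benchmark_deposited.py --workdir scratch/pdb
"""

from __future__ import annotations

import argparse
import pathlib
import urllib.request

import numpy as np

from channelgate.compare import domain_rotation_angle, superpose_calpha
from channelgate.pore import AxisSpec, classify_gating, compute_pore_profile
from channelgate.structures import Selection, read_structure

RCSB = "https://files.rcsb.org/download/{}.cif"

# pore-lining helices of the tetramer (S5-S6 span, author numbering)
PORE_SEL = Selection(atom_names=("CA",), resnum_ranges=((1030, 1147),))
S1_S4_SEL = Selection(atom_names=("CA",), resnum_ranges=((843, 1029),))
NTD_SEL = Selection(atom_names=("CA",), resnum_ranges=((1, 789),),
                    chains=("A",))
TRP_HELIX_SEL = Selection(atom_names=("CA",), resnum_ranges=((1108, 1123),),
                          chains=("A",))


def fetch(pdb_id: str, workdir: pathlib.Path) -> pathlib.Path:
    path = workdir / f"{pdb_id}.cif"
    if not path.exists():
        print(f"downloading {pdb_id} ...")
        urllib.request.urlretrieve(RCSB.format(pdb_id), path)
    return path


def gate_metrics(st, label: str) -> None:
    prof = compute_pore_profile(
        st, axis=AxisSpec(mode="symmetry", selection=PORE_SEL),
        z_range=(-25.0, 25.0), z_step=0.25)
    call = classify_gating(prof)
    print(f"  {label}: min radius {prof.min_radius:.2f} A at "
          f"z = {prof.z_at_min:+.1f} A ({prof.limiting_residue}) "
          f"-> {call.state}")
    # radius at the Y1085 ring (extracellular selectivity filter)
    y = [i for i, lab in enumerate(prof.nearest_residue) if "1085" in lab]
    if y:
        r = prof.radius[y].min()
        print(f"  {label}: narrowest radius near Y1085 = {r:.2f} A")


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--workdir", type=pathlib.Path,
                    default=pathlib.Path("scratch/pdb"))
    args = ap.parse_args()
    args.workdir.mkdir(parents=True, exist_ok=True)

    closed = read_structure(fetch("8SI2", args.workdir))
    open_gof = read_structure(fetch("8SI4", args.workdir))
    open_ntb = read_structure(fetch("8SI5", args.workdir))

    print("pore geometry:")
    gate_metrics(closed, "closed (8SI2)")
    gate_metrics(open_gof, "N1098Q open (8SI4)")
    gate_metrics(open_ntb, "NTB open (8SI5)")

    sup = superpose_calpha(closed, open_gof, Selection(atom_names=("CA",)))
    print(f"\nCalpha RMSD closed vs N1098Q-open: {sup.rmsd:.2f} A "
          f"over {sup.n_pairs} pairs (expect ~1.53)")

    ntd = domain_rotation_angle(closed, open_ntb, S1_S4_SEL, NTD_SEL)
    print(f"NTD rigid-body rotation closed vs NTB-open: "
          f"{ntd.angle_deg:.1f} deg (expect ~21)")

    trp = domain_rotation_angle(closed, open_gof, S1_S4_SEL, TRP_HELIX_SEL,
                                mode="in-plane")
    print(f"TRP-helix in-plane rotation closed vs N1098Q-open: "
          f"{trp.angle_deg:.1f} deg (expect ~6)")

    lipids = closed.lipid_count(per_chain=True)
    n_sub = {c: n for c, n in lipids.items()}
    total = sum(n_sub.values())
    print(f"\nlipids in the closed nanodisc model: {total} total, "
          f"per chain {n_sub} (expect 18 per subunit)")


if __name__ == "__main__":
    main()
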