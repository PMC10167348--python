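"""Shared fixtures: small structures, helices and synthetic datasets."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from channelgate.structures import Atom, Structure
from channelgate.synthetic import build_peptide_backbone


@pytest.fixture(scope="session")
def alpha_helix() -> Structure:
    """Ideal alpha helix, 15 residues (phi = -57, psi = -47)."""
    return build_peptide_backbone([(-57.0, -47.0)] * 15)


@pytest.fixture(scope="session")
def pi_spliced_helix() -> Structure:
    """Alpha helix with a 4-residue pi-helical stretch in the middle."""
    dihed = [(-57.0, -47.0)] * 7 + [(-75.0, -50.0)] * 4 + [(-57.0, -47.0)] * 7
    return build_peptide_backbone(dihed)


@pytest.fixture(scope="session")
def tetramer() -> Structure:
    """C4-symmetric four-chain Calpha-only fixture, residues 843-1147.

    Each chain is a straight Calpha rod displaced 10 angstrom from the
    z axis, chains rotated 90 degrees apart, mimicking the subunit
    arrangement of a tetrameric channel for selection and axis tests.
    """
    atoms = []
    n_res = 1147 - 843 + 1
    for ci, chain in enumerate("ABCD"):
        ang = np.radians(90.0 * ci)
        R = np.array([[np.cos(ang), -np.sin(ang), 0],
                      [np.sin(ang), np.cos(ang), 0],
                      [0, 0, 1]])
        for k in range(n_res):
            pos = R @ np.array([10.0, 1.0, -40.0 + k * 80.0 / n_res])
            atoms.append(Atom(chain, 843 + k, "ALA", "CA", "C", pos))
    return Structure(atoms, name="tetramer-rod-fixture")


@pytest.fixture()
def three_atom_pdb(tmp_path):
    """Hand-written 3-atom PDB file."""
    text = (
        "ATOM      1  N   ALA A   1       1.000   2.000   3.000  1.00  0.00"
        "           N\n"
        "ATOM      2  CA  ALA A   1       2.500   2.000   3.000  1.00  0.00"
        "           C\n"
        "ATOM      3  C   ALA A   1       3.100   3.300   3.500  1.00  0.00"
        "           C\n"
        "END\n")
    p = tmp_path / "three.pdb"
    p.write_text(text)
    return p


@pytest.fixture()
def tetramer_cif(tmp_path, tetramer):
    from channelgate.structures import write_structure

    p = tmp_path / "tetramer.cif"
    write_structure(tetramer, p)
    return p


def rigid_copy(st: Structure, rotation: np.ndarray, translation: np.ndarray) -> Structure:
    return st.transformed(rotation, translation)


def random_rotation(seed: int) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    return Rotation.random(rng=np.random.default_rng(seed)).as_matrix()
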