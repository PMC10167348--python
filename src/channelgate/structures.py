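"""Structure model, PDB/mmCIF reading and atom selection.

The in-memory model is deliberately small: a flat list of :class:`Atom`
records plus numpy coordinate views.  Parsing of the standard formats is
delegated to gemmi; entity classification (polymer / lipid / ligand /
water) uses residue-name dictionaries so that, e.g., nanodisc lipids can
be counted directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "Selection",
    "VdwTable",
    "ParseError",
    "read_structure",
    "write_structure",
    "select_atoms",
]


class ParseError(ValueError):
    """Raised when a structure or trajectory file cannot be parsed."""


#: Residue names treated as water.
WATER_RESNAMES = {"HOH", "WAT", "TIP3", "TIP", "SOL", "H2O", "DOD"}

#: Residue names treated as membrane lipids / sterols (nanodisc and
#: detergent components included, since they are modelled as lipids).
LIPID_RESNAMES = {
    "POPC", "POPE", "POPG", "POPS", "DOPC", "DOPE", "DMPC", "DPPC",
    "CLR", "CHL", "CHL1", "CHS", "Y01", "GDN",
    # split-lipid component codes used in deposited models
    "PC1", "PE1", "PG1", "OLA", "OLB", "OLC", "PLM", "PCW", "LPP",
}

STANDARD_AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "SEC", "PYL",
}

#: Bondi van der Waals radii (angstrom), heavy atoms relevant to proteins,
#: lipids and common ions.
BONDI_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.90,
    "NA": 2.27, "K": 2.75, "MG": 1.73, "CA": 2.31, "ZN": 1.39, "X": 1.70,
}

DEFAULT_RADIUS = 1.70


@dataclass(frozen=True)
class Atom:
    chain: str
    resnum: int
    resname: str
    name: str
    element: str
    pos: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    bfactor: float = 0.0
    model: int = 1
    entity: str = "polymer"  # polymer | lipid | ligand | water

    def __post_init__(self):
        object.__setattr__(self, "pos", np.asarray(self.pos, dtype=float))
        if not np.all(np.isfinite(self.pos)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")


class Structure:
    """A set of atoms with convenience accessors.

    Atoms keep file order; :func:`select_atoms` returns a deterministic
    (chain, residue number, atom name) ordering instead.
    """

    def __init__(self, atoms, name: str = ""):
        self.atoms: list[Atom] = list(atoms)
        self.name = name

    def __len__(self):
        return len(self.atoms)

    def __iter__(self):
        return iter(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.pos for a in self.atoms], dtype=float).reshape(-1, 3)

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain)
        return list(seen)

    def transformed(self, R: np.ndarray | None = None,
                    t: np.ndarray | None = None) -> "Structure":
        """Return a rigidly transformed copy (x -> R x + t)."""
        R = np.eye(3) if R is None else np.asarray(R, float)
        t = np.zeros(3) if t is None else np.asarray(t, float)
        new = [replace(a, pos=R @ a.pos + t) for a in self.atoms]
        return Structure(new, name=self.name)

    def resolve_altlocs(self) -> "Structure":
        """Keep one conformer per (chain, resnum, name): highest occupancy,
        ties broken by altloc id ('A', then alphabetical; blank wins)."""
        best: dict[tuple, Atom] = {}
        for a in self.atoms:
            key = (a.model, a.chain, a.resnum, a.name)
            cur = best.get(key)
            if cur is None:
                best[key] = a
            else:
                # blank altloc sorts before 'A'; higher occupancy wins first
                if (a.occupancy, cur.altloc) > (cur.occupancy, a.altloc):
                    best[key] = a
                elif a.occupancy == cur.occupancy and a.altloc < cur.altloc:
                    best[key] = a
        return Structure(list(best.values()), name=self.name)

    def lipid_count(self, per_chain: bool = False):
        """Number of distinct lipid residues (optionally grouped by chain)."""
        lipids = {(a.chain, a.resnum) for a in self.atoms if a.entity == "lipid"}
        if not per_chain:
            return len(lipids)
        out: dict[str, int] = {}
        for chain, _ in lipids:
            out[chain] = out.get(chain, 0) + 1
        return out


def classify_entity(resname: str, is_water_flag: bool = False) -> str:
    rn = resname.upper()
    if is_water_flag or rn in WATER_RESNAMES:
        return "water"
    if rn in LIPID_RESNAMES:
        return "lipid"
    if rn in STANDARD_AMINO_ACIDS:
        return "polymer"
    return "ligand"


class VdwTable:
    """Element -> van der Waals radius (angstrom).  Defaults to Bondi radii;
    unknown elements get a warned fallback of 1.70 angstrom."""

    def __init__(self, radii: dict[str, float] | None = None,
                 fallback: float = DEFAULT_RADIUS):
        table = dict(BONDI_RADII)
        if radii:
            for el, r in radii.items():
                if r <= 0:
                    raise ValueError(f"vdw radius for {el!r} must be positive")
                table[el.upper()] = float(r)
        self._table = table
        self.fallback = float(fallback)
        self._warned: set[str] = set()

    def radius(self, element: str) -> float:
        el = element.upper()
        r = self._table.get(el)
        if r is None:
            if el not in self._warned:
                warnings.warn(
                    f"unknown element {element!r}: using fallback vdw radius "
                    f"{self.fallback} A")
                self._warned.add(el)
            return self.fallback
        return r

    def radii_for(self, atoms) -> np.ndarray:
        return np.array([self.radius(a.element) for a in atoms], dtype=float)


def read_structure(path, fmt: str | None = None) -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    ``fmt`` may be "pdb" or "cif"/"mmcif"; by default it is inferred from
    the extension.  All altloc conformers are retained (use
    :meth:`Structure.resolve_altlocs` before analysis).
    """
    import gemmi

    path = str(path)
    try:
        if fmt is None:
            st = gemmi.read_structure(path)
        elif fmt.lower() == "pdb":
            st = gemmi.read_pdb(path)
        elif fmt.lower() in ("cif", "mmcif"):
            st = gemmi.make_structure_from_block(gemmi.cif.read(path)[0])
        else:
            raise ValueError(f"unknown structure format {fmt!r}")
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    st.setup_entities()

    atoms: list[Atom] = []
    for imodel, model in enumerate(st, start=1):
        for chain in model:
            for res in chain:
                ent = classify_entity(res.name, res.is_water())
                for at in res:
                    atoms.append(Atom(
                        chain=chain.name,
                        resnum=res.seqid.num,
                        resname=res.name,
                        name=at.name,
                        element=at.element.name.upper(),
                        pos=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        occupancy=at.occ,
                        altloc=at.altloc if at.altloc else "",
                        bfactor=at.b_iso,
                        model=imodel,
                        entity=ent,
                    ))
    if not atoms:
        raise ParseError(f"no atoms parsed from {path} (empty or malformed file)")
    return Structure(atoms, name=st.name or path)


def write_structure(structure: Structure, path, fmt: str | None = None) -> None:
    """Write a :class:`Structure` to PDB or mmCIF (inferred from extension)."""
    import gemmi

    path = str(path)
    if fmt is None:
        fmt = "cif" if path.endswith((".cif", ".mmcif")) else "pdb"
    st = gemmi.Structure()
    st.name = structure.name or "model"
    models: dict[int, gemmi.Model] = {}
    for a in structure.atoms:
        model = models.get(a.model)
        if model is None:
            model = gemmi.Model(str(a.model))
            models[a.model] = model
        chain = model.find_chain(a.chain)
        if chain is None:
            model.add_chain(gemmi.Chain(a.chain))
            chain = model.find_chain(a.chain)
        res = None
        if len(chain) > 0:
            last = chain[len(chain) - 1]
            if last.seqid.num == a.resnum and last.name == a.resname:
                res = last
        if res is None:
            res = gemmi.Residue()
            res.name = a.resname
            res.seqid = gemmi.SeqId(a.resnum, " ")
            chain.add_residue(res)
            res = chain[len(chain) - 1]
        at = gemmi.Atom()
        at.name = a.name
        at.element = gemmi.Element(a.element.capitalize())
        at.pos = gemmi.Position(*a.pos)
        at.occ = a.occupancy
        at.b_iso = a.bfactor
        if a.altloc:
            at.altloc = a.altloc
        res.add_atom(at)
    for model in models.values():
        st.add_model(model)
    st.setup_entities()
    if fmt == "pdb":
        st.write_pdb(path)
    else:
        st.make_mmcif_document().write_file(path)


@dataclass(frozen=True)
class Selection:
    """Declarative atom selection.

    Any field left as ``None`` matches everything; residue ranges are
    inclusive.  Evaluation order over a structure is deterministic:
    (chain, residue number, atom name).
    """

    chains: tuple[str, ...] | None = None
    resnum_ranges: tuple[tuple[int, int], ...] | None = None
    resnames: tuple[str, ...] | None = None
    atom_names: tuple[str, ...] | None = None
    entity: str | None = None
    model: int | None = None

    def matches(self, atom: Atom) -> bool:
        if self.model is not None and atom.model != self.model:
            return False
        if self.chains is not None and atom.chain not in self.chains:
            return False
        if self.resnum_ranges is not None and not any(
                lo <= atom.resnum <= hi for lo, hi in self.resnum_ranges):
            return False
        if self.resnames is not None and atom.resname not in self.resnames:
            return False
        if self.atom_names is not None and atom.name not in self.atom_names:
            return False
        if self.entity is not None and atom.entity != self.entity:
            return False
        return True

    @classmethod
    def from_string(cls, text: str) -> "Selection":
        """Parse a compact selection string.

        Space-separated ``key=value`` clauses, values comma-separated;
        residue ranges use ``lo-hi``.  Example::

            "chain=A,B name=CA resi=843-1147,1200"
        """
        kwargs: dict = {}
        for clause in text.split():
            if "=" not in clause:
                raise ValueError(f"bad selection clause {clause!r}")
            key, val = clause.split("=", 1)
            vals = val.split(",")
            if key in ("chain", "chains"):
                kwargs["chains"] = tuple(vals)
            elif key in ("name", "names"):
                kwargs["atom_names"] = tuple(vals)
            elif key in ("resn", "resname"):
                kwargs["resnames"] = tuple(vals)
            elif key == "entity":
                kwargs["entity"] = vals[0]
            elif key in ("resi", "resnum"):
                import re
                ranges = []
                for v in vals:
                    m = re.fullmatch(r"(-?\d+)-(-?\d+)", v)
                    if m:
                        lo, hi = int(m.group(1)), int(m.group(2))
                    else:
                        lo = hi = int(v)
                    ranges.append((lo, hi))
                kwargs["resnum_ranges"] = tuple(ranges)
            else:
                raise ValueError(f"unknown selection key {key!r}")
        return cls(**kwargs)


def select_atoms(structure: Structure, selection: Selection) -> list[Atom]:
    """Atoms matching ``selection``, ordered by (chain, resnum, atom name).

    An empty result is allowed; a warning is emitted so silent mismatches
    (e.g. a wrong chain id) do not go unnoticed.
    """
    hits = [a for a in structure.atoms if selection.matches(a)]
    hits.sort(key=lambda a: (a.chain, a.resnum, a.name, a.altloc))
    if not hits:
        warnings.warn(f"selection {selection} matched no atoms")
    return hits
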