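"""3D structures for field computation.

A :class:`CompoundStructure` is a flat, array-backed view of one aligned
conformer: coordinates, partial charges, van der Waals radii, and the
per-atom weights the similarity fields need (hydrophobicity increments and
donor/acceptor flags).  RDKit does the chemistry: SDF/MOL2 parsing, Gasteiger
charges, Crippen atomic logP contributions, and the periodic-table vdW radii.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np

from rdkit import Chem
from rdkit.Chem import AllChem, rdMolDescriptors

__all__ = ["CompoundStructure", "load_structures", "write_sdf", "structure_from_mol"]

_PT = Chem.GetPeriodicTable()

# steric similarity weight normalised so an sp3 carbon counts 1
_CARBON_RVDW = _PT.GetRvdw(6)


@dataclass
class CompoundStructure:
    """One aligned conformer with per-atom modelling attributes.

    All per-atom arrays share the atom ordering of the source molecule.
    ``skeleton_atom_indices`` names the common-scaffold atoms used as the
    rigid-alignment anchor; at least three are required to define a pose.
    """

    compound_id: str
    elements: List[str]
    coords: np.ndarray  # (n_atoms, 3) Å
    partial_charges: np.ndarray  # (n_atoms,) e
    vdw_radii: np.ndarray  # (n_atoms,) Å
    hydrophobic: np.ndarray  # (n_atoms,) Crippen logP increments
    is_donor: np.ndarray  # (n_atoms,) bool
    is_acceptor: np.ndarray  # (n_atoms,) bool
    skeleton_atom_indices: Sequence[int] = field(default_factory=tuple)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        n = self.coords.shape[0]
        if len(self.elements) != n:
            raise ValueError("elements/coords length mismatch")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"{self.compound_id}: non-finite coordinates")
        for name in ("partial_charges", "vdw_radii", "hydrophobic"):
            arr = np.asarray(getattr(self, name), dtype=float).reshape(-1)
            if arr.shape[0] != n:
                raise ValueError(f"{self.compound_id}: {name} length mismatch")
            setattr(self, name, arr)
        if np.any(self.vdw_radii <= 0):
            raise ValueError(f"{self.compound_id}: vdW radii must be positive")
        self.is_donor = np.asarray(self.is_donor, dtype=bool).reshape(-1)
        self.is_acceptor = np.asarray(self.is_acceptor, dtype=bool).reshape(-1)
        idx = tuple(int(i) for i in self.skeleton_atom_indices)
        if len(set(idx)) != len(idx):
            raise ValueError(f"{self.compound_id}: duplicate skeleton indices")
        if idx and (min(idx) < 0 or max(idx) >= n):
            raise ValueError(f"{self.compound_id}: skeleton index out of range")
        self.skeleton_atom_indices = idx

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def skeleton_coords(self) -> np.ndarray:
        if len(self.skeleton_atom_indices) < 3:
            raise ValueError(
                f"{self.compound_id}: alignment needs >=3 skeleton atoms, "
                f"have {len(self.skeleton_atom_indices)}"
            )
        return self.coords[list(self.skeleton_atom_indices)]

    def steric_weights(self) -> np.ndarray:
        """Cube-of-radius steric similarity weights, carbon-normalised."""
        return (self.vdw_radii / _CARBON_RVDW) ** 3

    def with_coords(self, coords: np.ndarray) -> "CompoundStructure":
        return replace(self, coords=np.asarray(coords, dtype=float))


def _donor_acceptor_flags(mol: Chem.Mol):
    """Element/valence H-bond rules: O-H and N-H are donors; O and N with a
    lone pair (i.e. not quaternary/positively saturated) are acceptors."""
    n = mol.GetNumAtoms()
    donor = np.zeros(n, dtype=bool)
    acceptor = np.zeros(n, dtype=bool)
    for atom in mol.GetAtoms():
        z = atom.GetAtomicNum()
        i = atom.GetIdx()
        if z in (7, 8):
            if atom.GetTotalNumHs(includeNeighbors=True) > 0:
                donor[i] = True
            if atom.GetFormalCharge() <= 0 and atom.GetTotalValence() < (4 if z == 7 else 3):
                acceptor[i] = True
    return donor, acceptor


def structure_from_mol(
    mol: Chem.Mol,
    compound_id: Optional[str] = None,
    skeleton_atom_indices: Sequence[int] = (),
    assign_charges: bool = False,
) -> CompoundStructure:
    """Build a :class:`CompoundStructure` from an RDKit molecule with a 3D
    conformer.  Charges come from an ``atom.dprop.PartialCharge``-style
    property when present, otherwise Gasteiger charges are computed when
    ``assign_charges`` is set; missing charges are stored as zeros."""
    if mol is None:
        raise ValueError("molecule failed to parse")
    if mol.GetNumConformers() == 0:
        raise ValueError("molecule has no conformer")
    conf = mol.GetConformer()
    if not conf.Is3D():
        raise ValueError("molecule carries only 2D coordinates")
    name = compound_id
    if name is None:
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
    coords = conf.GetPositions()
    n = mol.GetNumAtoms()
    charges = np.zeros(n)
    have_charges = all(a.HasProp("_TriposPartialCharge") for a in mol.GetAtoms())
    if have_charges:
        charges = np.array([a.GetDoubleProp("_TriposPartialCharge") for a in mol.GetAtoms()])
    elif all(a.HasProp("_GasteigerCharge") for a in mol.GetAtoms()):
        charges = np.array([a.GetDoubleProp("_GasteigerCharge") for a in mol.GetAtoms()])
    elif assign_charges:
        AllChem.ComputeGasteigerCharges(mol)
        charges = np.array([a.GetDoubleProp("_GasteigerCharge") for a in mol.GetAtoms()])
        charges = np.nan_to_num(charges)
    # molecule-level properties written by write_sdf take precedence: they
    # survive the SDF round-trip, unlike RDKit atom properties
    if mol.HasProp("partial_charges"):
        charges = np.array([float(x) for x in mol.GetProp("partial_charges").split()])
        if charges.shape[0] != n:
            raise ValueError(f"{name}: partial_charges property length mismatch")
    if not skeleton_atom_indices and mol.HasProp("skeleton_atom_indices"):
        skeleton_atom_indices = tuple(
            int(x) for x in mol.GetProp("skeleton_atom_indices").split()
        )
    crippen = rdMolDescriptors._CalcCrippenContribs(mol)
    hydrophobic = np.array([c[0] for c in crippen])
    donor, acceptor = _donor_acceptor_flags(mol)
    return CompoundStructure(
        compound_id=str(name),
        elements=[a.GetSymbol() for a in mol.GetAtoms()],
        coords=coords,
        partial_charges=charges,
        vdw_radii=np.array([_PT.GetRvdw(a.GetAtomicNum()) for a in mol.GetAtoms()]),
        hydrophobic=hydrophobic,
        is_donor=donor,
        is_acceptor=acceptor,
        skeleton_atom_indices=skeleton_atom_indices,
    )


def _iter_mol2_blocks(text: str):
    marker = "@<TRIPOS>MOLECULE"
    parts = text.split(marker)
    for part in parts[1:]:
        yield marker + part


def load_structures(path, fmt: Optional[str] = None, assign_charges: bool = False):
    """Read all molecules from an SDF or MOL2 file as CompoundStructures.

    Hydrogens are kept as written.  Duplicate compound ids in one file raise,
    since descriptor rows are keyed by id.
    """
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    fmt = fmt.lower()
    if not path.exists():
        raise FileNotFoundError(path)
    structures = []
    if fmt == "sdf":
        supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
        for i, mol in enumerate(supplier):
            if mol is None:
                raise ValueError(f"{path}: molecule #{i} failed to parse")
            structures.append(structure_from_mol(mol, assign_charges=assign_charges))
    elif fmt == "mol2":
        text = path.read_text()
        blocks = list(_iter_mol2_blocks(text))
        if not blocks:
            raise ValueError(f"{path}: no @<TRIPOS>MOLECULE records found")
        for i, block in enumerate(blocks):
            mol = Chem.MolFromMol2Block(block, removeHs=False, sanitize=True)
            if mol is None:
                raise ValueError(f"{path}: MOL2 record #{i} failed to parse")
            structures.append(structure_from_mol(mol, assign_charges=assign_charges))
    else:
        raise ValueError(f"unsupported structure format: {fmt!r} (expected SDF or MOL2)")
    ids = [s.compound_id for s in structures]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"{path}: duplicate compound ids {dupes}")
    return structures


def write_sdf(structures, path) -> None:
    """Write structures as an SDF of disconnected atoms with coordinates and
    charges (geometry container, not a bond-perceived chemical archive)."""
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    try:
        for s in structures:
            mol = Chem.RWMol()
            conf = Chem.Conformer(s.n_atoms)
            for i, el in enumerate(s.elements):
                mol.AddAtom(Chem.Atom(el))
                conf.SetAtomPosition(i, tuple(float(x) for x in s.coords[i]))
            m = mol.GetMol()
            for atom, q in zip(m.GetAtoms(), s.partial_charges):
                atom.SetNoImplicit(True)
                atom.SetDoubleProp("_TriposPartialCharge", float(q))
            m.AddConformer(conf)
            m.SetProp("_Name", s.compound_id)
            m.SetProp("partial_charges", " ".join(f"{q:.6f}" for q in s.partial_charges))
            if s.skeleton_atom_indices:
                m.SetProp(
                    "skeleton_atom_indices",
                    " ".join(str(i) for i in s.skeleton_atom_indices),
                )
            Chem.SanitizeMol(m, Chem.SanitizeFlags.SANITIZE_FINDRADICALS)
            writer.write(m)
    finally:
        writer.close()
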