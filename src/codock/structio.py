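"""Molecular structure I/O and shared geometry primitives.

PDB files go through :mod:`gemmi`; SDF / MOL2 files and SMILES strings go
through RDKit.  Everything downstream works on :class:`MolecularStructure`,
an ordered list of :class:`Atom` records with coordinates in Å.  Atom
indices are 0-based throughout the package; PDB serial numbers survive
only as per-atom metadata.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit.Geometry import Point3D

logger = logging.getLogger(__name__)

RECEPTOR = "receptor"
LIGAND = "ligand"

WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}

# Elements recognised when the PDB element column is blank and the symbol
# must be inferred from the atom name (PDB v3 name conventions).
_TWO_LETTER = {
    "FE", "ZN", "MG", "MN", "CA", "NA", "CL", "BR", "CU", "NI", "CO",
    "CD", "HG", "SE", "SI", "LI", "AL", "RB", "CS", "SR", "BA", "MO",
}
_ONE_LETTER = set("CNOSPHFKI")

_VALID_ELEMENTS = {
    gemmi.Element(i).name.upper(): gemmi.Element(i).name
    for i in range(1, 104)
}


class StructureError(ValueError):
    """Raised for unreadable, empty or malformed structure input."""


@dataclass
class Atom:
    """One atom: element, coordinates (Å) and residue/chain metadata."""

    serial: int
    name: str
    element: str
    coords: np.ndarray
    residue_name: str = ""
    residue_number: int = 0
    chain_id: str = ""
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise StructureError(f"atom {self.name!r}: coords must be a finite 3-vector")
        canon = _VALID_ELEMENTS.get(self.element.upper())
        if canon is None:
            raise StructureError(f"atom {self.name!r}: invalid element {self.element!r}")
        self.element = canon

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"

    def copy(self) -> "Atom":
        return replace(self, coords=self.coords.copy())


@dataclass
class MolecularStructure:
    """An ordered collection of atoms playing the receptor or ligand role."""

    id: str
    role: str
    atoms: list[Atom] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.role not in (RECEPTOR, LIGAND):
            raise StructureError(f"role must be {RECEPTOR!r} or {LIGAND!r}, got {self.role!r}")

    def __len__(self) -> int:
        return len(self.atoms)

    def coords(self) -> np.ndarray:
        """(N, 3) coordinate array in file order."""
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([a.coords for a in self.atoms], dtype=float)

    def heavy_atoms(self) -> "MolecularStructure":
        """The same structure with every hydrogen removed."""
        return MolecularStructure(
            self.id, self.role, [a.copy() for a in self.atoms if not a.is_hydrogen]
        )

    def ca_atoms(self) -> "MolecularStructure":
        """Alpha-carbon subset (atom name CA, element C — calcium het atoms excluded)."""
        sel = [a.copy() for a in self.atoms if a.name.strip() == "CA" and a.element == "C"]
        return MolecularStructure(self.id, self.role, sel)

    def copy(self) -> "MolecularStructure":
        return MolecularStructure(self.id, self.role, [a.copy() for a in self.atoms])

    def with_coords(self, coords: np.ndarray) -> "MolecularStructure":
        """Copy of the structure with replaced coordinates (same atom order)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise StructureError("coordinate array shape does not match atom count")
        out = self.copy()
        for a, xyz in zip(out.atoms, coords):
            a.coords = xyz.copy()
        return out


@dataclass
class LigandTopology:
    """Heavy-atom connectivity of a ligand.

    ``bonds`` are 0-based ``(i, j, order)`` triples; aromatic bonds carry
    order 1.5.  Atom order matches the conformer coordinate order used by
    :mod:`codock.pose_gen`.
    """

    elements: list[str]
    bonds: list[tuple[int, int, float]]
    source_smiles: str | None = None

    def __post_init__(self) -> None:
        n = len(self.elements)
        for i, j, order in self.bonds:
            if not (0 <= i < n and 0 <= j < n and i != j):
                raise StructureError(f"bond ({i},{j}) out of range for {n} atoms")
        if n > 1 and not self._connected():
            raise StructureError("ligand topology graph is not connected")

    def _connected(self) -> bool:
        adj: dict[int, set[int]] = {i: set() for i in range(len(self.elements))}
        for i, j, _ in self.bonds:
            adj[i].add(j)
            adj[j].add(i)
        seen = {0}
        stack = [0]
        while stack:
            for nb in adj[stack.pop()]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return len(seen) == len(self.elements)

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def neighbor_map(self) -> dict[int, list[int]]:
        adj: dict[int, list[int]] = {i: [] for i in range(self.n_atoms)}
        for i, j, _ in self.bonds:
            adj[i].append(j)
            adj[j].append(i)
        return {k: sorted(v) for k, v in adj.items()}


# ---------------------------------------------------------------------------
# reading


def infer_element(name: str) -> str:
    """Element symbol from a PDB atom name (used when the element column is blank)."""
    stripped = re.sub(r"[\d'\"*]", "", name).strip().upper()
    if not stripped:
        raise StructureError(f"cannot infer element from atom name {name!r}")
    if stripped[:2] in _TWO_LETTER:
        sym = stripped[:2]
        return sym[0] + sym[1].lower()
    if stripped[0] in _ONE_LETTER:
        return stripped[0]
    canon = _VALID_ELEMENTS.get(stripped[:2]) or _VALID_ELEMENTS.get(stripped[:1])
    if canon is None:
        raise StructureError(f"cannot infer element from atom name {name!r}")
    return canon


def _from_gemmi(st: gemmi.Structure, role: str, drop_waters: bool) -> MolecularStructure:
    atoms: list[Atom] = []
    if len(st) == 0:
        raise StructureError(f"{st.name!r}: no models in file")
    model = st[0]
    for chain in model:
        for residue in chain:
            if drop_waters and residue.name.strip() in WATER_NAMES:
                continue
            het = residue.het_flag == "H"
            for atom in residue:
                # keep blank/'A' altloc only (common docking practice)
                if atom.altloc not in ("", "\x00", "A"):
                    continue
                sym = atom.element.name
                if sym in ("X", "", "D"):
                    sym = infer_element(atom.name)
                atoms.append(
                    Atom(
                        serial=atom.serial,
                        name=atom.name,
                        element=sym,
                        coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        residue_name=residue.name,
                        residue_number=residue.seqid.num,
                        chain_id=chain.name,
                        is_hetero=het,
                    )
                )
    return MolecularStructure(st.name or "structure", role, atoms)


def _from_rdkit(mol: Chem.Mol, role: str, mol_id: str) -> MolecularStructure:
    if mol.GetNumConformers() == 0:
        raise StructureError(f"{mol_id!r}: molecule has no 3D coordinates")
    conf = mol.GetConformer()
    atoms = []
    for i, a in enumerate(mol.GetAtoms()):
        p = conf.GetAtomPosition(i)
        atoms.append(
            Atom(
                serial=i + 1,
                name=f"{a.GetSymbol()}{i + 1}",
                element=a.GetSymbol(),
                coords=np.array([p.x, p.y, p.z]),
                residue_name="LIG",
                residue_number=1,
                chain_id="A",
                is_hetero=True,
            )
        )
    return MolecularStructure(mol_id, role, atoms)


def read_structure(
    path: str | Path,
    role: str,
    fmt: str | None = None,
    drop_waters: bool | None = None,
) -> MolecularStructure:
    """Read one molecular structure from a PDB, SDF or MOL2 file.

    ``fmt`` forces the format; otherwise it is inferred from the extension.
    For receptors, waters are dropped by default (override with
    ``drop_waters=False``).  Only the blank/'A' alternate locations of a
    PDB file are retained.
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such file: {path}")
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if drop_waters is None:
        drop_waters = role == RECEPTOR
    if fmt in ("pdb", "ent"):
        try:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
        except (RuntimeError, ValueError) as exc:
            raise StructureError(f"{path}: PDB parse error: {exc}") from exc
        st.name = path.stem
        structure = _from_gemmi(st, role, drop_waters)
    elif fmt in ("sdf", "mol", "mol2"):
        if fmt == "mol2":
            mol = Chem.MolFromMol2File(str(path), sanitize=False, removeHs=False)
        else:
            supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
            mol = next(iter(supplier), None)
        if mol is None:
            raise StructureError(f"{path}: unparseable {fmt.upper()} record")
        structure = _from_rdkit(mol, role, path.stem)
    else:
        raise StructureError(f"{path}: unsupported format {fmt!r}")
    if len(structure) == 0:
        raise StructureError(f"{path}: no atoms after filtering")
    return structure


def read_structures(path: str | Path, role: str = LIGAND) -> list[MolecularStructure]:
    """All records of a multi-record SDF file, in file order."""
    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such file: {path}")
    if not path.read_text().strip():
        return []
    supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
    out = []
    for k, mol in enumerate(supplier):
        if mol is None:
            raise StructureError(f"{path}: unparseable SDF record {k}")
        out.append(_from_rdkit(mol, role, f"{path.stem}_{k}"))
    return out


def parse_smiles(smiles: str) -> LigandTopology:
    """Heavy-atom topology of a SMILES string (hydrogens stay implicit)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureError(f"invalid SMILES: {smiles!r}")
    elements = [a.GetSymbol() for a in mol.GetAtoms()]
    bonds = []
    for b in mol.GetBonds():
        order = 1.5 if b.GetIsAromatic() else float(b.GetBondTypeAsDouble())
        bonds.append((b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order))
    return LigandTopology(elements=elements, bonds=bonds, source_smiles=smiles)


# ---------------------------------------------------------------------------
# geometry


def centroid(structure: MolecularStructure, heavy_only: bool = True) -> np.ndarray:
    """Unweighted arithmetic mean of the (optionally heavy-only) coordinates."""
    sel = structure.heavy_atoms() if heavy_only else structure
    if len(sel) == 0:
        raise StructureError(f"{structure.id!r}: empty selection for centroid")
    return sel.coords().mean(axis=0)


# ---------------------------------------------------------------------------
# writing


def _bond_type(order: float) -> Chem.BondType:
    return {
        1.0: Chem.BondType.SINGLE,
        2.0: Chem.BondType.DOUBLE,
        3.0: Chem.BondType.TRIPLE,
        1.5: Chem.BondType.AROMATIC,
    }.get(order, Chem.BondType.SINGLE)


def topology_to_mol(topology: LigandTopology) -> Chem.RWMol:
    """RDKit molecule (no coordinates) in topology atom order."""
    mol = Chem.RWMol()
    for el in topology.elements:
        atom = Chem.Atom(el)
        atom.SetNoImplicit(True)
        mol.AddAtom(atom)
    for i, j, order in topology.bonds:
        mol.AddBond(int(i), int(j), _bond_type(order))
        if order == 1.5:
            mol.GetAtomWithIdx(int(i)).SetIsAromatic(True)
            mol.GetAtomWithIdx(int(j)).SetIsAromatic(True)
            mol.GetBondBetweenAtoms(int(i), int(j)).SetIsAromatic(True)
    mol.UpdatePropertyCache(strict=False)
    return mol


def structure_to_mol(structure: MolecularStructure) -> Chem.RWMol:
    """RDKit molecule from a bare structure (no bonds)."""
    mol = Chem.RWMol()
    for a in structure.atoms:
        atom = Chem.Atom(a.element)
        atom.SetNoImplicit(True)
        mol.AddAtom(atom)
    mol.UpdatePropertyCache(strict=False)
    _set_conformer(mol, structure.coords())
    return mol


def _set_conformer(mol: Chem.RWMol, coords: np.ndarray) -> None:
    conf = Chem.Conformer(mol.GetNumAtoms())
    for i, (x, y, z) in enumerate(np.asarray(coords, dtype=float)):
        conf.SetAtomPosition(i, Point3D(float(x), float(y), float(z)))
    mol.RemoveAllConformers()
    mol.AddConformer(conf, assignId=True)


def write_sdf(structure: MolecularStructure, path: str | Path) -> None:
    """Write a single structure (no bond information) as one SDF record."""
    mol = structure_to_mol(structure)
    mol.SetProp("_Name", structure.id)
    with Chem.SDWriter(str(path)) as writer:
        writer.SetKekulize(False)
        writer.write(mol)


def _to_gemmi(structure: MolecularStructure) -> gemmi.Structure:
    # gemmi's add_* methods copy their argument, so assemble bottom-up:
    # group atoms first, then build residue -> chain -> model -> structure
    grouped: dict[str, dict[tuple[int, str], list[Atom]]] = {}
    for a in structure.atoms:
        chain_id = a.chain_id or "A"
        grouped.setdefault(chain_id, {}).setdefault(
            (a.residue_number, a.residue_name), []
        ).append(a)
    st = gemmi.Structure()
    st.name = structure.id
    model = gemmi.Model("1")
    for chain_id, residues in grouped.items():
        chain = gemmi.Chain(chain_id)
        for (res_num, res_name), atoms in residues.items():
            res = gemmi.Residue()
            res.name = res_name or ("LIG" if atoms[0].is_hetero else "UNK")
            res.seqid = gemmi.SeqId(res_num or 1, " ")
            res.het_flag = "H" if atoms[0].is_hetero else "A"
            for a in atoms:
                atom = gemmi.Atom()
                atom.name = a.name
                atom.element = gemmi.Element(a.element)
                atom.pos = gemmi.Position(*a.coords)
                atom.serial = a.serial
                atom.occ = 1.0
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    return st


def write_pdb(structure: MolecularStructure, path: str | Path) -> None:
    """Write a structure as a fixed-column PDB file (via gemmi)."""
    st = _to_gemmi(structure)
    st.setup_entities()
    st.write_pdb(str(path))


def write_poses(poses: Sequence, path: str | Path, fmt: str = "sdf") -> None:
    """Write docking poses in rank order; one record per pose.

    All poses must share one :class:`LigandTopology`.  Rank (1-based),
    scores, conformer index and template id land in per-record metadata.
    An empty pose list still produces a valid (empty) file, with a warning.
    """
    path = Path(path)
    if fmt not in ("sdf", "pdb"):
        raise StructureError(f"unsupported pose format {fmt!r}")
    if not poses:
        logger.warning("write_poses: no poses to write to %s", path)
        path.write_text("")
        return
    if fmt == "pdb":
        _write_poses_pdb(poses, path)
        return
    topology = poses[0].topology
    try:
        with Chem.SDWriter(str(path)) as writer:
            writer.SetKekulize(False)
            for rank, pose in enumerate(poses, start=1):
                mol = topology_to_mol(pose.topology)
                _set_conformer(mol, pose.coords)
                mol.SetProp("_Name", f"pose_{rank}")
                mol.SetProp("rank", str(rank))
                mol.SetProp("conformer_index", str(pose.conformer_index))
                mol.SetProp("template_id", pose.template_id)
                for name, value in pose.scores.items():
                    mol.SetProp(name, f"{value:.6f}")
                writer.write(mol)
    except OSError as exc:
        raise StructureError(f"cannot write poses to {path}: {exc}") from exc


def _write_poses_pdb(poses: Sequence, path: Path) -> None:
    lines = []
    for rank, pose in enumerate(poses, start=1):
        lines.append(f"MODEL     {rank:>4}")
        lines.append(f"REMARK   3 rank {rank} template {pose.template_id}")
        for name, value in pose.scores.items():
            lines.append(f"REMARK   3 score {name} {value:.6f}")
        for i, (el, xyz) in enumerate(zip(pose.topology.elements, pose.coords)):
            nm = f"{el}{i + 1}"
            lines.append(
                f"HETATM{i + 1:>5} {nm:<4}{'LIG':>4} A{1:>4}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {el:>2}"
            )
        lines.append("ENDMDL")
    lines.append("END")
    try:
        path.write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise StructureError(f"cannot write poses to {path}: {exc}") from exc
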