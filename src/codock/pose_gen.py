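"""Conformer generation and template-guided pose generation.

Conformers come from RDKit distance-geometry embedding when the topology
carries a SMILES string, or from a built-in internal-coordinate builder
for acyclic topologies (ideal bond lengths, tetrahedral angles, torsions
on a fixed three-value grid).  Each conformer is aligned onto the
template ligand with the correspondence-graph algorithm and then carried
into the query receptor frame through the inverse pocket transform.
Monatomic ions skip conformer generation: the template ion position is
mapped directly through the pocket transform.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from . import graph_align
from .graph_align import LIGAND_EPSILON, SimilarityResult
from .structio import (
    LIGAND,
    Atom,
    LigandTopology,
    MolecularStructure,
    StructureError,
    topology_to_mol,
)
from .template_search import TemplateRecord

logger = logging.getLogger(__name__)

DEFAULT_N_CONFORMERS = 20
DEFAULT_DEDUP_RMSD = 0.5

#: torsion grid (degrees) sampled on each rotatable bond by the built-in builder
TORSION_GRID = (-60.0, 60.0, 180.0)
#: tetrahedral bond angle (degrees) used by the built-in builder
IDEAL_ANGLE = 109.47

# ideal heavy-atom bond lengths (Å) by unordered element pair
_BOND_LENGTHS = {
    frozenset(["C"]): 1.54,
    frozenset(["C", "N"]): 1.47,
    frozenset(["C", "O"]): 1.43,
    frozenset(["C", "S"]): 1.81,
    frozenset(["N"]): 1.45,
    frozenset(["N", "O"]): 1.40,
    frozenset(["O"]): 1.48,
}
_DEFAULT_BOND_LENGTH = 1.50


class ConformerError(ValueError):
    """Raised when conformer embedding fails for a molecule."""


@dataclass
class ConformerSet:
    """Conformer coordinate arrays in topology atom order."""

    topology: LigandTopology
    conformers: list[np.ndarray]
    seed: int
    backend: str

    def __post_init__(self) -> None:
        for c in self.conformers:
            if np.asarray(c).shape != (self.topology.n_atoms, 3):
                raise ConformerError("conformer shape does not match topology")

    def __len__(self) -> int:
        return len(self.conformers)


@dataclass
class Pose:
    """One candidate ligand placement in the query receptor frame."""

    coords: np.ndarray
    topology: LigandTopology
    conformer_index: int
    template_id: str
    alignment: SimilarityResult | None = None
    scores: dict = field(default_factory=dict)
    low_confidence: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ConformerError("pose coordinates must be finite")

    def as_structure(self, structure_id: str = "pose") -> MolecularStructure:
        atoms = [
            Atom(serial=i + 1, name=f"{el}{i + 1}", element=el, coords=xyz,
                 residue_name="LIG", residue_number=1, chain_id="A", is_hetero=True)
            for i, (el, xyz) in enumerate(zip(self.topology.elements, self.coords))
        ]
        return MolecularStructure(structure_id, LIGAND, atoms)

    @property
    def s_t(self) -> float:
        return self.alignment.s_t if self.alignment is not None else 0.0


# ---------------------------------------------------------------------------
# built-in internal-coordinate conformer builder (acyclic topologies)


def bond_length(el_a: str, el_b: str) -> float:
    return _BOND_LENGTHS.get(frozenset([el_a, el_b]), _DEFAULT_BOND_LENGTH)


def _build_tree(topology: LigandTopology) -> tuple[list[int], dict[int, int], dict[int, list[int]]]:
    """BFS order from atom 0, parent map and ordered children (acyclic only)."""
    adj = topology.neighbor_map()
    n_edges = len(topology.bonds)
    if n_edges != topology.n_atoms - 1:
        raise ConformerError(
            "built-in conformer builder supports acyclic molecules only; "
            "use the RDKit backend (topology with source_smiles) for rings"
        )
    parent: dict[int, int] = {}
    order = [0]
    children: dict[int, list[int]] = {i: [] for i in range(topology.n_atoms)}
    seen = {0}
    queue = [0]
    while queue:
        node = queue.pop(0)
        for nb in adj[node]:
            if nb not in seen:
                seen.add(nb)
                parent[nb] = node
                children[node].append(nb)
                order.append(nb)
                queue.append(nb)
    return order, parent, children


def rotatable_bonds(topology: LigandTopology) -> list[tuple[int, int]]:
    """Internal (parent, child) bonds of the BFS tree whose torsions are sampled."""
    order, parent, children = _build_tree(topology)
    adj = topology.neighbor_map()
    # a bond (g=parent, p=child) is rotatable when the child branches further
    # and the parent has a reference neighbor besides the child
    return [
        (par, child)
        for child, par in sorted(parent.items())
        if children[child] and len(adj[par]) > 1
    ]


def _place_nerf(ref: np.ndarray, g: np.ndarray, p: np.ndarray,
                length: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Natural-extension-reference-frame placement of one atom.

    Places atom ``a`` at distance ``length`` from ``p``, angle a-p-g and
    dihedral a-p-g-ref as given.
    """
    theta = np.deg2rad(angle_deg)
    phi = np.deg2rad(torsion_deg)
    b1 = p - g
    b1 /= np.linalg.norm(b1)
    b0 = g - ref
    n = np.cross(b0, b1)
    norm = np.linalg.norm(n)
    if norm < 1e-9:  # collinear reference chain: pick any perpendicular
        helper = np.array([1.0, 0.0, 0.0])
        if abs(b1[0]) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        n = np.cross(helper, b1)
        norm = np.linalg.norm(n)
    n /= norm
    m = np.cross(n, b1)
    d = np.array([
        -length * np.cos(theta),
        length * np.sin(theta) * np.cos(phi),
        length * np.sin(theta) * np.sin(phi),
    ])
    return p + d[0] * b1 + d[1] * m + d[2] * n


def build_conformer(topology: LigandTopology, torsions: dict[tuple[int, int], float]) -> np.ndarray:
    """Cartesian coordinates for one torsion assignment of an acyclic topology.

    Branches at one atom are separated by 120° offsets from the bond's
    base torsion; non-rotatable bonds use a 180° base.
    """
    order, parent, children = _build_tree(topology)
    coords = np.zeros((topology.n_atoms, 3))
    placed: dict[int, np.ndarray] = {}
    for atom in order:
        if atom == 0:
            placed[0] = np.zeros(3)
            continue
        p = parent[atom]
        length = bond_length(topology.elements[atom], topology.elements[p])
        if p not in parent:  # child of the root
            siblings = children[p]
            k = siblings.index(atom)
            if k == 0:
                placed[atom] = placed[p] + np.array([length, 0.0, 0.0])
            else:
                # later root children: tetrahedral angle from the first child
                ref = placed[p] + np.array([0.0, 0.0, 1.0])
                base = 0.0 + 120.0 * (k - 1)
                placed[atom] = _place_nerf(
                    ref, placed[siblings[0]], placed[p], length, IDEAL_ANGLE, base
                )
        else:
            g = parent[p]
            ref_candidates = [a for a in ([parent.get(g)] + children[g]) if a is not None and a != p and a in placed]
            ref = placed[ref_candidates[0]] if ref_candidates else placed[g] + np.array([0.0, 0.0, 1.0])
            base = torsions.get((g, p), 180.0)
            k = children[p].index(atom)
            placed[atom] = _place_nerf(
                ref, placed[g], placed[p], length, IDEAL_ANGLE, base + 120.0 * k
            )
    for i in range(topology.n_atoms):
        coords[i] = placed[i]
    return coords


def torsion_combinations(topology: LigandTopology) -> tuple[list[tuple[int, int]], int]:
    bonds = rotatable_bonds(topology)
    return bonds, len(TORSION_GRID) ** len(bonds)


def _combo_torsions(bonds: list[tuple[int, int]], index: int) -> dict[tuple[int, int], float]:
    torsions = {}
    for bond in reversed(bonds):
        torsions[bond] = TORSION_GRID[index % len(TORSION_GRID)]
        index //= len(TORSION_GRID)
    return torsions


def _fallback_conformers(topology: LigandTopology, n: int, seed: int) -> list[np.ndarray]:
    bonds, n_combo = torsion_combinations(topology)
    if n_combo <= n:
        indices = list(range(n_combo))
    else:
        rng = np.random.default_rng(seed)
        indices = sorted(rng.choice(n_combo, size=n, replace=False).tolist())
    return [build_conformer(topology, _combo_torsions(bonds, i)) for i in indices]


def _rdkit_conformers(topology: LigandTopology, n: int, seed: int) -> list[np.ndarray]:
    mol = Chem.MolFromSmiles(topology.source_smiles)
    if mol is None:
        raise ConformerError(f"RDKit rejected SMILES {topology.source_smiles!r}")
    molh = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) & 0x7FFFFFFF
    ids = AllChem.EmbedMultipleConfs(molh, numConfs=n, params=params)
    if len(ids) == 0:
        raise ConformerError(
            f"distance-geometry embedding failed for {topology.source_smiles!r}"
        )
    n_heavy = topology.n_atoms  # AddHs appends hydrogens after the heavy atoms
    out = []
    for cid in ids:
        pos = molh.GetConformer(cid).GetPositions()
        out.append(np.array(pos[:n_heavy], dtype=float))
    return out


def generate_conformers(
    topology: LigandTopology,
    n: int = DEFAULT_N_CONFORMERS,
    seed: int = 0,
    backend: str = "auto",
) -> ConformerSet:
    """Up to ``n`` conformers, deterministic for fixed (topology, n, seed).

    ``backend="auto"`` uses RDKit embedding when a SMILES string is
    available and the internal builder otherwise; single heavy atoms get
    one conformer at the origin.
    """
    if n < 1:
        raise ConformerError("need n >= 1 conformers")
    if topology.n_atoms == 1:
        return ConformerSet(topology, [np.zeros((1, 3))], seed, "trivial")
    if backend == "auto":
        backend = "rdkit" if topology.source_smiles else "fallback"
    if backend == "rdkit":
        if not topology.source_smiles:
            raise ConformerError("RDKit backend needs topology.source_smiles")
        conformers = _rdkit_conformers(topology, n, seed)
    elif backend == "fallback":
        conformers = _fallback_conformers(topology, n, seed)
    else:
        raise ConformerError(f"unknown conformer backend {backend!r}")
    return ConformerSet(topology, conformers, seed, backend)


# ---------------------------------------------------------------------------
# template-guided pose generation


def align_to_template(
    conformer_coords: np.ndarray,
    topology: LigandTopology,
    template_ligand: MolecularStructure,
    epsilon: float = LIGAND_EPSILON,
    conformer_index: int = 0,
    template_id: str = "",
    n_seeds: int = graph_align.DEFAULT_N_SEEDS,
) -> Pose:
    """Rigidly align one conformer onto the template ligand.

    The correspondence graph uses element compatibility over heavy
    atoms; the whole conformer is carried by the fitted transform.  A
    degenerate clique (< 3 pairs) flags the pose low-confidence instead
    of dropping it.
    """
    conformer_coords = np.asarray(conformer_coords, dtype=float)
    query = Pose(conformer_coords, topology, conformer_index, template_id).as_structure()
    result = graph_align.align(
        query, template_ligand, epsilon=epsilon, compat="element", n_seeds=n_seeds
    )
    if result.n_shared == 0:
        coords = conformer_coords - conformer_coords.mean(axis=0) + \
            template_ligand.heavy_atoms().coords().mean(axis=0)
        pose = Pose(coords, topology, conformer_index, template_id, result, low_confidence=True)
        return pose
    coords = result.transform.apply(conformer_coords)
    return Pose(
        coords, topology, conformer_index, template_id, result,
        low_confidence=result.degenerate and topology.n_atoms >= 3,
    )


def place_ion(
    ion: MolecularStructure,
    pocket_alignment: SimilarityResult,
    template_ion: Atom,
) -> Pose:
    """Place a monatomic ion at the template ion position in the query frame.

    The pocket alignment maps query pocket coordinates onto the template
    pocket, so the template ion comes back through the inverse transform.
    """
    heavy = ion.heavy_atoms()
    if len(heavy) != 1:
        raise ConformerError(f"{ion.id!r}: ion placement needs exactly 1 heavy atom")
    if pocket_alignment.degenerate:
        raise ConformerError("pocket alignment is degenerate; cannot place ion")
    coords = pocket_alignment.transform.inverse().apply(template_ion.coords[None, :])
    topology = LigandTopology(elements=[heavy.atoms[0].element], bonds=[])
    return Pose(coords, topology, 0, "", alignment=pocket_alignment)


def _inplace_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(((a - b) ** 2).sum(axis=1).mean()))


def generate_poses(
    conformers: ConformerSet,
    template: TemplateRecord,
    pocket_alignment: SimilarityResult,
    dedup_rmsd: float = DEFAULT_DEDUP_RMSD,
    epsilon: float = LIGAND_EPSILON,
) -> list[Pose]:
    """Template-guided poses for every conformer, deduplicated.

    Each conformer is aligned to the template ligand and mapped into the
    query receptor frame via the inverse pocket transform.  Poses closer
    than ``dedup_rmsd`` (in-place RMSD, same atom order) collapse onto
    the member with the better alignment S_T.
    """
    if len(conformers) == 0:
        raise ConformerError("no conformers to place")
    into_query = pocket_alignment.transform.inverse()
    poses = []
    for k, conf in enumerate(conformers.conformers):
        pose = align_to_template(
            conf, conformers.topology, template.template_ligand,
            epsilon=epsilon, conformer_index=k, template_id=template.template_id,
        )
        pose.coords = into_query.apply(pose.coords)
        poses.append(pose)
    # keep the best-S_T representative of every < dedup_rmsd cluster
    order = sorted(range(len(poses)), key=lambda i: (-poses[i].s_t, i))
    kept: list[Pose] = []
    for i in order:
        if all(_inplace_rmsd(poses[i].coords, k.coords) >= dedup_rmsd for k in kept):
            kept.append(poses[i])
    kept.sort(key=lambda p: p.conformer_index)
    return kept
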