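"""Voxel-grid atom-type featurization, scoring and submission selection.

The featurizer discretizes receptor and ligand heavy atoms into a cubic
grid (24 Å edge, 0.5 Å spacing by default) with one channel per atom
type: 16 receptor types and 18 ligand types, 34 channels in all, the
input representation a CNN scorer consumes.  Scoring is pluggable: a
built-in contact/clash surrogate (explicitly *not* a trained CNN) and a
hook for an external scorer executable.
"""

from __future__ import annotations

import json
import logging
import shlex
import subprocess
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .structio import LigandTopology, MolecularStructure, StructureError, read_structures
from .pose_gen import Pose

logger = logging.getLogger(__name__)

DEFAULT_BOX_EDGE = 24.0
DEFAULT_SPACING = 0.5

# Atom-type tables.  Versioned; the channel counts (16 receptor + 18
# ligand = 34) are the fixed contract, the labels subdivide elements by
# aromaticity and hydrogen-bonding role with catch-alls for the rest.
RECEPTOR_TYPES: tuple[str, ...] = (
    "rec_C_aliphatic", "rec_C_aromatic",
    "rec_N", "rec_N_donor", "rec_N_acceptor", "rec_N_donor_acceptor",
    "rec_O_acceptor", "rec_O_donor_acceptor",
    "rec_S", "rec_P",
    "rec_F", "rec_Cl", "rec_Br", "rec_I",
    "rec_metal", "rec_other",
)
LIGAND_TYPES: tuple[str, ...] = (
    "lig_C_aliphatic", "lig_C_aromatic",
    "lig_N", "lig_N_donor", "lig_N_acceptor", "lig_N_donor_acceptor",
    "lig_O", "lig_O_acceptor", "lig_O_donor_acceptor",
    "lig_S", "lig_S_acceptor", "lig_P",
    "lig_F", "lig_Cl", "lig_Br", "lig_I",
    "lig_metal", "lig_other",
)
N_CHANNELS = len(RECEPTOR_TYPES) + len(LIGAND_TYPES)

_METALS = {
    "Li", "Na", "K", "Rb", "Cs", "Mg", "Ca", "Sr", "Ba", "Mn", "Fe",
    "Co", "Ni", "Cu", "Zn", "Cd", "Hg", "Al",
}

# van der Waals radii (Å) for the density kernel
_VDW = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "Cl": 1.75, "Br": 1.85, "I": 1.98,
    "Mg": 1.73, "Zn": 1.39, "Fe": 1.40, "Ca": 2.31, "Na": 2.27, "K": 2.75,
}
_DEFAULT_VDW = 1.70

#: kernel truncation radius multiplier (× vdW radius)
KERNEL_RADIUS_FACTOR = 1.5
#: relative-coordinate quantum (Å) for bit-reproducible voxelization
COORD_QUANTUM = 1e-6


class GridError(ValueError):
    """Raised for inconsistent grid specifications."""


class ScoringError(RuntimeError):
    """Raised when an external scorer fails or returns malformed output."""


@dataclass
class GridSpec:
    """Geometry and channel layout of the featurization grid."""

    center: np.ndarray
    box_edge: float = DEFAULT_BOX_EDGE
    spacing: float = DEFAULT_SPACING
    receptor_types: tuple[str, ...] = RECEPTOR_TYPES
    ligand_types: tuple[str, ...] = LIGAND_TYPES

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if self.center.shape != (3,):
            raise GridError("grid center must be a 3-vector")
        n = self.box_edge / self.spacing
        if self.box_edge <= 0 or self.spacing <= 0 or abs(n - round(n)) > 1e-9:
            raise GridError(
                f"box_edge/spacing must be a positive integer, got {self.box_edge}/{self.spacing}"
            )
        if len(self.receptor_types) != 16 or len(self.ligand_types) != 18:
            raise GridError("need 16 receptor and 18 ligand atom types")

    @property
    def n_voxels(self) -> int:
        return int(round(self.box_edge / self.spacing))

    @property
    def n_channels(self) -> int:
        return len(self.receptor_types) + len(self.ligand_types)

    def voxel_centers_1d(self) -> np.ndarray:
        """Voxel-center offsets from the grid center along one axis."""
        n = self.n_voxels
        return (np.arange(n) + 0.5 - n / 2.0) * self.spacing

    def to_json(self) -> str:
        return json.dumps(
            {
                "center": [float(v) for v in self.center],
                "box_edge": self.box_edge,
                "spacing": self.spacing,
                "receptor_types": list(self.receptor_types),
                "ligand_types": list(self.ligand_types),
            },
            indent=2,
        )


@dataclass
class GridTensor:
    """(34, N, N, N) voxel density tensor plus its spec."""

    values: np.ndarray
    spec: GridSpec

    def __post_init__(self) -> None:
        n = self.spec.n_voxels
        if self.values.shape != (self.spec.n_channels, n, n, n):
            raise GridError(f"tensor shape {self.values.shape} does not match spec")

    def save(self, path: str | Path) -> None:
        """NumPy ``.npy`` tensor plus a JSON sidecar with the grid spec."""
        path = Path(path)
        np.save(path, self.values)
        sidecar = path.with_suffix(".json")
        sidecar.write_text(self.spec.to_json())


@dataclass
class ScoreResult:
    """Score of one pose; higher pose_score is better."""

    pose_score: float
    affinity: float | None = None
    scorer: str = "surrogate"

    def __post_init__(self) -> None:
        if not np.isfinite(self.pose_score):
            raise ScoringError("pose_score must be finite")
        if self.affinity is not None and not np.isfinite(self.affinity):
            raise ScoringError("affinity must be finite")


# ---------------------------------------------------------------------------
# atom typing


def _aromatic_atoms(topology: LigandTopology | None) -> set[int]:
    if topology is None:
        return set()
    out = set()
    for i, j, order in topology.bonds:
        if order == 1.5:
            out.update((i, j))
    return out


def assign_atom_types(
    structure: MolecularStructure,
    role: str,
    topology: LigandTopology | None = None,
) -> list[str]:
    """One type label per heavy atom from the role's table.

    With a topology, aromatic carbons are split out; element-only
    mapping otherwise.  Nitrogen defaults to the donor/acceptor label
    and oxygen to the acceptor label — deliberately coarse rules that
    fill the printed channel counts; unknown elements land in the
    catch-all label with a log line.
    """
    table = RECEPTOR_TYPES if role == "receptor" else LIGAND_TYPES
    prefix = "rec" if role == "receptor" else "lig"
    aromatic = _aromatic_atoms(topology)
    labels = []
    for idx, atom in enumerate(structure.heavy_atoms().atoms):
        el = atom.element
        if el == "C":
            label = f"{prefix}_C_aromatic" if idx in aromatic else f"{prefix}_C_aliphatic"
        elif el == "N":
            label = f"{prefix}_N_donor_acceptor"
        elif el == "O":
            label = f"{prefix}_O_acceptor"
        elif el in ("S", "P", "F", "Cl", "Br", "I"):
            label = f"{prefix}_{el}"
        elif el in _METALS:
            label = f"{prefix}_metal"
        else:
            label = f"{prefix}_other"
            logger.info("atom %s (%s) mapped to catch-all %s", atom.name, el, label)
        assert label in table
        labels.append(label)
    return labels


# ---------------------------------------------------------------------------
# featurization


def _kernel(d2: np.ndarray, radius: float) -> np.ndarray:
    """Quartic bump kernel on squared distance: 1 at the atom center,
    smooth (C1) decay to 0 at ``radius`` = 1.5 × vdW radius."""
    x = d2 / (radius * radius)
    out = np.zeros_like(d2)
    inside = x < 1.0
    out[inside] = (1.0 - x[inside]) ** 2
    return out


def _deposit(values: np.ndarray, channel: int, rel: np.ndarray, radius: float,
             offsets: np.ndarray, spacing: float) -> None:
    n = offsets.size
    lo_hi = []
    for axis in range(3):
        lo = int(np.searchsorted(offsets, rel[axis] - radius))
        hi = int(np.searchsorted(offsets, rel[axis] + radius))
        if lo >= n or hi <= 0:
            return
        lo_hi.append((max(lo, 0), min(hi, n)))
    (xl, xh), (yl, yh), (zl, zh) = lo_hi
    dx = offsets[xl:xh] - rel[0]
    dy = offsets[yl:yh] - rel[1]
    dz = offsets[zl:zh] - rel[2]
    d2 = (dx[:, None, None] ** 2 + dy[None, :, None] ** 2) + dz[None, None, :] ** 2
    values[channel, xl:xh, yl:yh, zl:zh] += _kernel(d2, radius)


def featurize(
    receptor: MolecularStructure,
    pose: Pose | MolecularStructure,
    spec: GridSpec,
    ligand_topology: LigandTopology | None = None,
) -> GridTensor:
    """Voxelize a receptor and a ligand pose into the 34-channel grid.

    Each heavy atom deposits the quartic bump kernel (1 at its center,
    0 beyond 1.5 × vdW radius) into its type channel; receptor atoms
    touch channels 0–15 only, ligand atoms channels 16–33 only.  Atoms
    outside the box contribute nothing.  Atom-minus-center offsets are
    quantized to 1e-6 Å so jointly translated inputs reproduce the
    tensor bit-for-bit.
    """
    ligand = pose.as_structure() if isinstance(pose, Pose) else pose
    if ligand_topology is None and isinstance(pose, Pose):
        ligand_topology = pose.topology
    n = spec.n_voxels
    values = np.zeros((spec.n_channels, n, n, n), dtype=np.float64)
    offsets = spec.voxel_centers_1d()

    def run(structure: MolecularStructure, labels: list[str], table: Sequence[str], base: int) -> None:
        heavy = structure.heavy_atoms()
        for atom, label in zip(heavy.atoms, labels):
            channel = base + list(table).index(label)
            radius = KERNEL_RADIUS_FACTOR * _VDW.get(atom.element, _DEFAULT_VDW)
            rel = atom.coords - spec.center
            rel = np.round(rel / COORD_QUANTUM) * COORD_QUANTUM
            _deposit(values, channel, rel, radius, offsets, spec.spacing)

    run(receptor, assign_atom_types(receptor, "receptor"), spec.receptor_types, 0)
    run(ligand, assign_atom_types(ligand, "ligand", ligand_topology),
        spec.ligand_types, len(spec.receptor_types))
    return GridTensor(values, spec)


# ---------------------------------------------------------------------------
# scoring


def _pair_potential(d: np.ndarray) -> np.ndarray:
    """Contact/clash pair term: -10 below 2.5 Å, linear to +1 at 3.0 Å,
    +1 on [3.0, 5.0] Å, 0 beyond."""
    out = np.zeros_like(d)
    out[d < 2.5] = -10.0
    ramp = (d >= 2.5) & (d < 3.0)
    out[ramp] = -10.0 + 11.0 * (d[ramp] - 2.5) / 0.5
    out[(d >= 3.0) & (d <= 5.0)] = 1.0
    return out


def surrogate_score(receptor: MolecularStructure, pose: Pose | MolecularStructure) -> ScoreResult:
    """Deterministic contact-minus-clash surrogate score.

    Sum of the pair term over all receptor–ligand heavy-atom pairs.
    This is a documented stand-in scorer, not a trained CNN; use
    :func:`external_score` for CNN parity.
    """
    ligand = pose.as_structure() if isinstance(pose, Pose) else pose
    rc = receptor.heavy_atoms().coords()
    lc = ligand.heavy_atoms().coords()
    if rc.shape[0] == 0 or lc.shape[0] == 0:
        raise ScoringError("surrogate_score needs non-empty receptor and ligand")
    d = cdist(rc, lc)
    return ScoreResult(pose_score=float(_pair_potential(d).sum()), scorer="surrogate")


def external_score(
    receptor_path: str | Path,
    poses_path: str | Path,
    command_template: str,
) -> list[ScoreResult]:
    """Invoke an external scorer executable and parse its scores.

    The command template is formatted with ``{receptor}`` and
    ``{poses}``.  Expected output: one whitespace-separated line per
    pose, ``<pose_index> <pose_score> [<affinity>]`` with 0-based SDF
    record indices in any order; scores are re-associated by index.
    """
    receptor_path, poses_path = Path(receptor_path), Path(poses_path)
    n_poses = len(read_structures(poses_path))
    cmd = shlex.split(command_template.format(receptor=receptor_path, poses=poses_path))
    try:
        proc = subprocess.run(cmd, capture_output=True, text=True, check=False)
    except FileNotFoundError as exc:
        raise ScoringError(f"external scorer not found: {cmd[0]!r}") from exc
    if proc.returncode != 0:
        raise ScoringError(
            f"external scorer failed (exit {proc.returncode}): {proc.stderr.strip()}"
        )
    parsed: dict[int, ScoreResult] = {}
    for line in proc.stdout.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        try:
            idx = int(fields[0])
            score = float(fields[1])
            affinity = float(fields[2]) if len(fields) > 2 else None
        except (IndexError, ValueError) as exc:
            raise ScoringError(f"unparseable scorer line {line!r}") from exc
        if idx in parsed:
            raise ScoringError(f"duplicate pose index {idx} in scorer output")
        parsed[idx] = ScoreResult(score, affinity, scorer="external")
    if sorted(parsed) != list(range(n_poses)):
        raise ScoringError(
            f"scorer returned indices {sorted(parsed)} for {n_poses} poses:\n{proc.stdout}"
        )
    return [parsed[i] for i in range(n_poses)]


# ---------------------------------------------------------------------------
# submission selection


def select_submission(
    poses: Sequence[Pose],
    scores: Sequence[ScoreResult],
    n_models: int = 5,
    poses_per_model: int = 5,
) -> list[list[Pose]]:
    """Partition scored poses into submission groups (5 models × 5 poses).

    Poses are sorted by pose_score descending (ties by alignment S_T
    descending, then pose index) and cut into consecutive groups;
    trailing groups may be short but are never padded.
    """
    if not poses:
        raise ScoringError("no poses to select from")
    if len(poses) != len(scores):
        raise ScoringError("scores are not aligned to poses")
    order = sorted(
        range(len(poses)),
        key=lambda i: (-scores[i].pose_score, -poses[i].s_t, i),
    )
    ranked = [poses[i] for i in order]
    for i, pose in zip(order, ranked):
        pose.scores.setdefault("pose_score", scores[i].pose_score)
    groups = [
        ranked[g * poses_per_model:(g + 1) * poses_per_model]
        for g in range(n_models)
    ]
    return [g for g in groups if g]
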