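"""Docking evaluation: RMSD, quality categories and success rates.

Docking RMSD is computed over ligand heavy atoms in a common frame with
*no* superposition, matching standard redocking assessment.  A
symmetry-corrected variant minimizes over automorphisms of the
element-labeled bond graph; it is reported separately, never silently
substituted.  Predictions are binned into high quality (RMSD ≤ 2.0 Å),
accepted site (2.0 < RMSD ≤ 5.0 Å) and failed (> 5.0 Å).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .pose_gen import Pose
from .structio import LigandTopology, MolecularStructure

logger = logging.getLogger(__name__)

HIGH_QUALITY_CUTOFF = 2.0
ACCEPTED_SITE_CUTOFF = 5.0

HIGH_QUALITY = "high_quality"
ACCEPTED_SITE = "acceptable_site"
FAILED = "failed"

#: heavy-atom count above which automorphism enumeration falls back to plain RMSD
SYMMETRY_ATOM_GUARD = 12


class EvaluationError(ValueError):
    """Raised for inconsistent evaluation inputs."""


@dataclass
class EvaluationResult:
    """Per-pose evaluation against the reference ligand."""

    rmsd: float
    rmsd_symmetry_corrected: float
    category: str
    pose_rank: int

    def __post_init__(self) -> None:
        if self.rmsd_symmetry_corrected > self.rmsd + 1e-12:
            raise EvaluationError("symmetry-corrected RMSD cannot exceed plain RMSD")
        if self.category != classify_quality(self.rmsd_symmetry_corrected):
            raise EvaluationError("category inconsistent with the RMSD cutoffs")


def _pose_coords(pose: Pose | MolecularStructure | np.ndarray) -> np.ndarray:
    if isinstance(pose, Pose):
        return pose.coords
    if isinstance(pose, MolecularStructure):
        return pose.heavy_atoms().coords()
    return np.asarray(pose, dtype=float)


def docking_rmsd(
    pose: Pose | MolecularStructure | np.ndarray,
    reference: MolecularStructure,
    mapping: Sequence[tuple[int, int]] | None = None,
) -> float:
    """Heavy-atom RMSD between pose and reference, no superposition.

    Default mapping is by shared atom order; an explicit
    ``(pose_index, reference_index)`` mapping overrides it.  By-name
    mapping is available through :func:`mapping_by_name`.
    """
    pc = _pose_coords(pose)
    rc = reference.heavy_atoms().coords()
    if mapping is None:
        if pc.shape[0] != rc.shape[0]:
            raise EvaluationError(
                f"atom count mismatch ({pc.shape[0]} vs {rc.shape[0]}): "
                "provide an explicit atom mapping"
            )
        delta = pc - rc
    else:
        pi = [m[0] for m in mapping]
        ri = [m[1] for m in mapping]
        delta = pc[pi] - rc[ri]
    return float(np.sqrt((delta**2).sum(axis=1).mean()))


def mapping_by_name(
    pose_structure: MolecularStructure, reference: MolecularStructure
) -> list[tuple[int, int]]:
    """Heavy-atom correspondence by (unique) atom name, for PDB references."""
    ref_names = {a.name.strip(): i for i, a in enumerate(reference.heavy_atoms().atoms)}
    mapping = []
    for i, atom in enumerate(pose_structure.heavy_atoms().atoms):
        name = atom.name.strip()
        if name not in ref_names:
            raise EvaluationError(f"atom name {name!r} missing from reference")
        mapping.append((i, ref_names[name]))
    return mapping


def _element_graph(topology: LigandTopology) -> nx.Graph:
    g = nx.Graph()
    for i, el in enumerate(topology.elements):
        g.add_node(i, element=el)
    for i, j, _ in topology.bonds:
        g.add_edge(i, j)
    return g


def graph_automorphisms(topology: LigandTopology) -> list[dict[int, int]]:
    """All automorphisms of the element-labeled bond graph."""
    g = _element_graph(topology)
    matcher = nx.algorithms.isomorphism.GraphMatcher(
        g, g, node_match=lambda a, b: a["element"] == b["element"]
    )
    return list(matcher.isomorphisms_iter())


def symmetry_rmsd(
    pose: Pose | MolecularStructure | np.ndarray,
    reference: MolecularStructure,
    topology: LigandTopology,
) -> tuple[float, bool]:
    """Minimum docking RMSD over bond-graph automorphisms.

    Returns ``(rmsd, corrected)``; for more than ``SYMMETRY_ATOM_GUARD``
    heavy atoms the enumeration is refused and the plain RMSD is
    returned with ``corrected=False`` and a warning.
    """
    pc = _pose_coords(pose)
    if topology.n_atoms != pc.shape[0]:
        raise EvaluationError("topology does not match the pose atom count")
    plain = docking_rmsd(pc, reference)
    if topology.n_atoms > SYMMETRY_ATOM_GUARD:
        logger.warning(
            "symmetry correction refused for %d heavy atoms (guard %d); "
            "returning plain RMSD", topology.n_atoms, SYMMETRY_ATOM_GUARD,
        )
        return plain, False
    rc = reference.heavy_atoms().coords()
    if rc.shape[0] != topology.n_atoms:
        raise EvaluationError("reference does not match the topology atom count")
    best = plain
    for auto in graph_automorphisms(topology):
        perm = [auto[i] for i in range(topology.n_atoms)]
        delta = pc - rc[perm]
        best = min(best, float(np.sqrt((delta**2).sum(axis=1).mean())))
    return best, True


def classify_quality(rmsd: float) -> str:
    """Quality category with boundaries exactly at 2.0 and 5.0 Å."""
    if rmsd < 0:
        raise EvaluationError(f"RMSD must be non-negative, got {rmsd}")
    if rmsd <= HIGH_QUALITY_CUTOFF:
        return HIGH_QUALITY
    if rmsd <= ACCEPTED_SITE_CUTOFF:
        return ACCEPTED_SITE
    return FAILED


def evaluate_pose(
    pose: Pose,
    reference: MolecularStructure,
    pose_rank: int,
    symmetry: bool = True,
) -> EvaluationResult:
    plain = docking_rmsd(pose, reference)
    if symmetry:
        corrected, _ = symmetry_rmsd(pose, reference, pose.topology)
    else:
        corrected = plain
    return EvaluationResult(
        rmsd=plain,
        rmsd_symmetry_corrected=corrected,
        category=classify_quality(corrected),
        pose_rank=pose_rank,
    )


def success_rate(
    per_system_rmsds: Sequence[Sequence[float]],
    top_k: int,
    cutoff: float,
) -> float:
    """Fraction of systems whose best of the first ``top_k`` ranked RMSDs
    is at or below ``cutoff``."""
    if not per_system_rmsds:
        raise EvaluationError("no systems to evaluate")
    if top_k < 1 or cutoff < 0:
        raise EvaluationError("need top_k >= 1 and cutoff >= 0")
    hits = 0
    for rmsds in per_system_rmsds:
        if not rmsds:
            raise EvaluationError("every system needs at least one ranked RMSD")
        if min(rmsds[:top_k]) <= cutoff:
            hits += 1
    return hits / len(per_system_rmsds)


def report(per_target: dict[str, Sequence[float]]) -> pd.DataFrame:
    """Per-target summary: lowest RMSD over submitted poses + category tallies.

    ``per_target`` maps target id to the RMSDs of all its submitted
    poses.  Use ``to_csv(sep="\\t")`` for the machine-readable form and
    :func:`format_report` for the pretty-printed one.
    """
    rows = []
    for target, rmsds in per_target.items():
        cats = [classify_quality(r) for r in rmsds]
        rows.append(
            {
                "target": target,
                "n_poses": len(rmsds),
                "lowest_rmsd": min(rmsds) if rmsds else np.nan,
                "n_high_quality": cats.count(HIGH_QUALITY),
                "n_acceptable_site": cats.count(ACCEPTED_SITE),
                "n_failed": cats.count(FAILED),
            }
        )
    columns = [
        "target", "n_poses", "lowest_rmsd",
        "n_high_quality", "n_acceptable_site", "n_failed",
    ]
    return pd.DataFrame(rows, columns=columns)


def format_report(table: pd.DataFrame) -> str:
    if table.empty:
        return "\t".join(table.columns)
    return table.to_string(index=False, float_format=lambda v: f"{v:.2f}")
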