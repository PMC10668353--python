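"""End-to-end template-based docking pipeline.

Wires the components together: pocket extraction around a known or
scanned center, ranked template retrieval, conformer generation,
template-guided pose generation, scoring and submission selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import grid_score, pose_gen, template_search
from .config import Config
from .graph_align import SimilarityResult
from .pose_gen import Pose
from .structio import LigandTopology, MolecularStructure
from .template_search import TemplateLibrary, TemplateRecord

logger = logging.getLogger(__name__)


class DockingError(RuntimeError):
    """Raised when no usable template or pose can be produced."""


@dataclass
class DockingRun:
    """Poses in score order plus submission groups and template hits."""

    poses: list[Pose]
    groups: list[list[Pose]]
    hits: list[tuple[TemplateRecord, SimilarityResult]]
    center: np.ndarray

    @property
    def ranked_poses(self) -> list[Pose]:
        return [p for group in self.groups for p in group]


def scan_centers(receptor: MolecularStructure) -> list[np.ndarray]:
    """Candidate binding-site centers when none is supplied: every CA position.

    A documented extension for the blind setting — template retrieval
    itself then localizes the site by picking the center whose pocket
    aligns best against the library.
    """
    cas = receptor.ca_atoms()
    return [a.coords.copy() for a in cas.atoms]


def _best_center(
    receptor: MolecularStructure,
    library: TemplateLibrary,
    config: Config,
) -> tuple[np.ndarray, list[tuple[TemplateRecord, SimilarityResult]]]:
    best = None
    for center in scan_centers(receptor):
        try:
            pocket = template_search.extract_pocket(receptor, center, config.search.cutoff)
        except template_search.TemplateError:
            continue
        hits = template_search.search_templates(
            pocket, library, top_k=config.search.top_k,
            epsilon=config.align.pocket_epsilon, n_seeds=config.align.n_seeds,
        )
        if not hits:
            continue
        key = (hits[0][1].s_t, -hits[0][1].fit_rmsd)
        if best is None or key > best[0]:
            best = (key, center, hits)
    if best is None:
        raise DockingError("no candidate center produced a usable template alignment")
    return best[1], best[2]


def dock(
    receptor: MolecularStructure,
    topology: LigandTopology,
    library: TemplateLibrary,
    center: np.ndarray | None = None,
    config: Config | None = None,
    seed: int = 0,
    n_templates: int = 1,
) -> DockingRun:
    """Template-based docking of one ligand into one receptor.

    Monatomic ligands are placed by coordinate transformation through
    the pocket alignment; everything else goes through conformer
    generation and template-guided alignment.  Poses are scored with
    the configured scorer and partitioned into 5x5 submission groups.
    """
    config = config or Config()
    if center is not None:
        pocket = template_search.extract_pocket(receptor, center, config.search.cutoff)
        hits = template_search.search_templates(
            pocket, library, top_k=config.search.top_k,
            epsilon=config.align.pocket_epsilon, n_seeds=config.align.n_seeds,
        )
        if not hits:
            raise DockingError("no usable template for the supplied center")
        center = np.asarray(center, dtype=float)
    else:
        center, hits = _best_center(receptor, library, config)

    poses: list[Pose] = []
    for record, pocket_alignment in hits[:max(1, n_templates)]:
        if topology.n_atoms == 1:
            poses.extend(_ion_poses(topology, record, pocket_alignment))
            continue
        conformers = pose_gen.generate_conformers(
            topology, n=config.conformers.n, seed=seed, backend=config.conformers.backend
        )
        poses.extend(
            pose_gen.generate_poses(
                conformers, record, pocket_alignment,
                epsilon=config.align.ligand_epsilon,
            )
        )
    if not poses:
        raise DockingError("pose generation produced no poses")
    scores = [grid_score.surrogate_score(receptor, p) for p in poses]
    groups = grid_score.select_submission(poses, scores)
    return DockingRun(poses=poses, groups=groups, hits=hits, center=center)


def _ion_poses(
    topology: LigandTopology,
    record: TemplateRecord,
    pocket_alignment: SimilarityResult,
) -> list[Pose]:
    element = topology.elements[0]
    ion = pose_gen.Pose(np.zeros((1, 3)), topology, 0, record.template_id).as_structure("ion")
    candidates = [
        a for a in record.template_ligand.heavy_atoms().atoms if a.element == element
    ] or record.template_ligand.heavy_atoms().atoms
    out = []
    for template_ion in candidates:
        pose = pose_gen.place_ion(ion, pocket_alignment, template_ion)
        pose.template_id = record.template_id
        out.append(pose)
    return out
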