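"""Binding-pocket extraction, the local template library, and retrieval.

A pocket is the set of receptor CA atoms within a cutoff (12 Å by
default) of the ligand center.  Template records pair such a pocket with
the ligand bound in the source complex, emulating a BioLiP-style library
built from user-supplied complexes.  Retrieval aligns the query pocket
against every library pocket with the correspondence-graph algorithm and
ranks by the similarity coefficient S_T.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import graph_align
from .graph_align import SimilarityResult
from .structio import (
    LIGAND,
    RECEPTOR,
    MolecularStructure,
    StructureError,
    centroid,
    read_structure,
    write_pdb,
    write_sdf,
)

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF = 12.0


class TemplateError(ValueError):
    """Raised for invalid pockets, records or library layouts."""


@dataclass
class Pocket:
    """CA atoms within ``cutoff`` Å of the ligand centroid."""

    source_id: str
    ca_atoms: list
    ligand_centroid: np.ndarray
    cutoff: float

    def __post_init__(self) -> None:
        self.ligand_centroid = np.asarray(self.ligand_centroid, dtype=float)
        if not self.ca_atoms:
            raise TemplateError(f"{self.source_id!r}: pocket has no CA atoms")
        for a in self.ca_atoms:
            if np.linalg.norm(a.coords - self.ligand_centroid) > self.cutoff + 1e-9:
                raise TemplateError(
                    f"{self.source_id!r}: CA atom outside the {self.cutoff} Å cutoff"
                )

    @property
    def n_ca(self) -> int:
        return len(self.ca_atoms)

    def as_structure(self) -> MolecularStructure:
        return MolecularStructure(
            f"{self.source_id}_pocket", RECEPTOR, [a.copy() for a in self.ca_atoms]
        )


@dataclass
class TemplateRecord:
    """One pocket plus the ligand bound in the source complex."""

    template_id: str
    pocket: Pocket
    template_ligand: MolecularStructure
    ligand_code: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.template_ligand.heavy_atoms()) == 0:
            raise TemplateError(f"{self.template_id!r}: template ligand has no heavy atoms")


@dataclass
class TemplateLibrary:
    """An ordered collection of template records with id/code lookups."""

    records: list[TemplateRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.template_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise TemplateError("duplicate template_id in library")

    def __len__(self) -> int:
        return len(self.records)

    def add(self, record: TemplateRecord) -> None:
        if any(r.template_id == record.template_id for r in self.records):
            raise TemplateError(f"duplicate template_id {record.template_id!r}")
        self.records.append(record)

    def by_id(self, template_id: str) -> TemplateRecord:
        for r in self.records:
            if r.template_id == template_id:
                return r
        raise KeyError(template_id)

    def by_ligand_code(self, ligand_code: str) -> list[TemplateRecord]:
        return [r for r in self.records if r.ligand_code == ligand_code]

    def by_source_id(self, source_id: str) -> list[TemplateRecord]:
        return [r for r in self.records if r.pocket.source_id == source_id]

    # -- on-disk layout: <lib>/<template_id>/{receptor.pdb, ligand.sdf, manifest.json}

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for record in self.records:
            rec_dir = directory / record.template_id
            rec_dir.mkdir(parents=True, exist_ok=True)
            write_pdb(record.pocket.as_structure(), rec_dir / "receptor.pdb")
            write_sdf(record.template_ligand, rec_dir / "ligand.sdf")
            manifest = {
                "template_id": record.template_id,
                "ligand_code": record.ligand_code,
                "source_id": record.pocket.source_id,
                "cutoff": record.pocket.cutoff,
                "n_ca": record.pocket.n_ca,
                "ligand_centroid": [float(v) for v in record.pocket.ligand_centroid],
                "meta": record.meta,
            }
            (rec_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "TemplateLibrary":
        directory = Path(directory)
        if not directory.is_dir():
            raise TemplateError(f"no such library directory: {directory}")
        library = cls()
        for rec_dir in sorted(p for p in directory.iterdir() if p.is_dir()):
            manifest_path = rec_dir / "manifest.json"
            if not manifest_path.exists():
                logger.warning("skipping %s: no manifest.json", rec_dir)
                continue
            manifest = json.loads(manifest_path.read_text())
            pocket_structure = read_structure(rec_dir / "receptor.pdb", RECEPTOR)
            ligand = read_structure(rec_dir / "ligand.sdf", LIGAND)
            ligand.id = manifest["ligand_code"]
            pocket = Pocket(
                source_id=manifest["source_id"],
                ca_atoms=pocket_structure.ca_atoms().atoms,
                ligand_centroid=np.asarray(manifest["ligand_centroid"], dtype=float),
                cutoff=float(manifest["cutoff"]),
            )
            library.add(
                TemplateRecord(
                    template_id=manifest["template_id"],
                    pocket=pocket,
                    template_ligand=ligand,
                    ligand_code=manifest["ligand_code"],
                    meta=manifest.get("meta", {}),
                )
            )
        return library


# ---------------------------------------------------------------------------
# operations


def extract_pocket(
    receptor: MolecularStructure,
    ligand_centroid: np.ndarray,
    cutoff: float = DEFAULT_CUTOFF,
) -> Pocket:
    """CA atoms within ``cutoff`` (inclusive) of the ligand centroid, in order."""
    ligand_centroid = np.asarray(ligand_centroid, dtype=float)
    cas = receptor.ca_atoms()
    if len(cas) == 0:
        raise TemplateError(f"{receptor.id!r}: receptor has no CA atoms")
    dist = np.linalg.norm(cas.coords() - ligand_centroid, axis=1)
    selected = [a.copy() for a, d in zip(cas.atoms, dist) if d <= cutoff]
    if not selected:
        raise TemplateError(
            f"{receptor.id!r}: no CA atoms within {cutoff} Å of the ligand center"
        )
    return Pocket(receptor.id, selected, ligand_centroid, cutoff)


def make_record(
    receptor: MolecularStructure,
    ligand: MolecularStructure,
    cutoff: float = DEFAULT_CUTOFF,
    ligand_code: str | None = None,
    meta: dict | None = None,
) -> TemplateRecord:
    """Build one template record from a receptor–ligand complex."""
    code = ligand_code or ligand.id
    center = centroid(ligand, heavy_only=True)
    pocket = extract_pocket(receptor, center, cutoff)
    return TemplateRecord(
        template_id=f"{receptor.id}_{code}",
        pocket=pocket,
        template_ligand=ligand.heavy_atoms(),
        ligand_code=code,
        meta=meta or {},
    )


def build_library(
    complexes: Sequence[tuple[MolecularStructure, MolecularStructure]],
    cutoff: float = DEFAULT_CUTOFF,
) -> TemplateLibrary:
    """One template record per (receptor, bound ligand) pair.

    Complexes whose ligand sits beyond the cutoff from every CA are
    rejected with a warning rather than aborting the build.
    """
    library = TemplateLibrary()
    for receptor, ligand in complexes:
        try:
            record = make_record(receptor, ligand, cutoff)
        except TemplateError as exc:
            logger.warning("rejecting complex %s/%s: %s", receptor.id, ligand.id, exc)
            continue
        library.add(record)
    return library


def search_templates(
    query_pocket: Pocket,
    library: TemplateLibrary,
    top_k: int | None = None,
    epsilon: float = graph_align.POCKET_EPSILON,
    n_seeds: int = graph_align.DEFAULT_N_SEEDS,
) -> list[tuple[TemplateRecord, SimilarityResult]]:
    """Rank library templates against a query pocket.

    Every record is aligned pocket-vs-pocket (CA compatibility); results
    are ordered by S_T descending, ties by fit RMSD ascending then
    template id.  Degenerate alignments (clique < 3) are excluded; an
    all-degenerate search returns an empty list with a warning.
    """
    if len(library) == 0:
        raise TemplateError("template library is empty")
    query = query_pocket.as_structure()
    scored = []
    for record in library.records:
        result = graph_align.align(
            query,
            record.pocket.as_structure(),
            epsilon=epsilon,
            compat="ca",
            n_seeds=n_seeds,
        )
        if result.degenerate:
            continue
        scored.append((record, result))
    if not scored:
        logger.warning("all template alignments degenerate; no usable template")
        return []
    scored.sort(key=lambda rr: (-rr[1].s_t, rr[1].fit_rmsd, rr[0].template_id))
    return scored[:top_k] if top_k else scored
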