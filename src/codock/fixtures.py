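"""Synthetic receptor–ligand complexes and template libraries.

Everything the test-suite and the demonstration pipeline consume is
generated here, deterministically per seed: a CA-trace receptor whose
helical path winds around a concave binding site, a connected
heavy-atom ligand with ideal bond lengths built on the same torsion
grid the built-in conformer backend samples, perturbed copies emulating
imperfect experimental templates, and decoy records with unrelated
pocket geometry.

What these fixtures emulate — and what they do not — is discussed in
the methods note; in short they exercise the geometry and bookkeeping
of the docking protocol, not protein physics.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, replace

import numpy as np

from . import pose_gen
from .structio import LIGAND, RECEPTOR, Atom, LigandTopology, MolecularStructure
from .template_search import DEFAULT_CUTOFF, TemplateLibrary, TemplateRecord, make_record

logger = logging.getLogger(__name__)

#: minimum receptor–ligand heavy-atom separation (Å) a fixture guarantees
MIN_SEPARATION = 2.5
#: per-CA random displacement (Å) giving every scaffold a unique distance set
SCAFFOLD_JITTER = 0.6
#: coordinate noise (Å) on the planted template ligand: crystal-ligand
#: coordinate precision, distinct from the larger pocket deviation that
#: emulates receptor-side structural differences
TEMPLATE_LIGAND_SIGMA = 0.15

_VALENCE_CAP = {"C": 4, "N": 3, "O": 2}
_ELEMENT_POOL = ("C", "C", "C", "N", "O")
_ION_POOL = ("Zn", "Mg", "K")


class FixtureError(RuntimeError):
    """Raised when fixture generation cannot satisfy its geometric contract."""


@dataclass
class FixtureConfig:
    """Study conditions for synthetic complexes and libraries."""

    seed: int = 0
    n_receptor_residues: int = 24
    ligand_size: int = 8
    pocket_noise_sigma: float = 0.3
    decoy_count: int = 9

    def __post_init__(self) -> None:
        if self.n_receptor_residues < 4 or self.ligand_size < 1 or self.decoy_count < 0:
            raise FixtureError("fixture sizes must be positive")
        if self.pocket_noise_sigma < 0:
            raise FixtureError("noise sigma must be non-negative")


def split_seed(seed: int, tag: str) -> int:
    """Deterministic per-purpose substream seed (< 2**31)."""
    digest = hashlib.sha256(f"{seed}:{tag}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


# ---------------------------------------------------------------------------
# ligand generation


def _random_topology(rng: np.random.Generator, size: int, max_rotatable: int = 2) -> LigandTopology:
    """Connected acyclic heavy-atom topology with few rotatable bonds.

    Capping the rotatable-bond count keeps the built-in torsion grid
    exhaustively enumerable within the default conformer budget, so
    redocking a fixture ligand is a well-posed self-consistency test.
    """
    if size == 1:
        element = str(rng.choice(_ION_POOL))
        return LigandTopology(elements=[element], bonds=[])
    for _ in range(200):
        elements = ["C"]
        bonds: list[tuple[int, int, float]] = []
        degree = [0]
        ok = True
        for new in range(1, size):
            open_sites = [
                i for i in range(new) if degree[i] < _VALENCE_CAP[elements[i]]
            ]
            if not open_sites:
                ok = False
                break
            parent = int(rng.choice(open_sites))
            element = str(rng.choice(_ELEMENT_POOL))
            elements.append(element)
            bonds.append((parent, new, 1.0))
            degree[parent] += 1
            degree.append(1)
        if not ok:
            continue
        topology = LigandTopology(elements=elements, bonds=bonds)
        if len(pose_gen.rotatable_bonds(topology)) <= max_rotatable:
            return topology
    raise FixtureError(f"could not build a {size}-atom topology within retries")


def _ligand_structure(topology: LigandTopology, coords: np.ndarray, ligand_id: str) -> MolecularStructure:
    atoms = [
        Atom(serial=i + 1, name=f"{el}{i + 1}", element=el, coords=xyz,
             residue_name="LIG", residue_number=1, chain_id="A", is_hetero=True)
        for i, (el, xyz) in enumerate(zip(topology.elements, coords))
    ]
    return MolecularStructure(ligand_id, LIGAND, atoms)


# ---------------------------------------------------------------------------
# receptor generation


def _spherical_helix(
    n: int, radius: float, theta_span: tuple[float, float], chord: float, phi0: float
) -> np.ndarray:
    """CA positions along a helical path on a sphere around the origin."""
    theta0, theta1 = np.deg2rad(theta_span)
    thetas = np.linspace(theta0, theta1, n)
    dtheta = float(thetas[1] - thetas[0]) if n > 1 else 0.0
    phis = np.empty(n)
    phis[0] = phi0
    for k in range(1, n):
        arc = (radius * dtheta) ** 2
        dphi = np.sqrt(max(chord**2 - arc, 0.25)) / (radius * np.sin(thetas[k]))
        phis[k] = phis[k - 1] + dphi
    return np.stack(
        [
            radius * np.sin(thetas) * np.cos(phis),
            radius * np.sin(thetas) * np.sin(phis),
            radius * np.cos(thetas),
        ],
        axis=1,
    )


def _receptor_scaffold(
    rng: np.random.Generator,
    n_residues: int,
    radius: float,
    theta_span: tuple[float, float],
    chord: float,
    receptor_id: str,
) -> MolecularStructure:
    ca = _spherical_helix(n_residues, radius, theta_span, chord, phi0=float(rng.uniform(0, 2 * np.pi)))
    # idiosyncratic per-CA displacement: makes each pocket's internal
    # distance set unique, so independently generated pockets are
    # geometrically unrelated while perturbed copies still match
    ca = ca + rng.normal(0.0, SCAFFOLD_JITTER, size=ca.shape)
    atoms: list[Atom] = []
    serial = 1
    for i, p in enumerate(ca):
        u = p / np.linalg.norm(p)
        nxt = ca[i + 1] if i + 1 < n_residues else ca[i - 1]
        t = nxt - p
        t = t - (t @ u) * u
        t_norm = np.linalg.norm(t)
        t = t / t_norm if t_norm > 1e-9 else np.cross(u, [0.0, 0.0, 1.0])
        d_n = 0.6 * u + t
        d_n /= np.linalg.norm(d_n)
        d_c = 0.6 * u - t
        d_c /= np.linalg.norm(d_c)
        n_pos = p + 1.46 * d_n
        c_pos = p + 1.52 * d_c
        o_pos = c_pos + 1.23 * u
        cb_pos = p - 1.53 * u  # pseudo side chain lining the concave site
        for name, element, xyz in (
            ("N", "N", n_pos), ("CA", "C", p), ("C", "C", c_pos), ("O", "O", o_pos),
            ("CB", "C", cb_pos),
        ):
            atoms.append(
                Atom(serial=serial, name=name, element=element, coords=xyz,
                     residue_name="ALA", residue_number=i + 1, chain_id="A")
            )
            serial += 1
    return MolecularStructure(receptor_id, RECEPTOR, atoms)


# ---------------------------------------------------------------------------
# public generators


def make_toy_complex(
    config: FixtureConfig,
) -> tuple[MolecularStructure, MolecularStructure, LigandTopology]:
    """A clash-free synthetic receptor–ligand complex, deterministic per seed.

    The ligand sits at the origin inside a helical CA shell; its
    torsions are drawn from the same grid the built-in conformer
    backend enumerates.  Shell radius, span and CA spacing are drawn
    per seed so independently seeded complexes have unrelated pocket
    geometry.
    """
    rng = np.random.default_rng(split_seed(config.seed, "complex"))
    for attempt in range(30):
        topology = _random_topology(rng, config.ligand_size)
        if config.ligand_size == 1:
            coords = np.zeros((1, 3))
        else:
            bonds, n_combo = pose_gen.torsion_combinations(topology)
            combo = int(rng.integers(n_combo))
            coords = pose_gen.build_conformer(
                topology, pose_gen._combo_torsions(bonds, combo)
            )
            coords = coords - coords.mean(axis=0)
        ligand_radius = float(np.linalg.norm(coords, axis=1).max()) if len(coords) else 0.0
        # snug concave site: the CB lining sits a contact distance beyond the
        # outermost ligand atom, so near-native poses make 3-5 Å contacts
        # while distorted ones run into the wall
        radius = ligand_radius + float(rng.uniform(4.2, 5.0))
        span_width = float(rng.uniform(80.0, 140.0))
        theta_span = (90.0 - span_width / 2.0, 90.0 + span_width / 2.0)
        chord = float(rng.uniform(3.4, 4.2))
        receptor = _receptor_scaffold(
            rng, config.n_receptor_residues, radius, theta_span, chord,
            receptor_id=f"toy{config.seed % 10**8:08d}",
        )
        ligand = _ligand_structure(topology, coords, "LIG")
        dmin = np.min(
            np.linalg.norm(
                receptor.coords()[:, None, :] - ligand.coords()[None, :, :], axis=2
            )
        )
        if dmin >= MIN_SEPARATION:
            return receptor, ligand, topology
        logger.debug("fixture attempt %d clashed (min distance %.2f)", attempt, dmin)
    raise FixtureError("could not generate a clash-free complex within retries")


def perturb_template(
    complex_: tuple[MolecularStructure, MolecularStructure, LigandTopology],
    noise_sigma: float,
    delete_fraction: float,
    seed: int,
    cutoff: float = DEFAULT_CUTOFF,
    ligand_noise_sigma: float | None = None,
) -> TemplateRecord:
    """Template record from a jittered, partially deleted copy of a complex.

    Emulates an imperfect experimental template: Gaussian coordinate
    noise on receptor and ligand plus random deletion of ligand atoms.
    ``ligand_noise_sigma`` defaults to ``noise_sigma``; passing a smaller
    value models a template whose pocket deviates structurally while its
    bound ligand is known to crystallographic precision.
    """
    if not 0 <= delete_fraction < 1:
        raise FixtureError("delete_fraction must be in [0, 1)")
    if ligand_noise_sigma is None:
        ligand_noise_sigma = noise_sigma
    receptor, ligand, _ = complex_
    rng = np.random.default_rng(split_seed(seed, "perturb"))
    rec = receptor.with_coords(
        receptor.coords() + rng.normal(0.0, noise_sigma, size=(len(receptor), 3))
    )
    lig = ligand.with_coords(
        ligand.coords() + rng.normal(0.0, ligand_noise_sigma, size=(len(ligand), 3))
    )
    n = len(lig)
    n_delete = int(round(delete_fraction * n))
    if n_delete >= n:
        raise FixtureError("deletion would remove every ligand atom")
    if n_delete:
        drop = set(rng.choice(n, size=n_delete, replace=False).tolist())
        lig = MolecularStructure(
            lig.id, LIGAND, [a for i, a in enumerate(lig.atoms) if i not in drop]
        )
    return make_record(
        rec, lig, cutoff,
        meta={"perturbed": True, "noise_sigma": noise_sigma, "delete_fraction": delete_fraction},
    )


def make_library(
    n_records: int,
    true_complex: tuple[MolecularStructure, MolecularStructure, LigandTopology],
    config: FixtureConfig,
    cutoff: float = DEFAULT_CUTOFF,
) -> TemplateLibrary:
    """Planted-template library: one perturbed copy of the true complex
    plus ``n_records - 1`` decoys with unrelated pocket geometry.

    Exactly one record carries ``meta["planted"] = True``.
    """
    if n_records < 1:
        raise FixtureError("need n_records >= 1")
    library = TemplateLibrary()
    planted = perturb_template(
        true_complex, config.pocket_noise_sigma, 0.0,
        seed=split_seed(config.seed, "planted"), cutoff=cutoff,
        ligand_noise_sigma=TEMPLATE_LIGAND_SIGMA,
    )
    planted.meta["planted"] = True
    library.add(planted)
    for i in range(n_records - 1):
        decoy_cfg = replace(config, seed=split_seed(config.seed, f"decoy{i}"))
        receptor, ligand, _ = make_toy_complex(decoy_cfg)
        record = make_record(receptor, ligand, cutoff, meta={"planted": False})
        library.add(record)
    return library
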