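"""Conformer generation and template-guided pose generation."""

import numpy as np
import pytest

from codock import graph_align, structio
from codock.fixtures import FixtureConfig, make_toy_complex, perturb_template, split_seed
from codock.pose_gen import (
    ConformerError,
    align_to_template,
    build_conformer,
    generate_conformers,
    generate_poses,
    place_ion,
    rotatable_bonds,
    torsion_combinations,
    _combo_torsions,
)
from codock.structio import LIGAND, Atom, LigandTopology, MolecularStructure, parse_smiles
from codock.evaluate import docking_rmsd
from codock.graph_align import superpose

from conftest import random_rotation


def _structure_from(topology, coords, sid="lig"):
    atoms = [
        Atom(i + 1, f"{el}{i + 1}", el, c)
        for i, (el, c) in enumerate(zip(topology.elements, coords))
    ]
    return MolecularStructure(sid, LIGAND, atoms)


BUTANE = LigandTopology(["C", "C", "C", "C"], [(0, 1, 1.0), (1, 2, 1.0), (2, 3, 1.0)])


# ---------------------------------------------------------------------------
# conformers


def test_single_atom_one_conformer_at_origin():
    topo = parse_smiles("O")
    cs = generate_conformers(topo, n=5, seed=1)
    assert len(cs) == 1
    np.testing.assert_allclose(cs.conformers[0], np.zeros((1, 3)))


def test_rdkit_backend_deterministic():
    topo = parse_smiles("CCO")
    a = generate_conformers(topo, n=10, seed=42)
    b = generate_conformers(topo, n=10, seed=42)
    assert a.backend == "rdkit"
    assert len(a) == len(b)
    for ca, cb in zip(a.conformers, b.conformers):
        assert np.array_equal(ca, cb)


def test_fallback_backend_deterministic_and_diverse():
    cs1 = generate_conformers(BUTANE, n=20, seed=0, backend="fallback")
    cs2 = generate_conformers(BUTANE, n=20, seed=0, backend="fallback")
    for a, b in zip(cs1.conformers, cs2.conformers):
        assert np.array_equal(a, b)
    # one rotatable bond -> all 3 grid torsions enumerated
    assert len(cs1) == 3
    rmsds = []
    for i in range(len(cs1)):
        for j in range(i + 1, len(cs1)):
            _, r = superpose(cs1.conformers[i], cs1.conformers[j])
            rmsds.append(r)
    assert max(rmsds) > 0.5  # torsional diversity after best rigid fit


def test_fallback_bond_lengths_in_sanity_band(toy_complex):
    _, _, topology = toy_complex
    cs = generate_conformers(topology, n=9, seed=5, backend="fallback")
    for conf in cs.conformers:
        for i, j, _ in topology.bonds:
            d = np.linalg.norm(conf[i] - conf[j])
            assert 0.9 <= d <= 1.9


def test_fallback_refuses_rings():
    ring = parse_smiles("C1CC1")
    with pytest.raises(ConformerError, match="acyclic"):
        generate_conformers(ring, n=5, seed=0, backend="fallback")


def test_rdkit_invalid_topology_error():
    topo = LigandTopology(["C", "C"], [(0, 1, 1.0)], source_smiles=None)
    with pytest.raises(ConformerError):
        generate_conformers(topo, n=5, seed=0, backend="rdkit")


# ---------------------------------------------------------------------------
# ligand alignment


def test_align_identical_conformer_recovers_pose(toy_complex):
    _, ligand, topology = toy_complex
    template = ligand
    pose = align_to_template(ligand.coords(), topology, template)
    assert docking_rmsd(pose.coords, template) < 1e-6
    assert pose.alignment.s_t == 1.0


def test_align_template_with_extra_atom():
    """Template = conformer plus one extra atom: s_t = 10/11."""
    rng = np.random.default_rng(8)
    coords = rng.uniform(-4, 4, size=(10, 3))
    topo = LigandTopology(
        ["C"] * 10, [(i, i + 1, 1.0) for i in range(9)]
    )
    extra = np.vstack([coords, [[20.0, 0.0, 0.0]]])
    template = _structure_from(
        LigandTopology(["C"] * 11, [(i, i + 1, 1.0) for i in range(10)]), extra, "t"
    )
    # exhaustive clique oracle on a subgraph within the exact-search guard
    g_small = graph_align.build_graph(
        _structure_from(topo, coords).atoms[:7], template.atoms[:7], 0.5
    )
    assert len(graph_align.exact_max_clique(g_small)) == 7
    pose = align_to_template(coords, topo, template)
    assert pose.alignment.n_shared == 10
    assert pose.alignment.n_template == 11
    assert pose.alignment.s_t == pytest.approx(10 / 11)


def test_shared_rigid_core_lands_on_template():
    """Six shared core atoms land on the template core within epsilon."""
    rng = np.random.default_rng(21)
    core = rng.uniform(-2, 2, size=(6, 3))
    # conformer: core + 2 atoms on one side; template: core + 3 elsewhere
    conf_coords = np.vstack([core, [[5.0, 0, 0], [6.0, 0, 0]]])
    conf_topo = LigandTopology(["C"] * 8, [(i, i + 1, 1.0) for i in range(7)])
    templ_coords = np.vstack([core, [[0, 5.0, 0], [0, 6.0, 0], [0, 7.0, 0]]])
    templ = _structure_from(
        LigandTopology(["C"] * 9, [(i, i + 1, 1.0) for i in range(8)]), templ_coords, "t"
    )
    rot, shift = random_rotation(rng), rng.normal(size=3)
    moved = conf_coords @ rot.T + shift
    pose = align_to_template(moved, conf_topo, templ, epsilon=0.5)
    assert pose.alignment.n_shared >= 6
    core_dev = np.linalg.norm(pose.coords[:6] - core, axis=1)
    assert core_dev.max() < 0.5


# ---------------------------------------------------------------------------
# ion placement


def _ion():
    return MolecularStructure("ion", LIGAND, [Atom(1, "ZN", "Zn", [0.0, 0.0, 0.0])])


def _pocket_alignment(rotation, translation):
    from codock.graph_align import Matching, RigidTransform, SimilarityResult

    return SimilarityResult(
        Matching([(i, i) for i in range(5)]),
        RigidTransform(rotation, translation),
        5, 5, 1.0, 0.1,
    )


def test_place_ion_identity_transform():
    template_ion = Atom(1, "ZN", "Zn", [1.0, 2.0, 3.0])
    pose = place_ion(_ion(), _pocket_alignment(np.eye(3), np.zeros(3)), template_ion)
    np.testing.assert_allclose(pose.coords[0], [1.0, 2.0, 3.0], atol=1e-12)


def test_place_ion_equivariant_under_pocket_rotation():
    rot = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])  # +90 deg z
    template_ion = Atom(1, "MG", "Mg", [1.0, 0.0, 0.0])
    # pocket transform maps query -> template; ion goes through the inverse
    pose = place_ion(_ion(), _pocket_alignment(rot, np.zeros(3)), template_ion)
    np.testing.assert_allclose(pose.coords[0], rot.T @ np.array([1.0, 0.0, 0.0]), atol=1e-12)


def test_place_ion_rejects_multi_atom(toy_complex):
    _, ligand, _ = toy_complex
    with pytest.raises(ConformerError):
        place_ion(ligand, _pocket_alignment(np.eye(3), np.zeros(3)), ligand.atoms[0])


def test_place_ion_accuracy_under_pocket_noise():
    """Ion lands within 1 Å of truth for sigma = 0.2 pocket noise, 10 seeds."""
    for seed in range(10):
        config = FixtureConfig(seed=200 + seed, ligand_size=1)
        receptor, ion, topo = make_toy_complex(config)
        record = perturb_template(
            (receptor, ion, topo), 0.2, 0.0, seed=split_seed(seed, "ion")
        )
        from codock.template_search import extract_pocket

        query_pocket = extract_pocket(receptor, structio.centroid(ion, heavy_only=True))
        result = graph_align.align(
            query_pocket.as_structure(), record.pocket.as_structure(),
            epsilon=1.0, compat="ca",
        )
        template_ion = record.template_ligand.atoms[0]
        pose = place_ion(ion, result, template_ion)
        assert np.linalg.norm(pose.coords[0] - ion.atoms[0].coords) < 1.0


# ---------------------------------------------------------------------------
# pose generation


def test_single_conformer_single_pose(toy_complex, toy_library):
    receptor, ligand, topology = toy_complex
    record = [r for r in toy_library.records if r.meta.get("planted")][0]
    from codock.template_search import extract_pocket

    pocket = extract_pocket(receptor, structio.centroid(ligand))
    pa = graph_align.align(
        pocket.as_structure(), record.pocket.as_structure(), epsilon=1.0, compat="ca"
    )
    from codock.pose_gen import ConformerSet

    cs = ConformerSet(topology, [ligand.coords()], seed=0, backend="given")
    poses = generate_poses(cs, record, pa)
    assert len(poses) == 1


def test_identical_conformers_dedup_to_one(toy_complex, toy_library):
    receptor, ligand, topology = toy_complex
    record = [r for r in toy_library.records if r.meta.get("planted")][0]
    from codock.template_search import extract_pocket
    from codock.pose_gen import ConformerSet

    pocket = extract_pocket(receptor, structio.centroid(ligand))
    pa = graph_align.align(
        pocket.as_structure(), record.pocket.as_structure(), epsilon=1.0, compat="ca"
    )
    cs = ConformerSet(topology, [ligand.coords().copy() for _ in range(10)], 0, "given")
    poses = generate_poses(cs, record, pa, dedup_rmsd=0.5)
    assert len(poses) == 1


def test_dedup_matches_pairwise_clustering_oracle(toy_complex, toy_library):
    receptor, ligand, topology = toy_complex
    record = [r for r in toy_library.records if r.meta.get("planted")][0]
    from codock.template_search import extract_pocket
    from codock.pose_gen import ConformerSet, align_to_template

    pocket = extract_pocket(receptor, structio.centroid(ligand))
    pa = graph_align.align(
        pocket.as_structure(), record.pocket.as_structure(), epsilon=1.0, compat="ca"
    )
    cs = generate_conformers(topology, n=20, seed=13, backend="fallback")
    poses = generate_poses(cs, record, pa, dedup_rmsd=0.5)

    # oracle: recompute all candidate poses, then greedy leader clustering
    # in descending-s_t order with an O(n^2) distance matrix
    candidates = []
    for k, conf in enumerate(cs.conformers):
        p = align_to_template(conf, topology, record.template_ligand,
                              conformer_index=k, template_id=record.template_id)
        p.coords = pa.transform.inverse().apply(p.coords)
        candidates.append(p)
    order = sorted(range(len(candidates)), key=lambda i: (-candidates[i].s_t, i))
    kept = []
    for i in order:
        d = [np.sqrt(((candidates[i].coords - candidates[j].coords) ** 2)
                     .sum(axis=1).mean()) for j in kept]
        if all(x >= 0.5 for x in d):
            kept.append(i)
    assert sorted(p.conformer_index for p in poses) == sorted(kept)


def test_redocking_identity(toy_complex):
    """A template built from the unperturbed complex redocks its own ligand."""
    receptor, ligand, topology = toy_complex
    record = perturb_template((receptor, ligand, topology), 0.0, 0.0, seed=1)
    from codock.template_search import extract_pocket
    from codock.pose_gen import ConformerSet

    pocket = extract_pocket(receptor, structio.centroid(ligand))
    pa = graph_align.align(
        pocket.as_structure(), record.pocket.as_structure(), epsilon=1.0, compat="ca"
    )
    cs = ConformerSet(topology, [ligand.coords()], 0, "given")
    poses = generate_poses(cs, record, pa)
    assert docking_rmsd(poses[0], ligand) < 0.1


def test_frame_correctness_under_receptor_motion(rng, toy_complex):
    """Moving the query receptor moves every pose by the same rigid motion."""
    receptor, ligand, topology = toy_complex
    record = perturb_template((receptor, ligand, topology), 0.0, 0.0, seed=2)
    from codock.template_search import extract_pocket
    from codock.pose_gen import ConformerSet

    def poses_for(rec, center):
        pocket = extract_pocket(rec, center)
        pa = graph_align.align(
            pocket.as_structure(), record.pocket.as_structure(), epsilon=1.0, compat="ca"
        )
        cs = generate_conformers(topology, n=9, seed=3, backend="fallback")
        return generate_poses(cs, record, pa)

    base = poses_for(receptor, structio.centroid(ligand))
    rot, shift = random_rotation(rng), rng.normal(size=3)
    moved_receptor = receptor.with_coords(receptor.coords() @ rot.T + shift)
    moved = poses_for(moved_receptor, structio.centroid(ligand) @ rot.T + shift)
    assert len(base) == len(moved)
    for a, b in zip(base, moved):
        np.testing.assert_allclose(b.coords, a.coords @ rot.T + shift, atol=1e-6)
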