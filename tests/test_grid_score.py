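"""Grid featurization, atom typing, scoring and submission selection."""

import numpy as np
import pytest

from codock import structio
from codock.grid_score import (
    GridError,
    GridSpec,
    LIGAND_TYPES,
    N_CHANNELS,
    RECEPTOR_TYPES,
    ScoreResult,
    ScoringError,
    assign_atom_types,
    external_score,
    featurize,
    select_submission,
    surrogate_score,
)
from codock.pose_gen import Pose
from codock.structio import LIGAND, RECEPTOR, Atom, LigandTopology, MolecularStructure


def _structure(coords, elements, role=LIGAND, sid="s"):
    atoms = [
        Atom(i + 1, f"{e}{i + 1}", e, c, is_hetero=(role == LIGAND))
        for i, (e, c) in enumerate(zip(elements, np.atleast_2d(coords)))
    ]
    return MolecularStructure(sid, role, atoms)


def _pose(coords, elements):
    topo = LigandTopology(
        list(elements), [(i, i + 1, 1.0) for i in range(len(elements) - 1)]
    )
    return Pose(np.atleast_2d(np.asarray(coords, float)), topo, 0, "t")


# ---------------------------------------------------------------------------
# atom typing


def test_channel_counts_are_the_contract():
    assert len(RECEPTOR_TYPES) == 16
    assert len(LIGAND_TYPES) == 18
    assert N_CHANNELS == 34


def test_cno_get_distinct_ligand_labels():
    s = _structure(np.zeros((3, 3)) + np.arange(3)[:, None], ["C", "N", "O"])
    labels = assign_atom_types(s, "ligand")
    assert len(set(labels)) == 3
    assert all(l in LIGAND_TYPES for l in labels)


def test_exotic_element_hits_catch_all(caplog):
    s = _structure([[0.0, 0.0, 0.0]], ["W"], role=RECEPTOR, sid="r")
    with caplog.at_level("INFO"):
        labels = assign_atom_types(s, "receptor")
    assert labels == ["rec_other"]


def test_label_histogram_matches_lookup_oracle(toy_complex):
    receptor, ligand, topology = toy_complex
    expected = {"C": "rec_C_aliphatic", "N": "rec_N_donor_acceptor", "O": "rec_O_acceptor"}
    labels = assign_atom_types(receptor, "receptor")
    oracle = [expected[a.element] for a in receptor.heavy_atoms().atoms]
    assert labels == oracle


def test_aromatic_carbons_split_with_topology():
    topo = structio.parse_smiles("c1ccccc1C")
    coords = np.random.default_rng(0).uniform(-2, 2, (7, 3))
    s = _structure(coords, topo.elements)
    labels = assign_atom_types(s, "ligand", topo)
    assert labels[:6] == ["lig_C_aromatic"] * 6
    assert labels[6] == "lig_C_aliphatic"


# ---------------------------------------------------------------------------
# featurization


def test_empty_box_all_zero_default_shape():
    spec = GridSpec(center=np.zeros(3))
    receptor = _structure([[100.0, 100.0, 100.0]], ["C"], role=RECEPTOR)
    pose = _pose([[-100.0, -100.0, -100.0]], ["C"])
    tensor = featurize(receptor, pose, spec)
    assert tensor.values.shape == (34, 48, 48, 48)
    assert not tensor.values.any()


def test_single_central_carbon_peaks_at_center():
    spec = GridSpec(center=np.zeros(3))
    receptor = _structure([[100.0, 0.0, 0.0]], ["C"], role=RECEPTOR)
    pose = _pose([[0.0, 0.0, 0.0]], ["C"])
    tensor = featurize(receptor, pose, spec)
    channel = 16 + LIGAND_TYPES.index("lig_C_aliphatic")
    nonzero_channels = sorted(set(np.nonzero(tensor.values)[0].tolist()))
    assert nonzero_channels == [channel]
    peak = np.unravel_index(np.argmax(tensor.values[channel]), (48, 48, 48))
    assert all(23 <= i <= 24 for i in peak)  # atom sits between the central voxels


def test_translation_equivariance_voxel_exact(toy_complex):
    receptor, ligand, topology = toy_complex
    pose = Pose(ligand.coords(), topology, 0, "t")
    center = structio.centroid(ligand)
    spec = GridSpec(center=center)
    base = featurize(receptor, pose, spec)
    shift = np.array([spec.spacing, 0.0, 0.0])
    moved = featurize(
        receptor.with_coords(receptor.coords() + shift),
        Pose(pose.coords + shift, topology, 0, "t"),
        GridSpec(center=center + shift),
    )
    assert np.array_equal(base.values, moved.values)


def test_rotation_covariance_90_degrees(toy_complex):
    receptor, ligand, topology = toy_complex
    pose = Pose(ligand.coords(), topology, 0, "t")
    spec = GridSpec(center=np.zeros(3))
    base = featurize(receptor, pose, spec)
    rot = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
    turned = featurize(
        receptor.with_coords(receptor.coords() @ rot.T),
        Pose(pose.coords @ rot.T, topology, 0, "t"),
        spec,
    )
    # (x, y, z) -> (-y, x, z): new[i, j, k] == old[j, N-1-i, k]
    expected = np.rot90(base.values, k=1, axes=(1, 2))
    assert np.array_equal(turned.values, expected)


def test_channel_separation(toy_complex):
    receptor, ligand, topology = toy_complex
    pose = Pose(ligand.coords(), topology, 0, "t")
    spec = GridSpec(center=structio.centroid(ligand))
    tensor = featurize(receptor, pose, spec)
    receptor_sum = tensor.values[:16].sum()
    ligand_sum = tensor.values[16:].sum()
    assert receptor_sum > 0 and ligand_sum > 0
    # swapping the pose leaves receptor channels untouched and vice versa
    other_pose = Pose(ligand.coords() + 0.7, topology, 0, "t")
    tensor2 = featurize(receptor, other_pose, spec)
    assert np.array_equal(tensor.values[:16], tensor2.values[:16])
    far_receptor = receptor.with_coords(receptor.coords() + 100.0)
    tensor3 = featurize(far_receptor, pose, spec)
    assert np.array_equal(tensor.values[16:], tensor3.values[16:])


def test_bad_box_spacing_ratio_rejected():
    with pytest.raises(GridError):
        GridSpec(center=np.zeros(3), box_edge=24.0, spacing=0.7)


def test_tensor_save_sidecar(tmp_path, toy_complex):
    receptor, ligand, topology = toy_complex
    tensor = featurize(
        receptor, Pose(ligand.coords(), topology, 0, "t"),
        GridSpec(center=structio.centroid(ligand)),
    )
    out = tmp_path / "grid.npy"
    tensor.save(out)
    assert np.array_equal(np.load(out), tensor.values)
    assert (tmp_path / "grid.json").exists()


# ---------------------------------------------------------------------------
# surrogate scorer


def test_far_apart_scores_zero():
    receptor = _structure([[0.0, 0.0, 0.0]], ["C"], role=RECEPTOR)
    assert surrogate_score(receptor, _pose([[10.0, 0.0, 0.0]], ["C"])).pose_score == 0.0


def test_single_contact_scores_one():
    receptor = _structure([[0.0, 0.0, 0.0]], ["C"], role=RECEPTOR)
    assert surrogate_score(receptor, _pose([[4.0, 0.0, 0.0]], ["C"])).pose_score == 1.0


def test_clash_deepening_monotone():
    receptor = _structure([[0.0, 0.0, 0.0]], ["C"], role=RECEPTOR)
    distances = np.arange(3.0, 0.99, -0.25)
    scores = [
        surrogate_score(receptor, _pose([[d, 0.0, 0.0]], ["C"])).pose_score
        for d in distances
    ]
    assert all(a >= b for a, b in zip(scores, scores[1:]))
    assert scores[0] == 1.0
    assert scores[-1] == -10.0


def test_native_beats_displaced_pose(toy_complex):
    receptor, ligand, topology = toy_complex
    native = Pose(ligand.coords(), topology, 0, "t")
    out_dir = ligand.coords().mean(axis=0)
    shifted = Pose(ligand.coords() + np.array([6.0, 0.0, 0.0]), topology, 0, "t")
    native_score = surrogate_score(receptor, native).pose_score
    shifted_score = surrogate_score(receptor, shifted).pose_score
    assert native_score > shifted_score


# ---------------------------------------------------------------------------
# external scorer hook


MOCK = """\
import sys
poses = open(sys.argv[2]).read().count("$$$$")
{body}
"""


def _write_mock(tmp_path, body):
    script = tmp_path / "mock_scorer.py"
    script.write_text(MOCK.format(body=body))
    return f"python {script} {{receptor}} {{poses}}"


@pytest.fixture()
def pose_files(tmp_path, toy_complex):
    receptor, ligand, topology = toy_complex
    poses = [Pose(ligand.coords() + 0.1 * k, topology, k, "t") for k in range(3)]
    receptor_path = tmp_path / "receptor.pdb"
    poses_path = tmp_path / "poses.sdf"
    structio.write_pdb(receptor, receptor_path)
    structio.write_poses(poses, poses_path)
    return receptor_path, poses_path


def test_external_scores_parsed_verbatim(tmp_path, pose_files):
    cmd = _write_mock(
        tmp_path, "print('\\n'.join(f'{i} {1.5*i} {-7.0 - i}' for i in range(poses)))"
    )
    results = external_score(*pose_files, cmd)
    assert [r.pose_score for r in results] == [0.0, 1.5, 3.0]
    assert [r.affinity for r in results] == [-7.0, -8.0, -9.0]


def test_external_count_mismatch_rejected(tmp_path, pose_files):
    cmd = _write_mock(
        tmp_path, "print('\\n'.join(f'{i} 1.0' for i in range(poses - 1)))"
    )
    with pytest.raises(ScoringError):
        external_score(*pose_files, cmd)


def test_external_shuffled_ids_reassociated(tmp_path, pose_files):
    cmd = _write_mock(
        tmp_path,
        "order = list(range(poses))[::-1]\n"
        "print('\\n'.join(f'{i} {10.0 + i}' for i in order))",
    )
    results = external_score(*pose_files, cmd)
    assert [r.pose_score for r in results] == [10.0, 11.0, 12.0]


def test_external_missing_executable(pose_files):
    with pytest.raises(ScoringError):
        external_score(*pose_files, "no_such_scorer_binary {receptor} {poses}")


# ---------------------------------------------------------------------------
# submission selection


def _scored_poses(rng, n):
    topo = LigandTopology(["C"], [])
    poses = [Pose(np.zeros((1, 3)), topo, k, "t") for k in range(n)]
    scores = [ScoreResult(float(s)) for s in rng.normal(size=n)]
    return poses, scores


def test_thirty_poses_give_five_by_five(rng):
    poses, scores = _scored_poses(rng, 30)
    groups = select_submission(poses, scores)
    assert [len(g) for g in groups] == [5, 5, 5, 5, 5]
    top = max(range(30), key=lambda i: scores[i].pose_score)
    assert groups[0][0] is poses[top]


def test_seven_poses_split_five_two(rng):
    poses, scores = _scored_poses(rng, 7)
    groups = select_submission(poses, scores)
    assert [len(g) for g in groups] == [5, 2]


def test_order_matches_independent_stable_sort(rng):
    poses, scores = _scored_poses(rng, 23)
    groups = select_submission(poses, scores)
    got = [p.conformer_index for g in groups for p in g]
    want = [
        i for i in sorted(
            range(23), key=lambda i: (-scores[i].pose_score, -poses[i].s_t, i)
        )
    ]
    assert got == want


def test_empty_pose_list_rejected():
    with pytest.raises(ScoringError):
        select_submission([], [])
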