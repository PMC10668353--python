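"""Correspondence-graph 3D structural alignment.

The alignment treats every compatible (query atom, template atom) pairing
as a node of a *correspondence graph*.  Two nodes are adjacent when their
query atoms and their template atoms are separated by equivalent distances
(within a tolerance ``epsilon``), so a clique — a completely connected
subgraph — is a set of pairings consistent with one rigid-body motion.
A seeded greedy search extracts a large clique quickly; an exhaustive
Bron–Kerbosch search (via networkx) is provided as the exact reference.
The matched pairs are superposed by a least-squares rigid fit (Kabsch)
and the similarity coefficient is

    S_T = N_S / N_T

with ``N_S`` the number of matched atoms and ``N_T`` the template atom
count.  Templates with S_T strictly above 0.8 count as highly similar.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import networkx as nx
import numpy as np
from scipy.spatial.distance import cdist

from .structio import Atom, MolecularStructure

#: distance-equivalence tolerance for CA-based pocket alignment (Å)
POCKET_EPSILON = 1.0
#: distance-equivalence tolerance for heavy-atom ligand alignment (Å)
LIGAND_EPSILON = 0.5
#: greedy multi-start seed count
DEFAULT_N_SEEDS = 10
#: smallest clique that still defines a unique rigid rotation
MIN_CLIQUE = 3
#: node-count guard for the exact clique search
EXACT_CLIQUE_GUARD = 64

CompatRule = Callable[[Atom, Atom], bool]


class AlignmentError(ValueError):
    """Raised for invalid alignment parameters or inputs."""


def _compat_rule(compat: str | CompatRule) -> CompatRule:
    if callable(compat):
        return compat
    if compat == "element":
        return lambda q, t: q.element == t.element
    if compat in ("all", "ca"):
        return lambda q, t: True
    raise AlignmentError(f"unknown compatibility rule {compat!r}")


@dataclass
class CorrespondenceGraph:
    """Graph of candidate atom pairings.

    ``nodes[k] = (query_index, template_index)``; ``adjacency`` is a
    symmetric, irreflexive boolean matrix.  The coordinate arrays the
    graph was built from ride along so downstream tie-breaks can
    superpose candidate cliques.
    """

    nodes: list[tuple[int, int]]
    adjacency: np.ndarray
    epsilon: float
    query_coords: np.ndarray | None = None
    template_coords: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.nodes)
        self.adjacency = np.asarray(self.adjacency, dtype=bool)
        if self.adjacency.shape != (n, n):
            raise AlignmentError("adjacency shape does not match node count")
        if n and (np.diag(self.adjacency).any() or not np.array_equal(self.adjacency, self.adjacency.T)):
            raise AlignmentError("adjacency must be symmetric and irreflexive")
        if len(set(self.nodes)) != n:
            raise AlignmentError("duplicate correspondence nodes")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)


@dataclass
class Matching:
    """A set of one-to-one atom pairings; ``clique`` marks mutual adjacency."""

    pairs: list[tuple[int, int]]
    clique: bool = True

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class RigidTransform:
    """Proper rigid motion ``x -> R x + t`` (rotation then translation)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise AlignmentError("transform must be a 3x3 rotation and 3-vector")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-9):
            raise AlignmentError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(self.rotation), 1.0, atol=1e-9):
            raise AlignmentError("rotation must be proper (det +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        rot = self.rotation.T
        return RigidTransform(rot, -rot @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equal to applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )


@dataclass
class SimilarityResult:
    """Outcome of one query-vs-template alignment."""

    matching: Matching
    transform: RigidTransform
    n_shared: int
    n_template: int
    s_t: float
    fit_rmsd: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.n_shared <= self.n_template):
            raise AlignmentError("need 0 <= N_S <= N_T")
        if self.n_template and self.s_t != self.n_shared / self.n_template:
            raise AlignmentError("S_T must equal N_S / N_T exactly")

    @property
    def high_similar(self) -> bool:
        """Strictly above the 0.8 similarity threshold."""
        return self.s_t > 0.8


# ---------------------------------------------------------------------------
# graph construction


def build_graph(
    query_atoms: Sequence[Atom],
    template_atoms: Sequence[Atom],
    epsilon: float,
    compat: str | CompatRule = "element",
) -> CorrespondenceGraph:
    """Build the correspondence graph of two atom sets.

    Nodes are all compatible (query, template) pairings; nodes
    ``(q1, t1)`` and ``(q2, t2)`` are adjacent iff ``q1 != q2``,
    ``t1 != t2`` and ``|d(q1, q2) - d(t1, t2)| <= epsilon``.
    """
    if epsilon <= 0:
        raise AlignmentError(f"epsilon must be positive, got {epsilon}")
    if not query_atoms or not template_atoms:
        raise AlignmentError("both atom lists must be non-empty")
    rule = _compat_rule(compat)
    qc = np.array([a.coords for a in query_atoms], dtype=float)
    tc = np.array([a.coords for a in template_atoms], dtype=float)
    nodes = [
        (qi, ti)
        for qi in range(len(query_atoms))
        for ti in range(len(template_atoms))
        if rule(query_atoms[qi], template_atoms[ti])
    ]
    if not nodes:
        return CorrespondenceGraph([], np.zeros((0, 0), dtype=bool), epsilon, qc, tc)
    q_idx = np.array([n[0] for n in nodes])
    t_idx = np.array([n[1] for n in nodes])
    dq = cdist(qc, qc)
    dt = cdist(tc, tc)
    adjacency = (
        (q_idx[:, None] != q_idx[None, :])
        & (t_idx[:, None] != t_idx[None, :])
        & (np.abs(dq[np.ix_(q_idx, q_idx)] - dt[np.ix_(t_idx, t_idx)]) <= epsilon)
    )
    np.fill_diagonal(adjacency, False)
    return CorrespondenceGraph(nodes, adjacency, epsilon, qc, tc)


# ---------------------------------------------------------------------------
# clique search


def _pairs_rmsd(graph: CorrespondenceGraph, members: Sequence[int]) -> float:
    if graph.query_coords is None or graph.template_coords is None or len(members) == 0:
        return np.inf
    q = graph.query_coords[[graph.nodes[m][0] for m in members]]
    t = graph.template_coords[[graph.nodes[m][1] for m in members]]
    _, rmsd = superpose(q, t)
    return rmsd


def greedy_clique(graph: CorrespondenceGraph, n_seeds: int = DEFAULT_N_SEEDS) -> Matching:
    """Seeded greedy clique search.

    Fixed procedure: take the ``n_seeds`` highest-degree nodes (ties by
    node order) as starting points; from each, repeatedly add the
    candidate adjacent to all current members with the highest degree
    among the remaining candidates (ties by node order).  The largest
    clique over all seeds wins; equal sizes are broken by the smaller
    superposition RMSD of the matched pairs, then by node order.
    """
    if graph.n_nodes == 0:
        return Matching([], clique=True)
    adj = graph.adjacency
    degrees = graph.degrees()
    order = np.lexsort((np.arange(graph.n_nodes), -degrees))
    seeds = order[: max(1, n_seeds)]
    best: list[int] | None = None
    best_key: tuple = ()
    for seed in seeds:
        members = [int(seed)]
        cand = np.flatnonzero(adj[seed])
        while cand.size:
            sub_deg = adj[np.ix_(cand, cand)].sum(axis=1)
            pick = cand[np.lexsort((cand, -sub_deg))[0]]
            members.append(int(pick))
            cand = cand[adj[pick, cand]]
        key = (-len(members), _pairs_rmsd(graph, members), tuple(sorted(members)))
        if best is None or key < best_key:
            best, best_key = members, key
    pairs = [graph.nodes[m] for m in sorted(best)]
    return Matching(pairs, clique=True)


def exact_max_clique(graph: CorrespondenceGraph) -> Matching:
    """Exact maximum clique via Bron–Kerbosch with pivoting.

    Guarded to at most ``EXACT_CLIQUE_GUARD`` nodes; ties between equal
    maximum cliques are broken lexicographically on sorted node indices.
    """
    if graph.n_nodes > EXACT_CLIQUE_GUARD:
        raise AlignmentError(
            f"exact clique search refused for {graph.n_nodes} nodes "
            f"(guard {EXACT_CLIQUE_GUARD})"
        )
    if graph.n_nodes == 0:
        return Matching([], clique=True)
    g = nx.from_numpy_array(graph.adjacency)
    best: tuple[int, ...] | None = None
    for clique in nx.find_cliques(g):
        cand = tuple(sorted(clique))
        if best is None or (-len(cand), cand) < (-len(best), best):
            best = cand
    pairs = [graph.nodes[m] for m in best]
    return Matching(pairs, clique=True)


# ---------------------------------------------------------------------------
# superposition


def superpose(
    query_coords: np.ndarray, template_coords: np.ndarray
) -> tuple[RigidTransform, float]:
    """Least-squares rigid fit of query onto template points (Kabsch).

    Returns the proper rigid transform minimising the RMSD of
    ``transform.apply(query) - template`` together with that RMSD.
    A single pair yields a pure translation; reflections are corrected
    to a proper rotation.
    """
    q = np.atleast_2d(np.asarray(query_coords, dtype=float))
    t = np.atleast_2d(np.asarray(template_coords, dtype=float))
    if q.shape != t.shape or q.ndim != 2 or q.shape[1] != 3:
        raise AlignmentError("superpose needs matching (N, 3) coordinate arrays")
    if q.shape[0] == 0:
        raise AlignmentError("superpose needs at least one pair")
    if q.shape[0] == 1:
        return RigidTransform(np.eye(3), t[0] - q[0]), 0.0
    qc = q.mean(axis=0)
    tc = t.mean(axis=0)
    h = (q - qc).T @ (t - tc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    transform = RigidTransform(rot, tc - rot @ qc)
    delta = transform.apply(q) - t
    rmsd = float(np.sqrt((delta**2).sum(axis=1).mean()))
    return transform, rmsd


# ---------------------------------------------------------------------------
# full alignment


def align(
    query: MolecularStructure,
    template: MolecularStructure,
    epsilon: float = LIGAND_EPSILON,
    compat: str | CompatRule = "element",
    n_seeds: int = DEFAULT_N_SEEDS,
    min_clique: int = MIN_CLIQUE,
) -> SimilarityResult:
    """Align a query structure onto a template structure.

    ``compat="element"`` aligns heavy atoms requiring identical elements
    (ligand mode); ``compat="ca"`` aligns CA traces with all pairings
    allowed (pocket mode).  ``n_template`` is the selected template atom
    count, so ``s_t = clique size / n_template``.  Cliques smaller than
    ``min_clique`` leave the result flagged degenerate.
    """
    if compat == "ca":
        q_sel, t_sel = query.ca_atoms(), template.ca_atoms()
    else:
        q_sel, t_sel = query.heavy_atoms(), template.heavy_atoms()
    if len(q_sel) == 0 or len(t_sel) == 0:
        raise AlignmentError("empty query or template after atom selection")
    graph = build_graph(q_sel.atoms, t_sel.atoms, epsilon, compat)
    matching = greedy_clique(graph, n_seeds=n_seeds)
    n_template = len(t_sel)
    n_shared = len(matching)
    if n_shared == 0:
        return SimilarityResult(
            matching, RigidTransform.identity(), 0, n_template, 0.0, np.inf, degenerate=True
        )
    q = q_sel.coords()[[p[0] for p in matching.pairs]]
    t = t_sel.coords()[[p[1] for p in matching.pairs]]
    transform, fit_rmsd = superpose(q, t)
    return SimilarityResult(
        matching=matching,
        transform=transform,
        n_shared=n_shared,
        n_template=n_template,
        s_t=n_shared / n_template,
        fit_rmsd=fit_rmsd,
        degenerate=n_shared < min_clique,
    )
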