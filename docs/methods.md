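# Methods

## Correspondence-graph alignment

Structural similarity between a query and a template atom set is cast
as maximum-clique search in a correspondence graph. Nodes are
compatible atom pairings; compatibility is identical element for ligand
(heavy-atom) alignment and unrestricted for pocket (CA-trace)
alignment. Nodes (q₁,t₁) and (q₂,t₂) are adjacent iff q₁ ≠ q₂, t₂ ≠ t₁
and the intra-structure distances agree within ε. A clique therefore
certifies a distance-consistent, one-to-one matching, and its
superposition (Kabsch, SVD with reflection correction) yields the
rigid transform and the fit RMSD. The similarity coefficient is
S_T = N_S/N_T with N_S the clique size and N_T the template atom count;
S_T > 0.8 (strict) marks a highly similar template.

Parameters:

| parameter | default | role |
|---|---|---|
| ε (pocket) | 1.0 Å | distance-equivalence tolerance for CA pockets; CA geometry is coarse |
| ε (ligand) | 0.5 Å | tolerance for covalent ligand geometry, which is finer |
| n_seeds | 10 | greedy multi-start width |
| min clique | 3 | smallest matching that fixes a unique rotation; below it the result is flagged degenerate and excluded from ranking |
| pocket cutoff | 12 Å | CA selection radius around the ligand center, boundary inclusive |

The greedy search is fully deterministic: seeds are the n_seeds
highest-degree nodes (ties by node order); growth adds the candidate
adjacent to all members with the largest degree among remaining
candidates (ties by node order); the best seed wins by clique size,
then smaller fit RMSD, then node order. The exact search
(Bron–Kerbosch with pivoting, via networkx, lexicographic tie-break)
is guarded to 64 nodes and serves as the reference in tests; on the
random-graph ensemble used for validation the greedy result matches
the exact maximum on essentially every instance.

"Unique atoms shared" is read as clique cardinality; the one-to-one
adjacency rule makes every clique member unique by construction.

## Pose generation

Conformers come from RDKit ETKDG (seeded, hydrogens added then
stripped; heavy-atom order preserved) when a SMILES is available, or
from a built-in internal-coordinate builder for acyclic topologies:
ideal bond lengths by element pair, tetrahedral angles, branch
separation 120°, and rotatable-bond torsions on the fixed grid
{−60°, 60°, 180°}. When the grid has at most n combinations they are
enumerated exhaustively; otherwise a seeded sample without replacement
is used. The builder ignores stereochemistry — a documented
limitation; the RDKit backend honors SMILES stereo.

Each conformer is aligned rigidly onto the template ligand and the
whole conformer is carried by the fitted transform into the template
frame, then into the query receptor frame through the inverse pocket
transform. Unmatched atoms ride along rigidly; no torsional relaxation
is attempted inside the pocket. Poses closer than 0.5 Å in-place RMSD
collapse onto the member with the better alignment S_T (the default
submission would otherwise contain near-duplicates). Monatomic ions
bypass conformer generation entirely: the template ion position is
mapped through the inverse pocket transform.

## Scoring

The built-in surrogate scorer is a deterministic contact/clash count,
summed over receptor–ligand heavy-atom pairs at distance d:

    g(d) = −10          d < 2.5 Å      (clash)
    g(d) = linear −10→+1  2.5 ≤ d < 3.0  (continuous ramp)
    g(d) = +1           3.0 ≤ d ≤ 5.0   (contact)
    g(d) = 0            d > 5.0

The ramp endpoints make g continuous and monotone on [2.5, 3.0], so
deepening a clash can never raise the score. The surrogate is
explicitly *not* a trained CNN and is labeled as such in every output;
the external-scorer hook (command template, one
`<pose_index> <pose_score> [<affinity>]` line per pose, re-associated
by index) is the path to CNN parity.

Submission selection sorts poses by score (ties by alignment S_T, then
pose index) and cuts consecutive groups of 5 into at most 5 models;
short trailing groups are kept, never padded.

## Grid featurization

The grid is a cube of edge 24 Å at 0.5 Å spacing (48 voxels per axis),
centered on the binding site, with 34 channels: 16 receptor and 18
ligand atom types (element plus aromatic/polar subdivisions, with
catch-all labels; the tables live in `grid_score.py` and are versioned
for replacement). Voxel centers sit at center + (i + 0.5 − N/2)·spacing.
Each heavy atom deposits the quartic bump kernel

    f(d) = (1 − (d/R)²)²  for d < R,  R = 1.5 × vdW radius

into its channel: value 1 at the atom center, C¹-smooth decay to 0 at
R. Atom-minus-center offsets are quantized to 10⁻⁶ Å before
voxelization so that jointly translated inputs reproduce the tensor
bit-for-bit despite floating-point non-associativity; squared distances
are accumulated in a fixed axis order, which also makes 90° axis
rotations of all inputs produce exactly permuted tensors.

## Evaluation

Docking RMSD is the root-mean-square heavy-atom deviation in a common
frame with no superposition, the standard redocking metric; atom
correspondence defaults to shared topology order, with by-name mapping
for PDB references. Symmetry correction minimizes over automorphisms
of the element-labeled bond graph (exhaustive up to 12 heavy atoms;
beyond that it falls back to the plain value with a warning and a
flag). The plain RMSD is always reported; the corrected value is never
silently substituted. Quality categories: high ≤ 2.0 Å, accepted site
in (2.0, 5.0], failed > 5.0 Å — boundary semantics exactly as printed
in the assessment scheme the package implements. Success rate is the
fraction of systems whose best of the first k ranked poses is at or
below the cutoff.

## Synthetic fixtures

The generator produces the study conditions every test and the
acceptance script run on:

- **Receptor**: a CA trace along a spherical helix (consecutive CA
  ≈ 3.4–4.2 Å) winding around the binding site, with backbone stubs
  (N, C, O) pointing outward and a CB pseudo-side-chain pointing
  inward, lining the concave site. Every CA receives an idiosyncratic
  0.6 Å Gaussian displacement: this gives each pocket a unique internal
  distance set, so independently generated pockets are geometrically
  unrelated — two smooth helices of similar radius would otherwise
  share large near-isometric CA subsets at ε = 1.0 and defeat
  retrieval benchmarking.
- **Ligand**: a connected acyclic heavy-atom graph (C/N/O, valence
  capped), built by the same torsion-grid machinery the fallback
  conformer backend uses, with at most 2 rotatable bonds so the grid
  (≤ 9 combinations) is exhaustively enumerable within the default
  20-conformer budget — redocking is then a well-posed
  self-consistency test. The shell radius is the outermost ligand atom
  + 4.2–5.0 Å, so native poses make 3–5 Å contacts with the CB lining
  while distorted poses clash; receptor–ligand separation is
  guaranteed ≥ 2.5 Å by rejection sampling.
- **Templates**: a planted record is a copy of the true complex with
  Gaussian pocket noise (default σ = 0.3 Å, emulating receptor-side
  structural deviation, the dominant error source in template docking)
  and a smaller σ = 0.15 Å on the template ligand (crystal-ligand
  coordinate precision — the template ligand is the same chemical
  species in essentially its solved conformation, while pockets differ
  by side-chain and backbone rearrangement). Decoys are independently
  generated complexes. `perturb_template` also supports random ligand
  atom deletion for partial-template scenarios.
- **Seeding**: one global seed is split per purpose via SHA-256
  (`split_seed(seed, tag)` < 2³¹), so any component is reproducible in
  isolation and all outputs are byte-identical per seed.

What the fixtures do *not* emulate: real protein side-chain chemistry
and rotamers, ring-containing or stereochemically constrained ligands,
solvent, and the statistics of a curated template database. Passing
tests therefore demonstrate the geometric and algorithmic correctness
of the protocol — retrieval, alignment, frame bookkeeping, ranking and
evaluation — not docking accuracy on real complexes.

## Problem sizes

The validation ensemble uses 100 random correspondence graphs of up to
12 nodes (exact clique vs 2ⁿ enumeration), 20 structures for
self-alignment, 20 replicates × 10-record libraries for retrieval and
the 4-level noise sweep, and 10 end-to-end redocking systems (24
residues, 8 heavy-atom ligands, 10-record libraries). These sizes keep
the full suite and the acceptance script in the tens of seconds on one
CPU while leaving every rate estimated from enough replicates to be
stable across seeds.

## Known limitations

- Flexible-receptor effects and in-pocket torsional refinement are out
  of scope; partially matching ligands keep their rigid conformer.
- The fallback conformer builder rejects rings and ignores chirality.
- The surrogate scorer is a geometric stand-in; quantitative pose
  scores are only meaningful relative to other poses of the same
  system.
- Blind-site scanning (no center supplied) evaluates candidate centers
  on every CA and is O(n_CA × library); intended for small receptors
  and libraries.
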