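# Methods

## The model

bsmm compares two protein ligand-binding sites as labeled point clouds.
Given a protein–ligand complex, every residue with a heavy atom within
6.0 Å (inclusive) of any ligand heavy atom belongs to the binding site.
Residues are abstracted into physicochemical (PC) points of five classes —
hydrogen-bond acceptor (HA), donor (HD), mixed (HAD), aliphatic hydrophobic
(ALI) and aromatic (ARO) — and the PC-site keeps the points whose own
position lies within the same 6.0 Å cutoff of the ligand.  Hydrogens are
excluded throughout (heavy-atom model).

Matching is rigid-motion-invariant via geometric hashing.  Every
non-collinear point triple whose three sides lie in [d_min, d_max] is a
reference triangle; its vertices are named by the side each one faces
(P1 faces the shortest side, P3 the longest) and define a right-handed
local frame: origin at P1, x-axis toward P2, z-axis along
(P1P2 × P1P3), y = z × x.  Expressing the full site in that frame yields a
*model*; the hash file is the collection of all models, indexed by the
vertex property triple and the floor-binned side lengths.

Two hash files are compared model-against-model.  Points of the two models
that fall in the same cell of a 1.0 Å cubic grid and carry compatible
properties (HA↔{HA,HAD}, HD↔{HD,HAD}, HAD↔{HA,HD,HAD}, ALI↔{ALI,ARO},
ARO↔{ALI,ARO}) vote, one-to-one, resolved greedily by ascending distance
within a cell.  A model pair whose vote reaches the threshold (default 7,
i.e. "more than 6") is refined: Kabsch least-squares superposition of the
voted points (proper rotation, reflection corrected) gives a
query→reference transform; correspondences are extended to all compatible
point pairs strictly closer than D_cutoff = 3.0 Å (greedy, one-to-one); the
fit and extension are repeated once so that every reported pair satisfies
the cutoff under the final transform.

Scores:

* M_score = Match_num / min(R_p_num, Q_p_num) — Simpson coefficient of the
  matched points over the smaller site; the matched pair set is the
  "similar site".
* The matched reference points are clustered by single linkage at the
  subsite linkage cutoff (default 5.0 Å); the largest family is the
  "similar subsite" and is scored by the Tanimoto coefficient
  L_score = L_Match_num / (LR_p_num + LQ_p_num − L_Match_num).

The best result over all model pairs is the one maximizing
(M_score, Match_num, −fit RMSD), iterated in sorted key order so matching
is fully deterministic.  Scanning stops early once every point of the
smaller site is matched, since no later round can score higher.

When both complexes bind the same chemical component, the match transform
is validated by the cross-aligned ligand RMSD: apply the transform to the
query ligand's heavy atoms, correspond atoms by name, and measure RMSD
against the reference ligand.  RMSD < 3.0 Å (strict) is a good match.  No
graph-symmetry correction is applied, so a symmetric or head-to-tail binder
legitimately reports a large RMSD even when the sites match well; the RMSD
then flags a different binding mode rather than a failed match.

## Parameters

| parameter | default | unit | role |
|---|---|---|---|
| site cutoff | 6.0 | Å | ligand proximity for residues and points (inclusive) |
| grid bin | 1.0 | Å | voting cell size; also the key's side-length bin |
| vote threshold | 7 | votes | minimum votes to refine a model pair ("> 6") |
| D_cutoff | 3.0 | Å | extension distance cutoff (strict <) |
| d_min / d_max | 2.0 / 13.0 | Å | admissible triangle side range |
| linkage cutoff | 5.0 | Å | single-linkage cutoff for the subsite |
| min area | 0.1 | Å² | collinearity rejection for triangles |

The 6.0 Å cutoff, 1.0 Å grid, vote > 6 and 3.0 Å D_cutoff are the method's
published operating point (a vote threshold of "> 8" is appropriate for
harder, low-homology screens).  The triangle side bounds and bin width are
configuration, not ground truth: d_min suppresses near-degenerate frames,
d_max bounds the model count, and any consistent choice preserves
correctness because both sites are hashed with the same parameters.  The
5.0 Å linkage cutoff groups matched points at roughly
residue-contact spacing.

## The typing table

The atom-to-class mapping is the largest genuinely open design choice, and
it is shipped as an editable, versioned YAML file rather than baked in.
The default follows pseudocenter conventions long used for cavity
comparison: carboxylate/amide oxygens and backbone O are HA; Lys NZ,
Arg guanidinium nitrogens, Trp NE1, amide NH2 groups and backbone N
(except proline) are HD; hydroxyls, Cys SG and His ring nitrogens are HAD;
each aromatic ring contributes one ARO point at its centroid (His rings
emit both ARO and the HAD nitrogens); each contiguous aliphatic side-chain
carbon group contributes one ALI point at its centroid, with Met SD counted
as a group member.  Missing side-chain atoms degrade gracefully: a group
pseudocenter is emitted from whatever members are present, logged.
Unknown residue names (modified residues, cofactors, metals) are skipped
with a warning — only protein points are matched.

## Numerical choices

* Canonical vertex order: side lengths are compared after quantizing at
  10⁻⁶ Å; surviving ties are broken by property rank HA<HD<HAD<ALI<ARO and
  then by lexicographically rounded coordinates, so ordering is stable
  under permutation of the input points.
* All greedy one-to-one resolutions sort by (distance, ref index, qry
  index), making them deterministic; tests compare the greedy extension
  against an optimal Hungarian assignment on small fixtures.
* Superposition is Kabsch via SVD with an explicit det-correction; it
  refuses fewer than three pairs or collinear clouds (second singular
  value below 10⁻⁸).
* Subsite counts (LR_p_num, LQ_p_num): the space the largest family
  encloses is defined as the union of balls of radius equal to the linkage
  cutoff around the family's matched points, evaluated per site in its own
  coordinates (the query via its own original frame).  This definition is
  chosen over a bounding-sphere variant because single linkage then
  guarantees that a self-match's subsite contains exactly its own members,
  making L_score(A,A) = 1 an exact identity rather than an approximation.
* The key pre-filter admits query models whose property triples are
  position-wise compatible and whose side bins differ by at most one; the
  `--no-prefilter` flag runs the exhaustive loop, and a test asserts both
  routes agree.

## The synthetic generator

`bsmm.synthetic` emulates PC-site geometry: by default 20 labeled points
drawn uniformly in a 15 Å box with a 2.0 Å minimum pairwise separation and
uniform labels — about the point count, pocket size and pseudocenter
spacing of a real ligand-binding site.  `make_pair` applies a uniformly
random proper rigid motion, optional per-coordinate Gaussian jitter, and
label-preserving partial overlap; decoy points stay at least 3.5 Å away
from every transformed true point so exact-recovery tests have clean ground
truth.  `make_complex` realizes a site as minimal PDB text (one single-atom
residue per point whose typing-table entry reproduces exactly that point,
plus a covering HET ligand placed rigid-covariantly), which exercises the
parsing, extraction and ligand-RMSD code paths end to end.

What the generator does **not** emulate: real backbone geometry and
side-chain packing, correlated point density, partial occupancy and
alternate conformations, conformational (non-rigid) change between two
complexes of a pair, and chemically realistic ligands.  Passing synthetic
tests therefore demonstrates algorithmic correctness — invariance,
recovery, scoring identities — not performance on crystal structures,
where the typing table and the site's conformational variability dominate.

Problem sizes used by the test suite and the acceptance script (15–25
points per site, 5–100 seeded replicates per property) keep a full run in
the tens of seconds while still exercising every code path; larger sites
change cost, not behavior.

## Known limitations

* Rigid matching only: no residue or ligand flexibility, no point weights.
* Scores depend on the typing table and the triangle-side bounds; absolute
  M_score values are comparable only across runs with the same
  configuration.
* Greedy one-to-one matching can, in adversarial geometries, pair one
  fewer point than an optimal assignment.
* Swapping reference and query can change the score slightly (greedy
  asymmetry); fixtures bound the discrepancy at 0.05.
* mmCIF input and multi-model averaging are unsupported; the first MODEL
  of a PDB file is used.
* Benchmarking against crystal-structure pairs requires the user to supply
  the PDB files (`data/pdb/`); the library never downloads structures.
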