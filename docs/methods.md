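# Methods

## Scope and coordinate system

The package analyzes a family of homodimeric enzyme structures against
one fixed multiple sequence alignment. All per-residue results are
indexed by **MSA numbers** — 1-based alignment columns — because family
members differ in length and only the alignment provides a shared
residue axis. The map between a sequence's ungapped positions and its
row's non-gap columns is an exact bijection (`map_position` /
`msa_to_seq_position`); a query at a gap column returns an explicit
absent value, never an interpolation.

## Structure model

PDB input is reduced to a heavy-atom model: protein residues keep only
N, C, O, S atoms; hydrogens, waters, ions and glycans are dropped;
glutathione-like hetero residues (GSH, GTX, GTS, GSF, …; configurable
list) are routed to a separate ligand list. For alternate locations the
first-listed conformer is kept — deterministic, and the common choice in
contact analyses. Residues are identified by (chain id, author residue
number, insertion code), which tolerates numbering gaps in crystal
structures. Predicted models carry pLDDT (0–100) in the temperature
factor column; confidence is read from the Cα record only, since
predictors write one value per residue, and residues lacking a Cα are
reported absent. Parsing and writing go through gemmi; the round trip
preserves coordinates to the PDB fixed-format precision (3 decimals).

## Alignment analytics

A column is *fully conserved* iff a single amino acid occupies every
row — a gap anywhere defeats it, so the criterion demands presence in
all sequences. Conservation frequencies are percentages of all rows
(gaps count against conservation), so the per-column amino-acid counts
plus the gap count always partition the row total.

Pairwise identity is 100 × (matching non-gap positions) / (columns where
at least one of the two rows is non-gap). This denominator penalizes
indels, which matters in families where lengths differ by tens of
residues; "shorter-sequence" and "full-alignment" denominators are
available as options since conventions differ between tools. Formal
charge is #(Lys, Arg) − #(Asp, Glu); histidine is neutral by default
and counted +1 behind a flag, because at physiological pH its
protonation is context-dependent and published totals may follow either
convention.

## Conformation comparison

Global deviation between two structures is the Cα RMSD over columns
non-gap in both rows, after optimal rigid superposition (Kabsch, SVD
with a determinant correction so the rotation is always proper).
Collinear point sets are rejected — the rotation about the common axis
is under-determined. Local deviation is the per-column Cα–Cα distance
in the superposed frame; for homodimers the two chains contribute two
values per column, which are averaged.

Coarse-grained angles are internal coordinates of the Cα trace: bond
angle θn at Cα n and torsion γn over Cα n−1…n+2, the discrete curvature
and torsion of the backbone. An N-residue chain has N−3 (θ, γ) pairs
(n = 2…N−2); θ alone also exists at n = N−1 and is computed there. The
dihedral sign follows the IUPAC convention, which must be fixed for χ1
comparisons to transfer across implementations. Angle deviations are
circular (wrapped to [0°, 180°]); the combined per-residue score is
max(|Δθ|, |Δγ|)/180 — conservative, unitless and bounded. The χ1
rotamer distance is d = (1 − cos Δχ1)/2: 0 for identical rotamers, 1
for the 180° (cis-vs-trans-like) flip, 0.5 at 90°. Residues without a
defined χ1 (Gly, Ala, missing side-chain atoms) are reported absent —
never as zero, which would fake agreement.

Secondary structure is assigned from the Cα trace alone: helix where
(θ, γ) falls in [80°, 105°] × [30°, 70°] over runs of ≥ 4 residues,
strand where θ ∈ [100°, 155°] and |γ| ∈ [140°, 180°] over runs of ≥ 3,
coil otherwise. The boxes are canonical Cα-trace geometry (an ideal
helix trace with 1.5 Å rise, 100°/residue, 2.3 Å radius gives θ ≈ 91°,
γ ≈ 50°; an extended trace γ = ±180°) and are configuration values, not
constants — they are deliberately labelled approximations of the
published Cα-only assignment algorithms.

## Contact sites

Two heavy atoms are in contact when their distance is strictly below
4.0 Å; two residues are in contact when any of their atom pairs is. The
neighbor search uses a k-d tree and is tested to agree exactly with the
all-pairs double loop. The dimerization interface of a two-chain model
is the set of residues with at least one inter-chain contact; interface
formal charge uses the same His convention flag as the alignment module.

Transplanted cofactor copies are clustered single-linkage with a 2.0 Å
threshold: the distance between two copies is the mean distance over
atoms shared by name, falling back to centroid distance. Single linkage
matches the notion of a threshold "between ligands in a given binding
site": any two resulting clusters are separated by more than the
threshold, and the cluster count is non-increasing in the threshold.
The binding site of a cluster is the union over its members of protein
residues within the 4.0 Å contact rule (the protein–ligand criterion
reuses the protein–protein one).

Buried interface area is (SASA(A) + SASA(B) − SASA(AB))/2 by
Shrake–Rupley sampling with a 1.4 Å probe, 960 points per atom on a
deterministic golden-spiral lattice, and Bondi radii (C 1.70, N 1.55,
O 1.52, S 1.80 Å). An isolated atom reproduces 4π(r + probe)² to the
lattice resolution (< 1%). This SASA-difference definition is the
package's own choice of interface-surface measure; force-field based
interface energies are out of scope.

## Communication pathways

The residue-interaction graph has one node per residue of both chains
plus one node for the bound cofactor; edges join contacting residues
(including inter-chain interface contacts — these are what let paths
cross between monomers) and the ligand to its contact residues. The
analysis is asymmetric by construction: the cofactor occupies the site
of monomer A (sources = its contact residues) while monomer B's site is
empty (targets = B's binding-site residues, identified from B's own
cluster before removal). Edges have unit weight, so path length is a
residue count; a distance-weighted mode (minimum heavy-atom distance as
edge cost) is available behind a flag. "All possible pathways" is
interpreted as **all minimum-length paths**: unrestricted simple-path
enumeration is combinatorial, and shortest paths are what the
per-residue visit statistics describe. Enumeration reduces the
set-to-set problem to single-pair Dijkstra via zero-cost virtual
endpoints and reads all shortest paths off the predecessor structure;
it is tested against exhaustive search capped at the shortest-path
distance. Unreachable targets yield an explicitly empty result.

## Parameter-free ANM

Nodes are all heavy atoms; every node pair is a spring with
Γij = γ/Rij². The absence of a cutoff is what makes the model
parameter-free — distance dependence replaces the usual cutoff radius.
(A cutoff option exists for speed experiments only and is off by
default.) The mass-weighted Hessian is assembled exactly as defined
(off-diagonal 3×3 blocks −(R⊗R/R²)Γ, diagonal blocks minus the row sum,
element-wise division by √(mi mj)) and diagonalized densely
(`scipy.linalg.eigh`); supported scale is ≈3,500 atoms (10,500²
matrix). Eigenvalues below 10⁻⁸ × the largest are rigid-body modes:
exactly 6 for a non-collinear network, 5 for a collinear one (the
diatomic is the documented degenerate case, with closed-form internal
eigenvalue Γ(1/m1 + 1/m2)); more than 6 indicates a disconnected or
degenerate network and is an error. A geometric caveat discovered in
fixture design: exactly planar networks are degenerate too, because
1/R² springs give zero out-of-plane stiffness — fixtures must be
genuinely three-dimensional.

B-factors use kB = 1 internal units and T = 300 K by default; with
γ = 1 the absolute Å² scale is arbitrary, which is acceptable because
the quantity of interest — the Pearson correlation with an experimental
profile — is scale-invariant. Least-squares rescaling onto an
experimental profile (equivalent to calibrating γ) is provided for
plotting on an absolute scale. Per-residue aggregation is the mean over
the residue's heavy atoms, with a Cα-only mode behind a flag, since
experimental comparisons are made per residue and either pairing
convention appears in practice. The implementation is cross-checked
against an independent pseudo-inverse oracle
(Bi ∝ (1/mi)·tr[Ĥ⁺]ii-block).

## Pipeline aggregation

Per structure, the pipeline reports the secondary-structure string,
radius of gyration, interface, binding sites, pathways and B-factor
profile; homodimer per-residue values are averaged over the two
monomers before MSA mapping (one profile per family member; a flag
keeps chains separate). Family aggregation counts, per MSA number, the
structures whose interface / binding site / pathways include that
column (occupancy), and the mean and population SD of B-factors across
structures. Aggregation is a sum over structures, hence
permutation-invariant and exactly decremented when a structure is
removed. Reports are TSV plus a JSON manifest carrying a config hash;
reruns with the same inputs are byte-identical. Failures in one
structure are collected in the manifest's error section and do not
abort the batch.

## Synthetic fixtures: what they do and do not show

Generators are pure functions of their arguments and a seed. The toy
dimer places two straight Cα chains (3.8 Å spacing) in exact two-fold
symmetry, out of contact range, with CB stubs on the first
`interface_size` residues reaching toward the partner — so interface
membership is exactly the planned set while each chain stays internally
connected for the pathway corridor; a small deterministic z-undulation
keeps the network non-planar for the ANM without moving any pair
distance across the 4.0 Å threshold. Ligand pockets are nine copies
jittered < 0.35 Å around a point 3 Å outside each chain's last residue,
forming one single-linkage cluster per pocket at 2.0 Å, mirroring the
two-sites-of-nine layout that cofactor-transplant pipelines produce.
The synthetic alignment plants invariant columns, gap blocks and
per-row charges on a charge-neutral background alphabet, so every
statistic has a known answer.

These fixtures validate the *machinery* — thresholds, clustering
semantics, path enumeration, eigenproblem, aggregation — exactly. They
do not emulate real protein energetics, side-chain rotamer libraries,
packing density or realistic interface topology; passing tests
therefore demonstrate correctness of the computations, not biological
accuracy of any particular threshold on real structures. Problem sizes
in the test suite and acceptance script (chains of 8–20 residues,
networks of ≤ 50 nodes, families of 3–4 structures) are chosen so the
full suite runs in seconds while still exercising every code path;
results on these fixtures are exact or closed-form, so size does not
limit their evidential value.

## Known limitations

- Secondary-structure boxes are approximations; no hydrogen-bond (DSSP)
  assignment.
- Interface "surface" is a SASA difference, not an MD- or force-field
  based measure; interface energies are not computed.
- The ANM is harmonic: experimental loop fluctuations with anharmonic
  character are not reproducible by construction.
- Multi-assembly crystal files are reduced to a dimer only by explicit
  chain-pair selection; no symmetry-mate reconstruction.
- Absolute B-factor scale requires calibration against an experimental
  profile; only correlations are parameter-free.
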