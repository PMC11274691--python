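# gstome

Structural analytics for multigene enzyme families, built around the
homodimeric glutathione transferases (GSTs). The package answers a family
of questions that come up whenever a set of related protein structures —
crystal structures or AlphaFold-multimer models — must be compared residue
by residue: which positions are conserved, which form the dimerization
interface, which bind the cofactor, how the two binding sites communicate
across the dimer, and how flexible each position is.

The unifying coordinate system is the **MSA number**: the 1-based column
index of one fixed multiple sequence alignment of the family. Every
per-residue quantity — interface membership, binding-site membership,
pathway visits, B-factors — is mapped onto MSA numbers, so structures of
different lengths aggregate onto a common axis.

## What it computes

**Alignment analytics** (`gstome.msa`): per-column amino-acid frequencies
and fully conserved columns, gap profiles, pairwise sequence identity
(100 × matches / columns where at least one row has a residue; other
denominators available), formal charge (#Lys + #Arg − #Asp − #Glu, His
optionally +1), and the bijection between ungapped sequence positions and
alignment columns.

**Conformation comparison** (`gstome.geometry`): Kabsch superposition and
Cα RMSD over doubly non-gap columns, per-column local Cα deviation,
coarse-grained angles of the Cα trace — the virtual bond angle θn
(Cα n−1, n, n+1) and torsion γn (Cα n−1 … n+2), giving N−3 (θ, γ) pairs
for an N-residue chain — χ1 rotamer distance d = (1 − cos Δχ1)/2, the
mass-weighted radius of gyration, and a Cα-only secondary-structure
assignment from configurable (θ, γ) boxes.

**Contact sites** (`gstome.sites`): residue contact maps at a strict
4.0 Å heavy-atom threshold, dimerization-interface (DI) residues of a
dimer, single-linkage clustering of transplanted cofactor copies at a
2.0 Å ligand–ligand threshold, binding-site (GS) residues contacting a
cluster, and buried interface area as half the Shrake–Rupley solvent
accessibility lost upon dimer formation.

**Communication pathways** (`gstome.pathways`): the residue-interaction
graph (contacts within and between chains plus a ligand node on the holo
side), and the enumeration of *all* minimum-length paths from the
ligand-bound site of monomer A to the empty site of monomer B, with
per-residue visit statistics.

**Thermal B-factors** (`gstome.anm`): the parameter-free anisotropic
network model on heavy atoms. Every pair of atoms i, j is a spring of
stiffness Γij = γ/Rij² (no cutoff); the mass-weighted Hessian

    Ĥij^{αβ} = Hij^{αβ}/√(mi·mj),  Hij^{αβ} = −(Rij^α Rij^β / Rij²)·Γij,
    Hii = −Σ_{j≠i} Hij

is diagonalized (Ĥ e_k = ω̃k² e_k, 3N−6 internal modes) and per-atom
B-factors follow as

    Bi = (8π²/3)·(kB T / mi)·Σ_k |e_ki|² / ω̃k².

With the default γ = 1 the scale of B is arbitrary; Pearson correlations
against experimental profiles are scale-invariant, and a least-squares
rescaling is provided.

**Pipeline** (`gstome.pipeline`, CLI `gstome`): runs a directory of PDB
files against one alignment and emits the per-MSA-number family profile
(N_DI, N_GS, N_path occupancy, mean/SD B-factor, residue occurrence),
pairwise RMSD and identity matrices, and per-structure correlations with
the family-mean flexibility profile.

**Synthetic fixtures** (`gstome.synthetic`): seeded generators for ideal
helices/strands/coils, two-fold-symmetric toy dimers with planned
interfaces, pockets and pathway corridors, alignments with planted
conservation/gap/charge structure, and a flexible dumbbell — each with a
ledger of its planted ground truth.

## Worked example

```python
import gstome

model, ledger = gstome.make_toy_dimer(
    n_per_chain=12, interface_size=4, ligand_copies_per_pocket=9, seed=11
)
iface = gstome.interface_residues(model)
clusters = gstome.cluster_ligands(model.ligands)
print(iface.n_di, clusters.n_clusters, [c.n_members for c in clusters.clusters])
```

prints `4 2 [9, 9]`: the four planted interface residues per monomer are
recovered at the 4.0 Å contact criterion, and the 18 jittered ligand
copies collapse into exactly two clusters of nine — one binding site per
monomer — at the 2.0 Å single-linkage threshold.

Running `python examples/communication_pathways.py`:

```
minimal pathways found: 1
pathway length: 18 residues (designed corridor: 18)
  A12 -> A11 -> A10 -> A9 -> A8 -> A7 -> A6 -> A5 -> A4 -> B4 -> B5 -> ... -> B12
```

The single shortest pathway descends chain A from the ligand-bound
pocket, crosses the interface at the contact nearest the pocket, and
climbs chain B to the empty site — 18 residues, exactly the designed
corridor length. `examples/` holds one such narrative script per
capability (conservation, sites, pathways, B-factors, full family run).

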