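"""Contact-based site analysis: residue contact maps, the dimerization
interface (DI), glutathione binding sites (GS), ligand-copy clustering and
buried interface surface area.

Two heavy atoms are "in contact" below a 4.0 Å distance threshold, and two
residues are in contact if any of their atom pairs is.  The DI of a
homodimer is the set of residues of one monomer with at least one atomic
contact to the other monomer; the GS is the set of residues in contact
with any copy of the clustered cofactor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial import cKDTree
from scipy.spatial.distance import squareform

from .chem import DEFAULT_VDW_RADIUS, NEGATIVE_AA, POSITIVE_AA, VDW_RADII
from .structure import Residue, StructureModel

CONTACT_THRESHOLD = 4.0  # Å, heavy-atom contact criterion
LIGAND_CLUSTER_THRESHOLD = 2.0  # Å, single-linkage threshold between ligand copies


class SiteError(ValueError):
    pass


def flatten_residues(model: StructureModel) -> list[Residue]:
    """Protein residues of all chains, in file order (global indexing)."""
    return list(model.iter_residues())


# ---------------------------------------------------------------------------
# residue contact map


@dataclass
class ResidueContactMap:
    """Symmetric residue–residue contact map at a heavy-atom threshold.

    ``contacts`` maps ordered index pairs (i < j, indices into
    ``residues``) to the number of atom pairs below the threshold."""

    residues: list[Residue]
    threshold: float
    contacts: dict[tuple[int, int], int] = field(default_factory=dict)

    def in_contact(self, i: int, j: int) -> bool:
        if i == j:
            return False
        key = (i, j) if i < j else (j, i)
        return key in self.contacts

    def neighbors(self, i: int) -> list[int]:
        out = []
        for a, b in self.contacts:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return sorted(out)

    def as_matrix(self) -> np.ndarray:
        n = len(self.residues)
        M = np.zeros((n, n), dtype=bool)
        for (i, j) in self.contacts:
            M[i, j] = M[j, i] = True
        return M


def residue_contact_map(
    model: StructureModel, threshold: float = CONTACT_THRESHOLD
) -> ResidueContactMap:
    """Contact map over all protein residues of the model.

    Uses a k-d tree for the atom neighbor search; the result is identical
    to the all-pairs double loop (strict ``< threshold``)."""
    residues = flatten_residues(model)
    coords = []
    owner = []
    for idx, res in enumerate(residues):
        for atom in res.atoms:
            coords.append(atom.coord)
            owner.append(idx)
    coords = np.asarray(coords)
    owner = np.asarray(owner)
    cmap = ResidueContactMap(residues=residues, threshold=threshold)
    if len(coords) == 0:
        return cmap
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=threshold, output_type="ndarray")
    if len(pairs) == 0:
        return cmap
    d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
    pairs = pairs[d < threshold]
    for a, b in pairs:
        i, j = owner[a], owner[b]
        if i == j:
            continue
        key = (i, j) if i < j else (j, i)
        cmap.contacts[key] = cmap.contacts.get(key, 0) + 1
    return cmap


# ---------------------------------------------------------------------------
# dimerization interface


def _residue_set_charge(residues: list[Residue], his_positive: bool = False) -> int:
    charge = 0
    for res in residues:
        aa = res.one_letter
        if aa in POSITIVE_AA or (his_positive and aa == "H"):
            charge += 1
        elif aa in NEGATIVE_AA:
            charge -= 1
    return charge


@dataclass
class InterfaceResult:
    """DI residues per monomer, their count, formal charge, and (when an
    alignment row is supplied) the MSA numbers they occupy."""

    residues_a: list[Residue]
    residues_b: list[Residue]
    charge_a: int
    charge_b: int
    threshold: float
    msa_numbers: set[int] = field(default_factory=set)
    buried_area: float | None = None

    @property
    def n_di(self) -> int:
        """Interface size per monomer (mean of the two chains)."""
        return round((len(self.residues_a) + len(self.residues_b)) / 2)


def interface_residues(
    dimer: StructureModel,
    threshold: float = CONTACT_THRESHOLD,
    aln=None,
    row_id: str | None = None,
    his_positive: bool = False,
) -> InterfaceResult:
    """Residues of each chain with ≥1 heavy-atom contact to the partner
    chain.  Requires exactly two protein chains."""
    if len(dimer.chains) != 2:
        raise SiteError(f"dimer expected (2 chains), got {len(dimer.chains)}")
    ch_a, ch_b = dimer.chains
    coords_b, owner_b = [], []
    for idx, res in enumerate(ch_b.residues):
        for atom in res.atoms:
            coords_b.append(atom.coord)
            owner_b.append(idx)
    tree = cKDTree(np.asarray(coords_b))
    set_a: set[int] = set()
    set_b: set[int] = set()
    for ia, res in enumerate(ch_a.residues):
        for atom in res.atoms:
            hits = tree.query_ball_point(atom.coord, r=threshold)
            close = [
                h for h in hits
                if np.linalg.norm(atom.coord - coords_b[h]) < threshold
            ]
            if close:
                set_a.add(ia)
                set_b.update(owner_b[h] for h in close)
    res_a = [ch_a.residues[i] for i in sorted(set_a)]
    res_b = [ch_b.residues[i] for i in sorted(set_b)]
    result = InterfaceResult(
        residues_a=res_a,
        residues_b=res_b,
        charge_a=_residue_set_charge(res_a, his_positive),
        charge_b=_residue_set_charge(res_b, his_positive),
        threshold=threshold,
    )
    if aln is not None and row_id is not None:
        result.msa_numbers = residues_to_msa_numbers(dimer, res_a + res_b, aln, row_id)
    return result


def residues_to_msa_numbers(
    model: StructureModel, residues: list[Residue], aln, row_id: str
) -> set[int]:
    """Map residues (by chain position) onto alignment columns of the
    structure's sequence row."""
    from .msa import map_position

    numbers: set[int] = set()
    pos_by_key = {}
    for chain in model.chains:
        for i, res in enumerate(chain.residues, start=1):
            pos_by_key[res.key] = i
    for res in residues:
        seq_pos = pos_by_key.get(res.key)
        if seq_pos is None:
            continue
        numbers.add(map_position(aln, row_id, seq_pos))
    return numbers


# ---------------------------------------------------------------------------
# ligand clustering


@dataclass
class LigandCluster:
    members: list[Residue]
    centroid: np.ndarray

    @property
    def n_members(self) -> int:
        return len(self.members)


@dataclass
class LigandClusterSet:
    clusters: list[LigandCluster]
    threshold: float

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


def ligand_distance(lig_a: Residue, lig_b: Residue) -> float:
    """Distance between two ligand copies: mean distance over atoms shared
    by name, falling back to the centroid distance when no names match."""
    names_a = {a.name: a.coord for a in lig_a.atoms}
    names_b = {a.name: a.coord for a in lig_b.atoms}
    shared = sorted(set(names_a) & set(names_b))
    if shared:
        return float(
            np.mean([np.linalg.norm(names_a[nm] - names_b[nm]) for nm in shared])
        )
    return float(np.linalg.norm(lig_a.coords().mean(axis=0) - lig_b.coords().mean(axis=0)))


def cluster_ligands(
    copies: list[Residue], threshold: float = LIGAND_CLUSTER_THRESHOLD
) -> LigandClusterSet:
    """Single-linkage clustering of ligand copies: two clusters are always
    separated by more than the threshold under the ligand metric."""
    if not copies:
        raise SiteError("no ligand copies to cluster")
    if len(copies) == 1:
        return LigandClusterSet(
            clusters=[LigandCluster([copies[0]], copies[0].coords().mean(axis=0))],
            threshold=threshold,
        )
    n = len(copies)
    dmat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dmat[i, j] = dmat[j, i] = ligand_distance(copies[i], copies[j])
    Z = linkage(squareform(dmat, checks=False), method="single")
    labels = fcluster(Z, t=threshold, criterion="distance")
    clusters = []
    for lab in sorted(set(labels)):
        members = [copies[i] for i in range(n) if labels[i] == lab]
        coords = np.vstack([m.coords() for m in members])
        clusters.append(LigandCluster(members=members, centroid=coords.mean(axis=0)))
    clusters.sort(key=lambda c: tuple(c.centroid))
    return LigandClusterSet(clusters=clusters, threshold=threshold)


# ---------------------------------------------------------------------------
# binding sites


@dataclass
class BindingSiteResult:
    residues: list[Residue]
    charge: int
    threshold: float
    msa_numbers: set[int] = field(default_factory=set)

    @property
    def n_gs(self) -> int:
        return len(self.residues)


def binding_site_residues(
    model: StructureModel,
    cluster: LigandCluster,
    threshold: float = CONTACT_THRESHOLD,
    aln=None,
    row_id: str | None = None,
    his_positive: bool = False,
) -> BindingSiteResult:
    """Union over cluster members of protein residues with any heavy atom
    within the contact threshold of a ligand atom."""
    if not cluster.members:
        raise SiteError("empty ligand cluster")
    residues = flatten_residues(model)
    lig_coords = np.vstack([m.coords() for m in cluster.members])
    tree = cKDTree(lig_coords)
    hits: set[int] = set()
    for idx, res in enumerate(residues):
        for atom in res.atoms:
            near = tree.query_ball_point(atom.coord, r=threshold)
            if any(np.linalg.norm(atom.coord - lig_coords[h]) < threshold for h in near):
                hits.add(idx)
                break
    site = [residues[i] for i in sorted(hits)]
    if not site:
        warnings.warn("ligand cluster contacts no protein residues", stacklevel=2)
    result = BindingSiteResult(
        residues=site,
        charge=_residue_set_charge(site, his_positive),
        threshold=threshold,
    )
    if aln is not None and row_id is not None:
        result.msa_numbers = residues_to_msa_numbers(model, site, aln, row_id)
    return result


# ---------------------------------------------------------------------------
# solvent accessibility


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral lattice of n points on the unit sphere."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0**0.5) * k
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


def shrake_rupley_sasa(
    coords: np.ndarray,
    elements: list[str],
    probe: float = 1.4,
    n_points: int = 960,
    radii: dict[str, float] | None = None,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Å²) by the Shrake–Rupley
    point-sampling method with a deterministic spiral lattice."""
    radii = radii or VDW_RADII
    coords = np.asarray(coords, float)
    r = np.array([radii.get(e.upper(), DEFAULT_VDW_RADIUS) for e in elements])
    R = r + probe
    unit = _sphere_points(n_points)
    tree = cKDTree(coords)
    max_R = R.max()
    areas = np.zeros(len(coords))
    for i in range(len(coords)):
        pts = coords[i] + R[i] * unit
        neigh = [j for j in tree.query_ball_point(coords[i], r=R[i] + max_R) if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neigh:
            d = np.linalg.norm(pts - coords[j], axis=1)
            accessible &= d >= R[j]
        areas[i] = 4.0 * np.pi * R[i] ** 2 * accessible.mean()
    return areas


def _chain_atoms(model: StructureModel, chain_idx: int) -> tuple[np.ndarray, list[str]]:
    chain = model.chains[chain_idx]
    coords, elems = [], []
    for res in chain.residues:
        for atom in res.atoms:
            coords.append(atom.coord)
            elems.append(atom.element)
    return np.asarray(coords), elems


def buried_interface_area(
    dimer: StructureModel, probe: float = 1.4, n_points: int = 960
) -> float:
    """Buried interface area (SASA(A) + SASA(B) − SASA(AB)) / 2, Å²."""
    if len(dimer.chains) != 2:
        raise SiteError("dimer expected (2 chains)")
    ca, ea = _chain_atoms(dimer, 0)
    cb, eb = _chain_atoms(dimer, 1)
    sa = shrake_rupley_sasa(ca, ea, probe, n_points).sum()
    sb = shrake_rupley_sasa(cb, eb, probe, n_points).sum()
    sab = shrake_rupley_sasa(
        np.vstack([ca, cb]), ea + eb, probe, n_points
    ).sum()
    return float((sa + sb - sab) / 2.0)
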