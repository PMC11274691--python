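"""Contact maps, interface and binding-site identification, ligand
clustering and solvent-accessible surface area."""

import numpy as np
import pytest

from gstome import (
    binding_site_residues,
    buried_interface_area,
    cluster_ligands,
    interface_residues,
    make_toy_dimer,
    residue_contact_map,
)
from gstome.chem import atomic_mass
from gstome.sites import SiteError, ligand_distance, shrake_rupley_sasa
from gstome.structure import Atom, Chain, Residue, StructureModel

from conftest import random_rotation


def single_atom_residue(xyz, seqid, chain_id="A", element="C", name="CA"):
    return Residue(
        name="GLY", seqid=seqid, chain_id=chain_id,
        atoms=[Atom(name, element, np.asarray(xyz, float), atomic_mass(element))],
    )


def point_model(points, chain_id="A"):
    chain = Chain(id=chain_id)
    for i, p in enumerate(points):
        chain.residues.append(single_atom_residue(p, i + 1, chain_id))
    return StructureModel(chains=[chain])


def ligand_at(center, seqid=900, jitter=None):
    center = np.asarray(center, float)
    if jitter is not None:
        center = center + jitter
    lig = Residue(name="GSH", seqid=seqid, chain_id="A")
    for nm, el, off in (("S1", "S", [0.2, 0, 0]), ("C2", "C", [-0.2, 0, 0])):
        lig.atoms.append(Atom(nm, el, center + off, atomic_mass(el), is_hetero=True))
    return lig


class TestContactMap:
    @pytest.mark.parametrize("d,expected", [(3.9, True), (4.1, False), (4.0, False)])
    def test_threshold_is_strict(self, d, expected):
        model = point_model([[0, 0, 0], [d, 0, 0]])
        cmap = residue_contact_map(model)
        assert cmap.in_contact(0, 1) is expected

    def test_matches_brute_force_all_pairs(self):
        rng = np.random.default_rng(17)
        pts = rng.uniform(0, 25, size=(50, 3))
        model = point_model(pts)
        cmap = residue_contact_map(model)
        brute = set()
        for i in range(50):
            for j in range(i + 1, 50):
                if np.linalg.norm(pts[i] - pts[j]) < 4.0:
                    brute.add((i, j))
        assert set(cmap.contacts) == brute
        M = cmap.as_matrix()
        assert (M == M.T).all() and not M.diagonal().any()


class TestInterface:
    def test_planted_interface_recovered_exactly(self, toy_dimer):
        model, ledger = toy_dimer
        iface = interface_residues(model)
        expected = ledger["interface_residues"]
        assert [r.seqid for r in iface.residues_a] == expected
        assert [r.seqid for r in iface.residues_b] == expected
        assert iface.n_di == ledger["interface_size"]

    def test_separated_chains_have_empty_interface(self):
        a = point_model([[0, 0, 0], [3.8, 0, 0], [7.6, 0, 0]], "A").chains[0]
        b = point_model([[0, 50, 0], [3.8, 50, 0], [7.6, 50, 0]], "B").chains[0]
        iface = interface_residues(StructureModel(chains=[a, b]))
        assert iface.residues_a == [] and iface.residues_b == []

    def test_single_chain_rejected(self):
        with pytest.raises(SiteError):
            interface_residues(point_model([[0, 0, 0], [3, 0, 0]]))

    def test_invariant_under_rigid_motion(self, toy_dimer_raw):
        model, _ = toy_dimer_raw
        before = interface_residues(model)
        rng = np.random.default_rng(21)
        R, t = random_rotation(rng), rng.normal(scale=30, size=3)
        import copy

        moved = copy.deepcopy(model)
        for res in list(moved.iter_residues()) + moved.ligands:
            for atom in res.atoms:
                atom.coord = R @ atom.coord + t
        after = interface_residues(moved)
        assert [r.key for r in after.residues_a] == [r.key for r in before.residues_a]
        assert [r.key for r in after.residues_b] == [r.key for r in before.residues_b]


class TestBindingSite:
    def test_ligand_next_to_planned_residues(self):
        model = point_model([[0, 0, 0], [3.8, 0, 0], [7.6, 0, 0], [11.4, 0, 0], [30, 0, 0]])
        lig = ligand_at([5.7, 3.0, 0.0])
        clusters = cluster_ligands([lig])
        site = binding_site_residues(model, clusters.clusters[0])
        assert [r.seqid for r in site.residues] == [2, 3]

    def test_far_ligand_warns_and_is_empty(self):
        model = point_model([[0, 0, 0], [3.8, 0, 0], [7.6, 0, 0]])
        clusters = cluster_ligands([ligand_at([0, 100, 0])])
        with pytest.warns(UserWarning):
            site = binding_site_residues(model, clusters.clusters[0])
        assert site.n_gs == 0

    def test_union_over_cluster_members(self):
        model = point_model([[0, 0, 0], [3.8, 0, 0], [7.6, 0, 0], [11.4, 0, 0]])
        lig1 = ligand_at([1.0, 3.0, 0], seqid=900)
        lig2 = ligand_at([2.5, 3.0, 0], seqid=901)
        clusters = cluster_ligands([lig1, lig2])
        assert clusters.n_clusters == 1
        site = binding_site_residues(model, clusters.clusters[0])
        expected = set()
        for lig in (lig1, lig2):
            for res_idx, res in enumerate(model.chains[0].residues):
                dmin = min(
                    np.linalg.norm(a.coord - la.coord)
                    for a in res.atoms for la in lig.atoms
                )
                if dmin < 4.0:
                    expected.add(res.seqid)
        assert {r.seqid for r in site.residues} == expected

    def test_empty_cluster_rejected(self):
        from gstome.sites import LigandCluster

        with pytest.raises(SiteError):
            binding_site_residues(
                point_model([[0, 0, 0]]), LigandCluster([], np.zeros(3))
            )


class TestLigandClustering:
    def test_two_pockets_of_nine(self, toy_dimer):
        model, ledger = toy_dimer
        clusters = cluster_ligands(model.ligands)
        assert clusters.n_clusters == ledger["n_pockets"]
        assert [c.n_members for c in clusters.clusters] == [9, 9]

    def test_single_copy_singleton(self):
        clusters = cluster_ligands([ligand_at([0, 0, 0])])
        assert clusters.n_clusters == 1 and clusters.clusters[0].n_members == 1

    def test_chain_linkage_semantics(self):
        copies = [ligand_at([1.9 * k, 0, 0], seqid=900 + k) for k in range(6)]
        assert cluster_ligands(copies).n_clusters == 1
        spread = [ligand_at([2.5 * k, 0, 0], seqid=900 + k) for k in range(6)]
        assert cluster_ligands(spread).n_clusters == 6

    def test_cluster_count_monotone_in_threshold(self, toy_dimer):
        model, _ = toy_dimer
        counts = [
            cluster_ligands(model.ligands, threshold=t).n_clusters
            for t in (0.05, 0.5, 2.0, 10.0, 100.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_metric_uses_shared_atom_names(self):
        a = ligand_at([0, 0, 0])
        b = ligand_at([1.0, 0, 0])
        assert ligand_distance(a, b) == pytest.approx(1.0)
        # no shared names: centroid distance
        c = Residue("GSH", 902, "A", atoms=[Atom("XX", "C", np.array([5.0, 0, 0]), 12.0)])
        assert ligand_distance(a, c) == pytest.approx(5.0)


class TestSasa:
    def test_isolated_carbon_full_sphere(self):
        areas = shrake_rupley_sasa(np.zeros((1, 3)), ["C"])
        assert areas[0] == pytest.approx(4 * np.pi * 3.10**2, rel=0.01)

    def test_nearly_coincident_spheres_half_occluded(self):
        areas = shrake_rupley_sasa(np.array([[0.0, 0, 0], [0.01, 0, 0]]), ["C", "C"])
        full = 4 * np.pi * 3.10**2
        assert areas.sum() == pytest.approx(full, rel=0.02)
        assert areas[0] == pytest.approx(full / 2, rel=0.03)

    def test_buried_area_zero_when_separated_and_symmetric(self):
        a = point_model([[0, 0, 0], [3.8, 0, 0], [7.6, 0, 0]], "A").chains[0]
        b = point_model([[0, 50, 0], [3.8, 50, 0], [7.6, 50, 0]], "B").chains[0]
        apart = StructureModel(chains=[a, b])
        assert buried_interface_area(apart) == pytest.approx(0.0, abs=1e-9)
        close_b = point_model([[0, 4.5, 0], [3.8, 4.5, 0], [7.6, 4.5, 0]], "B").chains[0]
        dimer = StructureModel(chains=[a, close_b])
        area_ab = buried_interface_area(dimer)
        flipped = StructureModel(chains=[close_b, a])
        assert area_ab > 0
        assert buried_interface_area(flipped) == pytest.approx(area_ab)
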