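"""Superposition, coarse-grained angles, χ1, Rg and secondary structure."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from gstome import (
    assign_secondary_structure,
    cga_deviation,
    chi1_angle,
    chi1_distance_value,
    coarse_grained_angles,
    kabsch_superpose,
    local_ca_deviation,
    make_ideal_chain,
    radius_of_gyration,
    rmsd_common_calpha,
)
from gstome.chem import atomic_mass
from gstome.geometry import GeometryError, matched_calpha
from gstome.msa import AlignedSequenceSet
from gstome.structure import Atom, Chain, Residue, StructureModel

from conftest import random_rotation


def ca_model(coords, name="m") -> StructureModel:
    chain = Chain(id="A")
    for i, xyz in enumerate(coords):
        chain.residues.append(
            Residue(name="GLY", seqid=i + 1, chain_id="A",
                    atoms=[Atom("CA", "C", np.asarray(xyz, float), atomic_mass("C"))])
        )
    return StructureModel(chains=[chain], name=name)


class TestKabsch:
    def test_identity_gives_zero_rmsd(self):
        P = np.random.default_rng(0).normal(size=(8, 3))
        res = kabsch_superpose(P, P)
        assert res.rmsd == pytest.approx(0.0, abs=1e-10)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(1)
        P = rng.normal(size=(10, 3))
        R = random_rotation(rng)
        Q = P @ R.T + np.array([5.0, -2.0, 7.0])
        assert kabsch_superpose(P, Q).rmsd == pytest.approx(0.0, abs=1e-8)

    def test_agrees_with_scipy_align_vectors(self):
        # independent oracle: scipy's own least-squares rotation solver
        rng = np.random.default_rng(2)
        P = rng.normal(size=(4, 3))
        Q = P.copy()
        Q[2] += [1.0, 0.0, 0.0]
        res = kabsch_superpose(P, Q)
        rot, rssd = Rotation.align_vectors(Q - Q.mean(0), P - P.mean(0))
        assert res.rmsd == pytest.approx(rssd / np.sqrt(len(P)), abs=1e-9)

    def test_beats_random_rigid_transforms(self):
        rng = np.random.default_rng(3)
        P = rng.normal(size=(12, 3))
        Q = rng.normal(size=(12, 3))
        best = kabsch_superpose(P, Q).rmsd
        for _ in range(50):
            R = random_rotation(rng)
            t = rng.normal(size=3)
            trial = np.sqrt((((P @ R.T + t) - Q) ** 2).sum() / len(P))
            assert best <= trial + 1e-9

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(GeometryError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.outer(np.arange(5.0), [1.0, 0, 0])
        with pytest.raises(GeometryError, match="collinear"):
            kabsch_superpose(line, line)


class TestCoarseGrainedAngles:
    def test_collinear_theta_180(self):
        pts = np.outer(np.arange(5.0), [3.8, 0, 0])
        cga = coarse_grained_angles(pts)
        np.testing.assert_allclose(cga.theta, 180.0)

    def test_trans_zigzag_gamma_180(self):
        model, _ = make_ideal_chain("strand", 8)
        cga = coarse_grained_angles(model.chains[0].calpha_coords())
        np.testing.assert_allclose(np.abs(cga.gamma), 180.0, atol=1e-8)

    def test_ideal_helix_angles_match_vector_oracle(self):
        model, _ = make_ideal_chain("helix", 12)
        X = model.chains[0].calpha_coords()
        cga = coarse_grained_angles(X)
        # independent oracle: cosine law for theta, atan2-free torsion sign
        for k in range(1, len(X) - 1):
            u, v = X[k - 1] - X[k], X[k + 1] - X[k]
            th = np.degrees(np.arccos(u @ v / np.linalg.norm(u) / np.linalg.norm(v)))
            assert cga.theta[k - 1] == pytest.approx(th, abs=1e-9)
        assert cga.theta.mean() == pytest.approx(91.0, abs=1.0)
        assert cga.gamma.mean() == pytest.approx(50.0, abs=1.0)

    def test_pair_count_is_n_minus_3(self):
        for n in (5, 9, 17):
            model, _ = make_ideal_chain("helix", n)
            cga = coarse_grained_angles(model.chains[0].calpha_coords())
            assert cga.n_pairs == n - 3
            assert cga.pairs().shape == (n - 3, 2)

    def test_invariance_under_rigid_motion(self):
        rng = np.random.default_rng(7)
        model, _ = make_ideal_chain("coil", 10, seed=4)
        X = model.chains[0].calpha_coords()
        R, t = random_rotation(rng), rng.normal(size=3)
        a, b = coarse_grained_angles(X), coarse_grained_angles(X @ R.T + t)
        np.testing.assert_allclose(a.theta, b.theta, atol=1e-8)
        np.testing.assert_allclose(a.gamma, b.gamma, atol=1e-8)

    def test_coincident_points_rejected(self):
        pts = np.array([[0.0, 0, 0], [0.0, 0, 0], [1, 0, 0], [2, 0, 0]])
        with pytest.raises(GeometryError):
            coarse_grained_angles(pts)


class TestCgaDeviation:
    def test_identical_traces_zero(self):
        model, _ = make_ideal_chain("helix", 10)
        cga = coarse_grained_angles(model.chains[0].calpha_coords())
        dev = cga_deviation(cga, cga)
        np.testing.assert_allclose(dev["combined"], 0.0)

    def test_wraparound_and_planted_flip(self):
        model, _ = make_ideal_chain("helix", 10)
        cga_a = coarse_grained_angles(model.chains[0].calpha_coords())
        import copy

        cga_b = copy.deepcopy(cga_a)
        cga_b.gamma = cga_b.gamma + 360.0  # full turn: no physical change
        np.testing.assert_allclose(
            cga_deviation(cga_a, cga_b)["combined"], 0.0, atol=1e-9
        )
        cga_b = copy.deepcopy(cga_a)
        cga_b.gamma[3] += 30.0
        dev = cga_deviation(cga_a, cga_b)
        assert dev["combined"].iloc[3] == pytest.approx(30.0 / 180.0)
        assert (dev["combined"].drop(dev.index[3]) == 0).all()


class TestChi1:
    @pytest.mark.parametrize("delta,expected", [(0.0, 0.0), (90.0, 0.5), (180.0, 1.0)])
    def test_distance_endpoints(self, delta, expected):
        assert chi1_distance_value(10.0, 10.0 - delta) == pytest.approx(expected)

    def test_angle_from_constructed_sidechain(self):
        def ser(chi_deg):
            chi = np.radians(chi_deg)
            atoms = [
                Atom("N", "N", np.array([1.0, 1.0, 0.0]), atomic_mass("N")),
                Atom("CA", "C", np.array([0.0, 0.0, 0.0]), atomic_mass("C")),
                Atom("CB", "C", np.array([0.0, 0.0, 1.5]), atomic_mass("C")),
                Atom("OG", "O", np.array([np.cos(chi), np.sin(chi), 1.5]) * [1, 1, 1]
                     + np.array([0, 0, 0.8]), atomic_mass("O")),
            ]
            return Residue("SER", 1, "A", atoms=atoms)

        a = chi1_angle(ser(30.0))
        b = chi1_angle(ser(75.0))
        assert abs(abs(a - b) - 45.0) < 1e-6

    def test_undefined_for_gly_and_missing_atoms(self):
        gly = Residue("GLY", 1, "A", atoms=[Atom("CA", "C", np.zeros(3), 12.0)])
        assert chi1_angle(gly) is None
        partial = Residue("SER", 1, "A", atoms=[
            Atom("N", "N", np.array([1.0, 0, 0]), 14.0),
            Atom("CA", "C", np.zeros(3) + [0, 1, 0], 12.0),
        ])
        assert chi1_angle(partial) is None


class TestRadiusOfGyration:
    def test_single_atom_zero(self):
        assert radius_of_gyration(ca_model([[1.0, 2.0, 3.0]])) == pytest.approx(0.0, abs=1e-12)

    def test_two_equal_masses_half_separation(self):
        assert radius_of_gyration(ca_model([[0, 0, 0], [6.0, 0, 0]])) == pytest.approx(3.0)

    def test_uniform_sphere_converges_to_closed_form(self):
        rng = np.random.default_rng(5)
        R = 10.0
        pts = []
        while len(pts) < 4000:
            cand = rng.uniform(-R, R, size=3)
            if np.linalg.norm(cand) <= R:
                pts.append(cand)
        rg = radius_of_gyration(ca_model(pts))
        assert rg == pytest.approx(R * np.sqrt(3.0 / 5.0), rel=0.02)


class TestAlignmentMappedComparison:
    def aln_pair(self, n):
        row = "A" * n
        return AlignedSequenceSet(ids=["x", "y"], rows=[row, row])

    def test_self_rmsd_zero(self):
        model, _ = make_ideal_chain("helix", 10)
        aln = self.aln_pair(10)
        assert rmsd_common_calpha(model, model, aln, "x", "y") == pytest.approx(0.0, abs=1e-9)

    def test_hinged_pair_matches_direct_kabsch(self):
        model, _ = make_ideal_chain("helix", 12)
        X = model.chains[0].calpha_coords()
        Y = X.copy()
        rng = np.random.default_rng(9)
        Rh = random_rotation(rng)
        pivot = Y[7]
        Y[8:] = (Y[8:] - pivot) @ Rh.T + pivot  # hinge the last domain
        other = ca_model(Y)
        aln = self.aln_pair(12)
        got = rmsd_common_calpha(model, other, aln, "x", "y")
        expect = kabsch_superpose(X, Y).rmsd  # recomputed from construction
        assert got == pytest.approx(expect, abs=1e-9)

    def test_matched_set_counts_doubly_nongap_columns(self):
        model_a, _ = make_ideal_chain("helix", 8)
        model_b, _ = make_ideal_chain("helix", 7)
        aln = AlignedSequenceSet(ids=["x", "y"], rows=["AAAAAAAA", "AAA-AAAA"[:8]])
        numbers, P, Q = matched_calpha(model_a, model_b, aln, "x", "y")
        assert len(numbers) == 7 == len(P) == len(Q)

    def test_local_deviation_reads_planted_shift(self):
        model, _ = make_ideal_chain("helix", 10)
        X = model.chains[0].calpha_coords().copy()
        X[4] += [0.0, 0.0, 2.5]
        other = ca_model(X)
        aln = self.aln_pair(10)
        dev = local_ca_deviation(model, other, aln, "x", "y", superpose=False)
        assert dev.loc[5] == pytest.approx(2.5)
        assert dev.drop(5).max() < 1e-9

    def test_local_deviation_invariant_under_corotation(self):
        rng = np.random.default_rng(11)
        model, _ = make_ideal_chain("helix", 10)
        X = model.chains[0].calpha_coords()
        Y = X + rng.normal(scale=0.3, size=X.shape)
        R, t = random_rotation(rng), rng.normal(size=3)
        aln = self.aln_pair(10)
        d1 = local_ca_deviation(ca_model(X), ca_model(Y), aln, "x", "y")
        d2 = local_ca_deviation(ca_model(X @ R.T + t), ca_model(Y @ R.T + t), aln, "x", "y")
        np.testing.assert_allclose(d1.to_numpy(), d2.to_numpy(), atol=1e-8)


class TestSecondaryStructure:
    def test_ideal_helix_all_h_interior(self):
        model, _ = make_ideal_chain("helix", 12)
        ss = assign_secondary_structure(
            coarse_grained_angles(model.chains[0].calpha_coords())
        )
        assert ss[0] == "C" and ss[-1] == "C"
        assert set(ss[1:-2]) == {"H"}

    def test_ideal_strand_all_e_interior(self):
        model, _ = make_ideal_chain("strand", 10)
        ss = assign_secondary_structure(
            coarse_grained_angles(model.chains[0].calpha_coords())
        )
        assert set(ss[1:-2]) == {"E"}

    def test_coil_all_c_and_idempotent(self):
        model, _ = make_ideal_chain("coil", 14, seed=6)
        cga = coarse_grained_angles(model.chains[0].calpha_coords())
        ss = assign_secondary_structure(cga)
        assert ss == "C" * 14
        assert assign_secondary_structure(cga) == ss
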