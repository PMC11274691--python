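"""Conformation comparison: superposition, Cα deviations, coarse-grained
backbone angles, side-chain χ1, radius of gyration and Cα-only secondary
structure.

The coarse-grained angles (θ, γ) are the discrete curvature and torsion of
the Cα trace: θn is the virtual bond angle at Cα n (from Cα n−1, n, n+1)
and γn the virtual torsion over Cα n−1…n+2.  A chain of N residues carries
N−3 (θ, γ) pairs (n = 2 … N−2).  Because they are internal coordinates
they compare local backbone conformation without any structural alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem import CHI1_GAMMA_ATOM
from .structure import Chain, Residue, StructureModel


class GeometryError(ValueError):
    pass


# ---------------------------------------------------------------------------
# rigid superposition


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # 3x3 proper orthogonal
    translation: np.ndarray  # 3-vector, Å
    rmsd: float  # Å
    n_atoms_used: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch_superpose(P: np.ndarray, Q: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid transform mapping point set P onto Q (Kabsch).

    Returns the proper rotation R and translation t minimizing
    ‖R·P + t − Q‖; the RMSD is evaluated after the transform.
    """
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise GeometryError("P and Q must be matched (n, 3) arrays")
    n = len(P)
    if n < 3:
        raise GeometryError("need at least 3 matched points")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    Pc, Qc = P - cp, Q - cq
    sv = np.linalg.svd(Pc, compute_uv=False)
    if sv[1] <= 1e-9 * max(sv[0], 1.0):
        raise GeometryError("points are collinear; rotation is under-determined")
    H = Pc.T @ Qc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    diff = (P @ R.T + t) - Q
    rmsd = float(np.sqrt((diff**2).sum() / n))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd, n_atoms_used=n)


# ---------------------------------------------------------------------------
# alignment-matched Cα sets


def matched_calpha(
    model_a: StructureModel,
    model_b: StructureModel,
    aln,
    id_a: str,
    id_b: str,
) -> tuple[list[int], np.ndarray, np.ndarray]:
    """Cα pairs at columns that are non-gap in both alignment rows.

    Chains are paired in file order (chain k of A with chain k of B); each
    chain must match its alignment row's ungapped length.  Returns the MSA
    numbers (repeated once per chain pair) and the two coordinate arrays.
    """
    from .msa import msa_to_seq_position

    row_a, row_b = aln.row(id_a), aln.row(id_b)
    if len(model_a.chains) != len(model_b.chains):
        raise GeometryError("models have different chain counts")
    numbers: list[int] = []
    pa, pb = [], []
    for ch_a, ch_b in zip(model_a.chains, model_b.chains):
        _check_chain_matches_row(ch_a, row_a, id_a)
        _check_chain_matches_row(ch_b, row_b, id_b)
        for col in range(1, aln.ncols + 1):
            ia = msa_to_seq_position(aln, id_a, col)
            ib = msa_to_seq_position(aln, id_b, col)
            if ia is None or ib is None:
                continue
            ca_a = ch_a.residues[ia - 1].calpha
            ca_b = ch_b.residues[ib - 1].calpha
            if ca_a is None or ca_b is None:
                continue
            numbers.append(col)
            pa.append(ca_a.coord)
            pb.append(ca_b.coord)
    return numbers, np.array(pa), np.array(pb)


def _check_chain_matches_row(chain: Chain, row: str, row_id: str) -> None:
    ungapped = len(row.replace("-", ""))
    if len(chain.residues) != ungapped:
        raise GeometryError(
            f"chain {chain.id!r} has {len(chain.residues)} residues but alignment "
            f"row {row_id!r} has ungapped length {ungapped}"
        )


def rmsd_common_calpha(
    model_a: StructureModel, model_b: StructureModel, aln, id_a: str, id_b: str
) -> float:
    """Global Cα RMSD over doubly non-gap alignment columns, after optimal
    superposition."""
    _, P, Q = matched_calpha(model_a, model_b, aln, id_a, id_b)
    if len(P) < 3:
        raise GeometryError("fewer than 3 common Cα positions")
    return kabsch_superpose(P, Q).rmsd


def local_ca_deviation(
    model_a: StructureModel,
    model_b: StructureModel,
    aln,
    id_a: str,
    id_b: str,
    superpose: bool = True,
) -> pd.Series:
    """Per-MSA-number Cα–Cα distance between two structures.

    With ``superpose`` the matched set is first brought into a common
    frame via Kabsch; otherwise coordinates are compared as given.
    Homodimer chains contribute two values per column, which are averaged.
    """
    numbers, P, Q = matched_calpha(model_a, model_b, aln, id_a, id_b)
    if len(P) < 3:
        raise GeometryError("fewer than 3 common Cα positions")
    if superpose:
        P = kabsch_superpose(P, Q).apply(P)
    dist = np.linalg.norm(P - Q, axis=1)
    return pd.Series(dist, index=numbers).groupby(level=0).mean().rename("ca_deviation")


# ---------------------------------------------------------------------------
# coarse-grained angles


@dataclass
class CoarseGrainedAngles:
    """θ (bond angle at Cα n, n = 2…N−1) and γ (torsion over n−1…n+2,
    n = 2…N−2), degrees.  ``pairs()`` yields the N−3 (θ, γ) pairs."""

    theta: np.ndarray
    gamma: np.ndarray
    n_residues: int

    @property
    def n_pairs(self) -> int:
        return min(len(self.theta), len(self.gamma))

    def pairs(self) -> np.ndarray:
        m = self.n_pairs
        return np.column_stack([self.theta[:m], self.gamma[:m]])


def _bond_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    u, v = a - b, c - b
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise GeometryError("coincident consecutive Cα atoms")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle in degrees, IUPAC convention, in (−180, 180]."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    nb1 = np.linalg.norm(b1)
    if nb1 == 0:
        raise GeometryError("coincident central atoms in dihedral")
    b1 = b1 / nb1
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    ang = float(np.degrees(np.arctan2(y, x)))
    return 180.0 if ang == -180.0 else ang


def coarse_grained_angles(ca_coords: np.ndarray) -> CoarseGrainedAngles:
    """CGA profile of a Cα trace; requires ≥4 consecutive Cα."""
    X = np.asarray(ca_coords, float)
    if X.ndim != 2 or X.shape[1] != 3 or len(X) < 4:
        raise GeometryError("need an (n≥4, 3) Cα coordinate array")
    if np.any(np.linalg.norm(np.diff(X, axis=0), axis=1) < 1e-9):
        raise GeometryError("coincident consecutive Cα atoms")
    n = len(X)
    theta = np.array([_bond_angle(X[i - 1], X[i], X[i + 1]) for i in range(1, n - 1)])
    gamma = np.array(
        [dihedral(X[i - 1], X[i], X[i + 1], X[i + 2]) for i in range(1, n - 2)]
    )
    return CoarseGrainedAngles(theta=theta, gamma=gamma, n_residues=n)


def circular_difference(a: float | np.ndarray, b: float | np.ndarray) -> np.ndarray:
    """|a − b| wrapped onto [0, 180] degrees."""
    d = np.abs(np.asarray(a, float) - np.asarray(b, float)) % 360.0
    return np.where(d > 180.0, 360.0 - d, d)


def cga_deviation(
    cga_a: CoarseGrainedAngles, cga_b: CoarseGrainedAngles
) -> pd.DataFrame:
    """Per-residue circular |Δθ|, |Δγ| and the combined score
    max(|Δθ|, |Δγ|)/180 ∈ [0, 1] over the matched (θ, γ) pairs."""
    m = min(cga_a.n_pairs, cga_b.n_pairs)
    dtheta = circular_difference(cga_a.theta[:m], cga_b.theta[:m])
    dgamma = circular_difference(cga_a.gamma[:m], cga_b.gamma[:m])
    combined = np.maximum(dtheta, dgamma) / 180.0
    # pair n corresponds to residue n, n = 2 … m+1 (1-based)
    idx = pd.RangeIndex(2, m + 2, name="residue")
    return pd.DataFrame(
        {"delta_theta": dtheta, "delta_gamma": dgamma, "combined": combined}, index=idx
    )


# ---------------------------------------------------------------------------
# side chains


def chi1_angle(res: Residue) -> float | None:
    """χ1 dihedral N–Cα–Cβ–Xγ in degrees; None for Gly/Ala or when any of
    the four atoms is missing."""
    gamma_name = CHI1_GAMMA_ATOM.get(res.name)
    if gamma_name is None:
        return None
    atoms = [res.atom(nm) for nm in ("N", "CA", "CB", gamma_name)]
    if any(a is None for a in atoms):
        return None
    return dihedral(*(a.coord for a in atoms))


def chi1_profile(chain: Chain) -> list[float | None]:
    return [chi1_angle(res) for res in chain.residues]


def chi1_distance_value(chi_a: float, chi_b: float) -> float:
    """d = (1 − cos Δχ1)/2: 0 for identical rotamers, 1 for a 180° flip."""
    delta = np.radians(chi_a - chi_b)
    return float((1.0 - np.cos(delta)) / 2.0)


def chi1_distance(
    model_a: StructureModel, model_b: StructureModel, aln, id_a: str, id_b: str
) -> pd.Series:
    """Per-MSA-number χ1 distance in [0, 1]; residues without a defined χ1
    on either side are absent from the result (never reported as 0)."""
    from .msa import msa_to_seq_position

    out: dict[int, list[float]] = {}
    for ch_a, ch_b in zip(model_a.chains, model_b.chains):
        for col in range(1, aln.ncols + 1):
            ia = msa_to_seq_position(aln, id_a, col)
            ib = msa_to_seq_position(aln, id_b, col)
            if ia is None or ib is None:
                continue
            xa = chi1_angle(ch_a.residues[ia - 1])
            xb = chi1_angle(ch_b.residues[ib - 1])
            if xa is None or xb is None:
                continue
            out.setdefault(col, []).append(chi1_distance_value(xa, xb))
    data = {c: float(np.mean(v)) for c, v in sorted(out.items())}
    return pd.Series(data, name="chi1_distance", dtype=float)


# ---------------------------------------------------------------------------
# global shape


def radius_of_gyration(model: StructureModel) -> float:
    """Mass-weighted radius of gyration over protein heavy atoms, Å."""
    coords = model.atom_coords()
    masses = model.atom_masses()
    if len(coords) == 0:
        raise GeometryError("no atoms")
    com = np.average(coords, axis=0, weights=masses)
    sq = ((coords - com) ** 2).sum(axis=1)
    return float(np.sqrt(np.average(sq, weights=masses)))


# ---------------------------------------------------------------------------
# Cα-only secondary structure


@dataclass
class SecondaryStructureConfig:
    """Angular boxes on (θ, γ) for helix/strand assignment from the Cα
    trace alone, with minimum run lengths.  The defaults are canonical
    Cα-trace geometry (ideal helix θ≈91°, γ≈50°; extended strand
    θ≈120–135°, |γ|≈180°) and are configuration, not constants."""

    helix_theta: tuple[float, float] = (80.0, 105.0)
    helix_gamma: tuple[float, float] = (30.0, 70.0)
    helix_min_run: int = 4
    strand_theta: tuple[float, float] = (100.0, 155.0)
    strand_gamma_abs: tuple[float, float] = (140.0, 180.0)
    strand_min_run: int = 3


def assign_secondary_structure(
    cga: CoarseGrainedAngles, config: SecondaryStructureConfig | None = None
) -> str:
    """Per-residue H/E/C labels (length = number of residues).

    A residue n (with both θn and γn defined) is helix-compatible when
    (θn, γn) falls in the helix box and strand-compatible in the strand
    box; runs of at least the configured length are labelled, everything
    else is coil.  Terminal residues without a full (θ, γ) pair are coil.
    """
    cfg = config or SecondaryStructureConfig()
    n = cga.n_residues
    m = cga.n_pairs
    helix_ok = np.zeros(n, dtype=bool)
    strand_ok = np.zeros(n, dtype=bool)
    for k in range(m):
        resi = k + 1  # 0-based residue index of residue n = k + 2
        th, ga = cga.theta[k], cga.gamma[k]
        if cfg.helix_theta[0] <= th <= cfg.helix_theta[1] and cfg.helix_gamma[0] <= ga <= cfg.helix_gamma[1]:
            helix_ok[resi] = True
        if cfg.strand_theta[0] <= th <= cfg.strand_theta[1] and cfg.strand_gamma_abs[0] <= abs(ga) <= cfg.strand_gamma_abs[1]:
            strand_ok[resi] = True
    labels = ["C"] * n
    for mask, label, min_run in (
        (helix_ok, "H", cfg.helix_min_run),
        (strand_ok, "E", cfg.strand_min_run),
    ):
        i = 0
        while i < n:
            if not mask[i]:
                i += 1
                continue
            j = i
            while j < n and mask[j]:
                j += 1
            if j - i >= min_run:
                for k in range(i, j):
                    if labels[k] == "C":
                        labels[k] = label
            i = j
    return "".join(labels)


def chain_secondary_structure(
    chain: Chain, config: SecondaryStructureConfig | None = None
) -> str:
    return assign_secondary_structure(coarse_grained_angles(chain.calpha_coords()), config)
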