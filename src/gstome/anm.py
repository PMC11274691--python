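"""Parameter-free anisotropic network model (pfANM) on heavy atoms.

Every heavy atom is a node and every node pair is joined by a spring of
stiffness Γij = γ / Rij² — no interaction cutoff, which is what makes the
model parameter-free.  The mass-weighted Hessian

    Ĥij^{αβ} = Hij^{αβ} / √(mi mj),   Hij^{αβ} = −(Rij^α Rij^β / Rij²) Γij,
    Hii = −Σ_{j≠i} Hij

is diagonalized into 3N−6 internal modes (ω̃k², ek); thermal B-factors
follow as

    Bi = (8π²/3) (kB T / mi) Σ_k |eki|² / ω̃k²,

which is the Debye–Waller factor predicted by the harmonic model.  With
the default γ = 1 the absolute scale of B is arbitrary; Pearson
correlations against experimental profiles, the quantity of interest, are
scale-invariant, and a least-squares rescaling onto an experimental
profile is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy.stats import pearsonr

from .structure import StructureModel

RIGID_MODE_TOL = 1e-8  # eigenvalue below tol × max ⇒ rigid-body mode


class AnmError(ValueError):
    pass


@dataclass
class ElasticNetwork:
    """All-pairs spring network: node coordinates (Å), masses (Da), and
    the overall stiffness scale γ."""

    coords: np.ndarray
    masses: np.ndarray
    gamma: float = 1.0
    cutoff: float | None = None  # optional spring cutoff, off by default

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, float)
        self.masses = np.asarray(self.masses, float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise AnmError("coords must be (N, 3)")
        if len(self.masses) != len(self.coords):
            raise AnmError("masses/coords length mismatch")
        if np.any(self.masses <= 0):
            raise AnmError("non-positive mass")

    @property
    def n_nodes(self) -> int:
        return len(self.coords)

    @classmethod
    def from_structure(
        cls, model: StructureModel, gamma: float = 1.0, include_ligands: bool = False
    ) -> "ElasticNetwork":
        coords = [a.coord for _, a in model.iter_atoms()]
        masses = [a.mass for _, a in model.iter_atoms()]
        if include_ligands:
            for lig in model.ligands:
                for a in lig.atoms:
                    coords.append(a.coord)
                    masses.append(a.mass)
        return cls(coords=np.array(coords), masses=np.array(masses), gamma=gamma)


def build_hessian(network: ElasticNetwork) -> np.ndarray:
    """Mass-weighted 3N×3N Hessian of the all-pairs 1/R² spring network."""
    X = network.coords
    n = network.n_nodes
    if n < 2:
        raise AnmError("need at least 2 nodes")
    diff = X[:, None, :] - X[None, :, :]  # Rij vectors
    R2 = np.einsum("ijk,ijk->ij", diff, diff)
    if np.any(R2[~np.eye(n, dtype=bool)] < 1e-12):
        raise AnmError("coincident nodes")
    np.fill_diagonal(R2, np.inf)
    spring = network.gamma / R2  # Γij = γ/Rij²
    if network.cutoff is not None:
        spring = np.where(np.sqrt(R2) <= network.cutoff, spring, 0.0)
    coef = spring / R2  # Γij / Rij²
    H = -coef[:, :, None, None] * diff[:, :, :, None] * diff[:, :, None, :]
    # diagonal super-elements: Hii = −Σ_{j≠i} Hij
    diag = -H.sum(axis=1)
    H[np.arange(n), np.arange(n)] = diag
    m = network.masses
    w = 1.0 / np.sqrt(m[:, None] * m[None, :])
    H *= w[:, :, None, None]
    return H.transpose(0, 2, 1, 3).reshape(3 * n, 3 * n)


@dataclass
class NormalModes:
    """Eigenpairs of the mass-weighted Hessian, rigid modes excluded.

    ``frequencies_sq`` are the 3N−6 (or 3N−5 for collinear networks)
    internal eigenvalues ω̃k² in ascending order; ``vectors`` the matching
    orthonormal eigenvectors as columns; rigid-body eigenvalues are kept
    for inspection."""

    frequencies_sq: np.ndarray
    vectors: np.ndarray
    rigid_values: np.ndarray
    n_nodes: int

    @property
    def n_internal(self) -> int:
        return len(self.frequencies_sq)


def normal_modes(hessian: np.ndarray, max_rigid: int = 6) -> NormalModes:
    """Full symmetric eigendecomposition with rigid-mode classification.

    Eigenvalues below ``RIGID_MODE_TOL`` × the largest are rigid-body
    modes; more than ``max_rigid`` of them indicates a disconnected or
    degenerate network and raises.  Non-collinear 3-D networks have
    exactly 6; collinear ones (e.g. a diatomic) have 5.
    """
    H = np.asarray(hessian, float)
    if H.ndim != 2 or H.shape[0] != H.shape[1] or H.shape[0] % 3:
        raise AnmError("hessian must be 3N×3N")
    if not np.allclose(H, H.T, atol=1e-9 * max(1.0, np.abs(H).max())):
        raise AnmError("hessian is not symmetric")
    vals, vecs = scipy.linalg.eigh(H)
    scale = np.abs(vals).max()
    near_zero = np.abs(vals) < RIGID_MODE_TOL * scale
    n_rigid = int(near_zero.sum())
    if n_rigid > max_rigid:
        raise AnmError(
            f"{n_rigid} near-zero modes (> {max_rigid}): disconnected or degenerate network"
        )
    internal = ~near_zero
    if np.any(vals[internal] <= 0):
        raise AnmError("negative internal eigenvalue: structure is not a minimum")
    return NormalModes(
        frequencies_sq=vals[internal],
        vectors=vecs[:, internal],
        rigid_values=vals[near_zero],
        n_nodes=H.shape[0] // 3,
    )


@dataclass
class BFactorProfile:
    """Per-atom and per-residue thermal B-factors, Å² up to the γ scale."""

    atom_bfactors: np.ndarray
    temperature: float
    residue_bfactors: dict[tuple[str, int, str], float] = field(default_factory=dict)


def thermal_bfactors(
    modes: NormalModes,
    masses: np.ndarray,
    temperature: float = 300.0,
    kb: float = 1.0,
    model: StructureModel | None = None,
    calpha_only: bool = False,
) -> BFactorProfile:
    """Thermal B-factor per node from the internal modes.

    Bi = (8π²/3)(kB T / mi) Σ_k |eki|² / ω̃k².  With γ = 1 and kB = 1 the
    values are meaningful up to a global scale; use
    :func:`rescale_to_experimental` to put them on an experimental scale.
    When ``model`` is given, per-residue values (mean over the residue's
    heavy atoms, or the Cα atom alone with ``calpha_only``) are attached.
    """
    masses = np.asarray(masses, float)
    if len(masses) != modes.n_nodes:
        raise AnmError("masses length does not match mode dimension")
    if np.any(modes.frequencies_sq <= 0):
        raise AnmError("zero or negative eigenvalue leaked into the B-factor sum")
    E = modes.vectors.reshape(modes.n_nodes, 3, modes.n_internal)
    amp2 = np.einsum("ick,ick->ik", E, E)  # |eki|² per node per mode
    per_atom = (8.0 * np.pi**2 / 3.0) * (kb * temperature / masses) * (
        amp2 / modes.frequencies_sq[None, :]
    ).sum(axis=1)
    profile = BFactorProfile(atom_bfactors=per_atom, temperature=temperature)
    if model is not None:
        idx = 0
        values: dict[tuple[str, int, str], list[float]] = {}
        for res, atom in model.iter_atoms():
            if not calpha_only or atom.name == "CA":
                values.setdefault(res.key, []).append(per_atom[idx])
            elif res.key not in values:
                values.setdefault(res.key, [])
            idx += 1
        profile.residue_bfactors = {
            k: float(np.mean(v)) for k, v in values.items() if v
        }
    return profile


def rescale_to_experimental(
    predicted: np.ndarray, experimental: np.ndarray
) -> tuple[np.ndarray, float]:
    """Least-squares scale factor s minimizing ‖s·pred − exp‖ (equivalent
    to calibrating γ); returns (s·pred, s)."""
    predicted = np.asarray(predicted, float)
    experimental = np.asarray(experimental, float)
    denom = float(predicted @ predicted)
    if denom == 0:
        raise AnmError("zero predicted profile")
    s = float(predicted @ experimental) / denom
    return s * predicted, s


def bfactor_correlation(
    predicted: dict[tuple[str, int, str], float] | np.ndarray,
    experimental: dict[tuple[str, int, str], float] | np.ndarray,
) -> tuple[float | None, int]:
    """Pearson correlation between predicted and experimental per-residue
    B-factors over their common residues.

    Dict inputs are matched on residue keys; array inputs positionally.
    Returns (ρ, n_common); ρ is None when either side has zero variance.
    """
    if isinstance(predicted, dict) and isinstance(experimental, dict):
        common = sorted(set(predicted) & set(experimental))
        x = np.array([predicted[k] for k in common])
        y = np.array([experimental[k] for k in common])
    else:
        x = np.asarray(predicted, float)
        y = np.asarray(experimental, float)
        if len(x) != len(y):
            raise AnmError("array profiles must have equal length")
        keep = np.isfinite(x) & np.isfinite(y)
        x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise AnmError("fewer than 3 common residues")
    if np.std(x) == 0 or np.std(y) == 0:
        return None, n
    rho, _ = pearsonr(x, y)
    return float(rho), n


def predict_bfactors(
    model: StructureModel,
    gamma: float = 1.0,
    temperature: float = 300.0,
    include_ligands: bool = False,
    calpha_only: bool = False,
) -> BFactorProfile:
    """End-to-end pfANM B-factor prediction for a structure."""
    network = ElasticNetwork.from_structure(model, gamma=gamma, include_ligands=include_ligands)
    modes = normal_modes(build_hessian(network))
    masses = network.masses
    return thermal_bfactors(
        modes, masses, temperature=temperature, model=model, calpha_only=calpha_only
    )
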