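"""Seeded synthetic fixtures emulating the pipeline's inputs.

Real inputs to the analysis are AlphaFold-multimer homodimers (pLDDT in
the temperature-factor column), AlphaFill-style transplanted cofactor
copies, and a Clustal-style multiple alignment.  The generators here build
miniature stand-ins with *planned* ground truth — interface residues,
ligand cluster membership, invariant alignment columns, per-row charge —
recorded in a ledger, so every analysis module can be tested against known
answers without downloads.  Each generator is a pure function of its
arguments and seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from .structure import Atom, Chain, Residue, StructureModel
from .chem import atomic_mass

NEUTRAL_AA = "ACFGILMNPQSTVWY"  # no Lys/Arg/Asp/Glu/His: charge fully planned

BOND_CA = 3.8  # Å, virtual Cα–Cα bond length
HELIX_RISE = 1.5  # Å per residue
HELIX_TWIST = 100.0  # degrees per residue
HELIX_RADIUS = 2.3  # Å


class SyntheticError(ValueError):
    pass


@dataclass
class FixtureLedger:
    """Planted ground truth for one generated fixture."""

    seed: int
    data: dict = field(default_factory=dict)

    def __getitem__(self, key):
        return self.data[key]

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, set):
                return sorted(o)
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            raise TypeError(f"not serializable: {type(o)}")

        return json.dumps({"seed": self.seed, **self.data}, indent=2, default=default)


def _ca_atom(coord, bfactor: float = 90.0) -> Atom:
    return Atom(
        name="CA", element="C", coord=np.asarray(coord, float),
        mass=atomic_mass("C"), bfactor=bfactor,
    )


def _chain_from_trace(
    coords: np.ndarray, chain_id: str = "A", resname: str = "GLY",
    bfactors: np.ndarray | None = None,
) -> Chain:
    chain = Chain(id=chain_id)
    for i, xyz in enumerate(coords):
        b = 90.0 if bfactors is None else float(bfactors[i])
        chain.residues.append(
            Residue(name=resname, seqid=i + 1, chain_id=chain_id, atoms=[_ca_atom(xyz, b)])
        )
    return chain


def _place_next(a, b, c, bond: float, theta_deg: float, gamma_deg: float) -> np.ndarray:
    """Natural-extension placement: new point d with |cd| = bond, angle
    b-c-d = theta and torsion a-b-c-d = gamma."""
    theta = np.radians(theta_deg)
    gamma = np.radians(gamma_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [-np.cos(theta), np.sin(theta) * np.cos(gamma), np.sin(theta) * np.sin(gamma)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _helix_trace(n: int) -> np.ndarray:
    k = np.arange(n)
    ang = np.radians(HELIX_TWIST * k)
    return np.column_stack(
        [HELIX_RADIUS * np.cos(ang), HELIX_RADIUS * np.sin(ang), HELIX_RISE * k]
    )


def _strand_trace(n: int) -> np.ndarray:
    """Planar zigzag with virtual bond angle 125° and torsion 180°."""
    alpha = np.radians((180.0 - 125.0) / 2.0)
    pts = [np.zeros(3)]
    for k in range(1, n):
        sign = 1.0 if k % 2 else -1.0
        step = BOND_CA * np.array([np.cos(alpha), sign * np.sin(alpha), 0.0])
        pts.append(pts[-1] + step)
    return np.array(pts)


def _coil_trace(n: int, rng: np.random.Generator) -> np.ndarray:
    """Self-avoiding walk whose (θ, γ) stay outside both the helix and
    strand boxes, so Cα-only secondary structure reads all-coil."""
    pts = [
        np.array([0.0, 0.0, 0.0]),
        np.array([BOND_CA, 0.0, 0.0]),
        np.array([BOND_CA + BOND_CA * np.cos(np.radians(60)), BOND_CA * np.sin(np.radians(60)), 0.0]),
    ]
    while len(pts) < n:
        for _ in range(200):
            theta = rng.uniform(85.0, 150.0)
            gamma = rng.uniform(75.0, 135.0) * rng.choice([-1.0, 1.0])
            cand = _place_next(pts[-3], pts[-2], pts[-1], BOND_CA, theta, gamma)
            prior = np.array(pts[:-1])
            if np.min(np.linalg.norm(prior - cand, axis=1)) >= 3.0:
                pts.append(cand)
                break
        else:
            raise SyntheticError("self-avoiding walk failed to extend")
    return np.array(pts)


def make_ideal_chain(
    kind: str, n: int, seed: int = 0
) -> tuple[StructureModel, FixtureLedger]:
    """Single-chain Cα-trace model of an ideal helix, extended strand or
    random coil.  Helix geometry: rise 1.5 Å, 100°/residue, radius 2.3 Å."""
    if n < 5:
        raise SyntheticError("need n >= 5 residues")
    rng = np.random.default_rng(seed)
    if kind == "helix":
        coords = _helix_trace(n)
    elif kind == "strand":
        coords = _strand_trace(n)
    elif kind == "coil":
        coords = _coil_trace(n, rng)
    else:
        raise SyntheticError(f"unknown chain kind {kind!r}")
    model = StructureModel(chains=[_chain_from_trace(coords)], name=f"ideal_{kind}")
    ledger = FixtureLedger(seed=seed, data={
        "kind": kind,
        "n_residues": n,
        "n_atoms": n,
        "coords": coords,
    })
    return model, ledger


def make_toy_dimer(
    n_per_chain: int = 12,
    interface_size: int = 4,
    ligand_copies_per_pocket: int = 9,
    seed: int = 0,
    plddt_low_tail: int = 0,
) -> tuple[StructureModel, FixtureLedger]:
    """Two-fold symmetric toy homodimer with a planned interface, two
    ligand pockets and a designed communication corridor.

    Chains run parallel along x (Cα spacing 3.8 Å) at y = ±2.6 Å, out of
    contact range; the first ``interface_size`` residues carry a CB stub
    reaching toward the partner so that exactly those residues form
    inter-chain contacts at the 4.0 Å criterion.  One pocket of jittered
    ligand copies sits 3 Å outside the last residue of each chain, giving
    one single-linkage cluster per pocket at the 2.0 Å threshold.  The
    unique shortest holo→apo pathway runs down chain A, crosses at the
    interface residue nearest the pocket, and runs back up chain B:
    2·(n_per_chain − interface_size + 1) residues.

    ``plddt_low_tail`` residues at each chain's C-terminal end get a
    planted confidence of 30 (disordered-terminus emulation); all others
    carry 90.
    """
    n, w = n_per_chain, interface_size
    if not 0 < w < n:
        raise SyntheticError("need 0 < interface_size < n_per_chain")
    if plddt_low_tail >= n:
        raise SyntheticError("plddt_low_tail must be smaller than the chain")
    rng = np.random.default_rng(seed)

    plddt = np.full(n, 90.0)
    if plddt_low_tail:
        plddt[-plddt_low_tail:] = 30.0

    # gentle z-undulation keeps the network non-planar (a flat all-pairs
    # 1/R² network has no out-of-plane stiffness) without perturbing any
    # planned contact: all pair distances stay on the same side of 4.0 Å.
    z_wave = 0.25 * np.cos(1.7 * np.arange(n))

    def build_chain(chain_id: str, sign: float) -> Chain:
        chain = Chain(id=chain_id)
        for k in range(n):
            ca = np.array([BOND_CA * k, sign * 2.6, sign * z_wave[k]])
            atoms = [_ca_atom(ca, bfactor=plddt[k])]
            resname = "GLY"
            if k < w:  # interface stub reaching toward the partner chain
                cb = np.array([BOND_CA * k, sign * 1.8, sign * z_wave[k]])
                atoms.append(Atom(name="CB", element="C", coord=cb,
                                  mass=atomic_mass("C"), bfactor=plddt[k]))
                resname = "ALA"
            chain.residues.append(
                Residue(name=resname, seqid=k + 1, chain_id=chain_id, atoms=atoms)
            )
        return chain

    chain_a = build_chain("A", +1.0)
    chain_b = build_chain("B", -1.0)

    # ligand pockets 3 Å outside (+y) the C-terminal residue of each chain
    pocket_a = np.array([BOND_CA * (n - 1), 5.6, z_wave[n - 1]])
    pocket_b = np.array([BOND_CA * (n - 1), -5.6, -z_wave[n - 1]])  # 2-fold image
    atom_offsets = {
        "S1": np.array([0.25, 0.0, 0.0]),
        "C2": np.array([-0.25, 0.0, 0.0]),
        "N3": np.array([0.0, 0.25, 0.0]),
    }
    elements = {"S1": "S", "C2": "C", "N3": "N"}
    ligands: list[Residue] = []
    for chain_id, center in (("A", pocket_a), ("B", pocket_b)):
        for c in range(ligand_copies_per_pocket):
            jitter = rng.uniform(-0.2, 0.2, size=3)
            lig = Residue(name="GSH", seqid=500 + c, chain_id=chain_id)
            for nm, off in atom_offsets.items():
                lig.atoms.append(
                    Atom(name=nm, element=elements[nm], coord=center + jitter + off,
                         mass=atomic_mass(elements[nm]), is_hetero=True)
                )
            ligands.append(lig)

    model = StructureModel(chains=[chain_a, chain_b], ligands=ligands, name="toy_dimer")
    ledger = FixtureLedger(seed=seed, data={
        "n_per_chain": n,
        "interface_size": w,
        "interface_residues": list(range(1, w + 1)),  # author seqids, both chains
        "ligand_copies_per_pocket": ligand_copies_per_pocket,
        "n_pockets": 2,
        "pocket_centers": {"A": pocket_a, "B": pocket_b},
        "pocket_residues": {"A": [n], "B": [n]},  # seqids contacting the ligand
        "corridor_length": 2 * (n - w + 1),
        "n_shortest_paths": 1,
        "n_protein_atoms": 2 * (n + w),
        "n_ligand_atoms": 2 * ligand_copies_per_pocket * len(atom_offsets),
        "plddt": plddt,
    })
    return model, ledger


def make_synthetic_msa(
    n_rows: int = 36,
    length: int = 60,
    invariant_columns: dict[int, str] | list[int] | None = None,
    gap_blocks: list[tuple[list[int], int, int]] | None = None,
    charge_plan: dict[int, int] | None = None,
    seed: int = 0,
    class_plan: dict[int, str] | None = None,
) -> tuple[str, FixtureLedger]:
    """Aligned FASTA with planted column/row structure.

    ``invariant_columns``: MSA numbers (1-based) forced to a single amino
    acid in every row — exactly these come out fully conserved.
    ``gap_blocks``: (row_indices, col_start, col_end) gap stretches
    (0-based rows, 1-based inclusive columns).
    ``charge_plan``: target formal charge per row index under the default
    convention (His neutral); realized with Lys/Asp placements on a
    neutral background alphabet.
    """
    rng = np.random.default_rng(seed)
    if isinstance(invariant_columns, (list, tuple)):
        invariant_columns = {
            c: NEUTRAL_AA[rng.integers(len(NEUTRAL_AA))] for c in invariant_columns
        }
    invariant_columns = invariant_columns or {}
    gap_blocks = gap_blocks or []
    charge_plan = charge_plan or {}

    for c in invariant_columns:
        if not 1 <= c <= length:
            raise SyntheticError(f"invariant column {c} outside 1..{length}")
    gap_mask = np.zeros((n_rows, length), dtype=bool)
    for rows, c0, c1 in gap_blocks:
        if not 1 <= c0 <= c1 <= length:
            raise SyntheticError(f"gap block {c0}..{c1} outside 1..{length}")
        for r in rows:
            gap_mask[r, c0 - 1 : c1] = True
    for c, aa in invariant_columns.items():
        if aa not in NEUTRAL_AA:
            raise SyntheticError(f"invariant residue {aa!r} must be charge-neutral here")
        if gap_mask[:, c - 1].any():
            raise SyntheticError(f"gap block overlaps invariant column {c}")

    letters = rng.choice(list(NEUTRAL_AA), size=(n_rows, length))
    for c, aa in invariant_columns.items():
        letters[:, c - 1] = aa

    # charged residues placed on free (non-invariant, non-gap) columns
    inv_set = set(invariant_columns)
    for r, q in charge_plan.items():
        free = [c for c in range(length)
                if (c + 1) not in inv_set and not gap_mask[r, c]]
        if abs(q) > len(free):
            raise SyntheticError(f"row {r}: charge {q} needs more free columns than exist")
        chosen = rng.choice(free, size=abs(q), replace=False)
        letters[r, chosen] = "K" if q > 0 else "D"

    # break accidental full conservation of non-planted columns
    for c in range(length):
        if (c + 1) in inv_set or gap_mask[:, c].any():
            continue
        col = letters[:, c]
        if len(set(col)) == 1 and col[0] in NEUTRAL_AA:
            # mutating a neutral cell never disturbs a planned charge
            alt = next(a for a in NEUTRAL_AA if a != col[0])
            letters[0, c] = alt

    rows = []
    for r in range(n_rows):
        chars = ["-" if gap_mask[r, c] else letters[r, c] for c in range(length)]
        rows.append("".join(chars))
    ids = [f"seq{r + 1:02d}" for r in range(n_rows)]
    fasta = "".join(f">{rid}\n{row}\n" for rid, row in zip(ids, rows))

    ledger = FixtureLedger(seed=seed, data={
        "n_rows": n_rows,
        "length": length,
        "ids": ids,
        "invariant_columns": dict(sorted(invariant_columns.items())),
        "gap_column_counts": gap_mask.sum(axis=0),
        "gap_row_totals": gap_mask.sum(axis=1),
        "charge_plan": dict(charge_plan),
        "class_plan": dict(class_plan or {}),
    })
    return fasta, ledger


def make_flexible_dumbbell(
    n_core: int = 12, n_linker: int = 5, seed: int = 0
) -> tuple[StructureModel, FixtureLedger]:
    """Two dense clusters joined by a sparse linker — flexibility fixture.

    In the pfANM the thin linker, coupled weakly to both cores, must show
    larger thermal B-factors than the core interiors."""
    if n_core < 4 or n_linker < 4:
        raise SyntheticError("need n_core >= 4 and n_linker >= 4")
    rng = np.random.default_rng(seed)
    half = (n_linker + 1) * 3.0 / 2.0 + 4.0
    coords: list[np.ndarray] = []
    kinds: list[str] = []

    def sample_core(center: np.ndarray) -> None:
        pts: list[np.ndarray] = []
        while len(pts) < n_core:
            cand = center + rng.uniform(-3.0, 3.0, size=3)
            if all(np.linalg.norm(cand - p) > 1.5 for p in pts):
                pts.append(cand)
        coords.extend(pts)
        kinds.extend(["core"] * n_core)

    sample_core(np.array([-half, 0.0, 0.0]))
    x0 = -half + 4.0
    x1 = half - 4.0
    for k in range(1, n_linker + 1):
        t = k / (n_linker + 1)
        coords.append(np.array([x0 + t * (x1 - x0), 0.0, 0.0]))
        kinds.append("linker")
    sample_core(np.array([half, 0.0, 0.0]))

    chain = _chain_from_trace(np.array(coords), chain_id="A")
    model = StructureModel(chains=[chain], name="dumbbell")
    ledger = FixtureLedger(seed=seed, data={
        "core_indices": [i for i, k in enumerate(kinds) if k == "core"],
        "linker_indices": [i for i, k in enumerate(kinds) if k == "linker"],
        "n_atoms": len(coords),
    })
    return model, ledger
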