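"""Atomic-structure I/O and the uniform heavy-atom model.

PDB text is parsed with :mod:`gemmi` and reduced to a plain heavy-atom
representation: protein chains of residues carrying only N/C/O/S atoms,
with hydrogens, waters, ions and glycans dropped and glutathione-like
cofactors routed to a separate ligand list.  The temperature-factor column
carries either an experimental B-factor (Å²) or, for predicted models, a
per-residue pLDDT confidence on the 0–100 scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import gemmi
import numpy as np

from .chem import (
    AA3_TO_1,
    DEFAULT_LIGAND_NAMES,
    HEAVY_ELEMENTS,
    WATER_NAMES,
    atomic_mass,
)


class StructureError(ValueError):
    """Raised for malformed or empty structure input."""


@dataclass
class Atom:
    """One heavy atom: name, element, position (Å), mass (Da), occupancy,
    temperature factor (experimental B in Å² or pLDDT 0–100)."""

    name: str
    element: str
    coord: np.ndarray
    mass: float
    occupancy: float = 1.0
    bfactor: float = 0.0
    is_hetero: bool = False
    altloc: str = ""

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise StructureError(f"atom {self.name}: coordinate must be a finite 3-vector")
        if self.mass <= 0:
            raise StructureError(f"atom {self.name}: non-positive mass")


@dataclass
class Residue:
    """A residue identified by (chain id, author sequence number, insertion code)."""

    name: str
    seqid: int
    chain_id: str
    icode: str = ""
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seqid, self.icode)

    @property
    def one_letter(self) -> str:
        return AA3_TO_1.get(self.name, "X")

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def calpha(self) -> Atom | None:
        return self.atom("CA")

    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms])


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)

    def calpha_coords(self) -> np.ndarray:
        """Cα trace as an (n, 3) array; residues lacking Cα are skipped."""
        return np.array([r.calpha.coord for r in self.residues if r.calpha is not None])

    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)


@dataclass
class StructureModel:
    """Heavy-atom model: ordered protein chains plus hetero ligands."""

    chains: list[Chain] = field(default_factory=list)
    ligands: list[Residue] = field(default_factory=list)
    name: str = ""

    def chain(self, chain_id: str) -> Chain:
        for ch in self.chains:
            if ch.id == chain_id:
                return ch
        raise KeyError(f"no chain {chain_id!r}")

    def iter_residues(self) -> Iterator[Residue]:
        for ch in self.chains:
            yield from ch.residues

    def iter_atoms(self) -> Iterator[tuple[Residue, Atom]]:
        for res in self.iter_residues():
            for atom in res.atoms:
                yield res, atom

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.iter_residues())

    @property
    def n_residues(self) -> int:
        return sum(len(ch) for ch in self.chains)

    def atom_coords(self) -> np.ndarray:
        return np.array([a.coord for _, a in self.iter_atoms()])

    def atom_masses(self) -> np.ndarray:
        return np.array([a.mass for _, a in self.iter_atoms()])

    def subset(self, chain_ids: Sequence[str]) -> "StructureModel":
        """New model restricted to the given chains (ligands kept if their
        chain id matches or is unassigned)."""
        wanted = set(chain_ids)
        chains = [ch for ch in self.chains if ch.id in wanted]
        if not chains:
            raise KeyError(f"no chains among {sorted(wanted)}")
        ligands = [lg for lg in self.ligands if lg.chain_id in wanted or not lg.chain_id]
        return StructureModel(chains=chains, ligands=ligands, name=self.name)


@dataclass
class ConfidenceProfile:
    """Per-residue pLDDT read from the Cα temperature-factor column.

    ``values[i]`` is None when residue i has no Cα record."""

    residue_keys: list[tuple[str, int, str]]
    values: list[float | None]

    def as_array(self) -> np.ndarray:
        return np.array([np.nan if v is None else v for v in self.values])


def _prescan(pdb_text: str) -> None:
    """Validate coordinate fields of ATOM/HETATM records, reporting the
    offending line number (gemmi silently zeroes bad floats)."""
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if line[:6] not in ("ATOM  ", "HETATM"):
            continue
        if len(line) < 54:
            raise StructureError(f"line {lineno}: truncated ATOM/HETATM record")
        for lo, hi in ((30, 38), (38, 46), (46, 54)):
            fieldtxt = line[lo:hi].strip()
            try:
                float(fieldtxt)
            except ValueError:
                raise StructureError(
                    f"line {lineno}: malformed coordinate field {fieldtxt!r}"
                ) from None


def parse_structure(
    pdb_text: str,
    ligand_names: frozenset[str] | set[str] = DEFAULT_LIGAND_NAMES,
    model_index: int = 0,
) -> StructureModel:
    """Parse PDB text into a heavy-atom :class:`StructureModel`.

    Hydrogens and waters are dropped; for alternate locations only the
    first-listed conformer of each atom is kept; hetero residues whose
    name is in ``ligand_names`` become ligands, other hetero groups
    (ions, glycans, buffer molecules) are discarded.
    """
    _prescan(pdb_text)
    try:
        st = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"PDB parse failed: {exc}") from exc
    if len(st) == 0:
        raise StructureError("empty model: no coordinates found")
    gmodel = st[model_index]

    chains: list[Chain] = []
    ligands: list[Residue] = []
    for gchain in gmodel:
        chain = Chain(id=gchain.name)
        for gres in gchain:
            if gres.name in WATER_NAMES:
                continue
            is_het = gres.het_flag == "H"
            if is_het and gres.name not in ligand_names:
                continue
            res = Residue(
                name=gres.name,
                seqid=gres.seqid.num,
                chain_id=gchain.name,
                icode=gres.seqid.icode.strip(),
            )
            seen: set[str] = set()
            for ga in gres:
                elem = ga.element.name.upper()
                if elem == "H" or elem == "D":
                    continue
                if not is_het and elem not in HEAVY_ELEMENTS:
                    continue
                if ga.name in seen:  # later altloc of an atom already kept
                    continue
                seen.add(ga.name)
                res.atoms.append(
                    Atom(
                        name=ga.name,
                        element=elem,
                        coord=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                        mass=atomic_mass(elem),
                        occupancy=ga.occ,
                        bfactor=ga.b_iso,
                        is_hetero=is_het,
                        altloc=ga.altloc.strip(),
                    )
                )
            if not res.atoms:
                continue
            if is_het:
                ligands.append(res)
            else:
                chain.residues.append(res)
        if chain.residues:
            chains.append(chain)
    model = StructureModel(chains=chains, ligands=ligands, name=st.name or "")
    if model.n_atoms == 0 and not ligands:
        raise StructureError("empty model: no heavy atoms after filtering")
    return model


def read_structure(path, **kwargs) -> StructureModel:
    """Parse a PDB file from disk; the file stem becomes the model name."""
    from pathlib import Path

    p = Path(path)
    model = parse_structure(p.read_text(), **kwargs)
    model.name = p.stem
    return model


_CHAIN_IDS = (
    "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"
)


def write_structure(model: StructureModel) -> str:
    """Serialize a model back to standards-conformant PDB text."""
    if len(model.chains) > len(_CHAIN_IDS):
        raise StructureError(f">{len(_CHAIN_IDS)} chains: PDB identifier space exhausted")
    st = gemmi.Structure()
    st.name = model.name or "model"
    gmodel = gemmi.Model("1")

    def to_gemmi_residue(res: Residue) -> gemmi.Residue:
        gres = gemmi.Residue()
        gres.name = res.name
        gres.seqid = gemmi.SeqId(res.seqid, res.icode or " ")
        gres.het_flag = "H" if any(a.is_hetero for a in res.atoms) else "A"
        for atom in res.atoms:
            ga = gemmi.Atom()
            ga.name = atom.name
            ga.element = gemmi.Element(atom.element.capitalize())
            ga.pos = gemmi.Position(*atom.coord)
            ga.occ = atom.occupancy
            ga.b_iso = atom.bfactor
            if atom.altloc:
                ga.altloc = atom.altloc
            gres.add_atom(ga)
        return gres

    for chain in model.chains:
        gchain = gemmi.Chain(chain.id)
        for res in chain.residues:
            gchain.add_residue(to_gemmi_residue(res))
        gmodel.add_chain(gchain)
    # hetero ligands appended to their host chain (or a fresh chain if unassigned)
    lig_chains: dict[str, gemmi.Chain] = {}
    for lig in model.ligands:
        cid = lig.chain_id or "L"
        host = None
        for gchain in gmodel:
            if gchain.name == cid:
                host = gchain
                break
        if host is None:
            if cid not in lig_chains:
                lig_chains[cid] = gemmi.Chain(cid)
            host = lig_chains[cid]
        host.add_residue(to_gemmi_residue(lig))
    for gchain in lig_chains.values():
        gmodel.add_chain(gchain)
    st.add_model(gmodel)
    return st.make_pdb_string()


def extract_confidence(model: StructureModel) -> ConfidenceProfile:
    """Per-residue pLDDT profile, read from each residue's Cα record.

    Residues without a Cα are flagged absent (None), never interpolated.
    """
    keys: list[tuple[str, int, str]] = []
    values: list[float | None] = []
    for res in model.iter_residues():
        keys.append(res.key)
        ca = res.calpha
        values.append(None if ca is None else float(ca.bfactor))
    return ConfidenceProfile(residue_keys=keys, values=values)
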