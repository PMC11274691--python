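import numpy as np
import pytest

from gstome import (
    make_synthetic_msa,
    make_toy_dimer,
    parse_structure,
    read_alignment,
    write_structure,
)


@pytest.fixture(scope="session")
def toy_dimer_raw():
    """Toy homodimer as generated (model, ledger)."""
    return make_toy_dimer(
        n_per_chain=10, interface_size=4, ligand_copies_per_pocket=9, seed=11,
        plddt_low_tail=2,
    )


@pytest.fixture(scope="session")
def toy_dimer(toy_dimer_raw, tmp_path_factory):
    """Toy homodimer written to a real PDB file and re-read through the
    public parser, so I/O is exercised on every run."""
    model, ledger = toy_dimer_raw
    path = tmp_path_factory.mktemp("fixtures") / "toy_dimer.pdb"
    path.write_text(write_structure(model))
    reread = parse_structure(path.read_text())
    reread.name = "toy_dimer"
    return reread, ledger


@pytest.fixture(scope="session")
def synthetic_alignment():
    """36-row alignment with 3 planted invariant columns, a 30-row gap
    block and planned per-row charges; re-read through the parser."""
    fasta, ledger = make_synthetic_msa(
        n_rows=36,
        length=50,
        invariant_columns=[7, 21, 44],
        gap_blocks=[(list(range(30)), 31, 35)],
        charge_plan={0: 4, 1: -3, 2: 0},
        seed=23,
    )
    return read_alignment(fasta), ledger


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniformly random proper rotation matrix."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q *= np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    return Q
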