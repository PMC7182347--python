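import numpy as np
import pytest

from disorderlink import (
    FamilyConfig,
    build_seed_backbone,
    generate_family,
)
from disorderlink.structure_io import ChainStructure, ResidueStructure


@pytest.fixture(scope="session")
def family_dir(tmp_path_factory):
    """A generated 25-member family on disk, shared across tests."""
    outdir = tmp_path_factory.mktemp("family")
    cfg = FamilyConfig(n_proteins=25, seed=7)
    data = generate_family(cfg, outdir)
    return data


@pytest.fixture(scope="session")
def seed_chain_50():
    return build_seed_backbone(FamilyConfig(length=50, seed=3))


def make_residue(seq_num, res_type="A", chain_id="A", **atom_coords):
    """Toy residue from keyword atom coordinates, e.g. CA=(0,0,0)."""
    atoms = {k: np.asarray(v, dtype=float) for k, v in atom_coords.items()}
    elements = {k: ("N" if k == "N" else "O" if k == "O" else "C") for k in atoms}
    return ResidueStructure(chain_id, seq_num, "", res_type, atoms, elements)


def make_chain(residues, missing=(), pdb_id="TOYS"):
    return ChainStructure(pdb_id, residues[0].chain_id, list(residues), list(missing))
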