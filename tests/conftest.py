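import numpy as np
import pytest

from immunoprofile.io_formats import ProteinStructure, Residue
from immunoprofile.synthetic_data import build_ideal_structure


@pytest.fixture(scope="session")
def helix20() -> ProteinStructure:
    """20-residue ideal alpha helix (polyalanine)."""
    return build_ideal_structure([("helix", 20)], protein_id="helix20")


@pytest.fixture(scope="session")
def hairpin() -> ProteinStructure:
    """Two antiparallel 8-residue strands closed by a tight turn."""
    return build_ideal_structure([("strand", 8), ("coil", 2), ("strand", 8)],
                                 sequence="V" * 18, protein_id="hairpin")


def single_atom_chain(distances) -> ProteinStructure:
    """Residues of one CA atom each, spaced along x at the given positions."""
    residues = [
        Residue(i + 1, "G", ["CA"], np.array([[x, 0.0, 0.0]]))
        for i, x in enumerate(distances)
    ]
    return ProteinStructure("beads", residues)


def random_chain(n_residues: int, seed: int, aa_pool: str = "ACDEFGHIKLMNPQRSTVWY"
                 ) -> ProteinStructure:
    """Random-coil ideal-geometry chain with random sequence."""
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list(aa_pool), size=n_residues))
    return build_ideal_structure([("coil", n_residues)], sequence=seq,
                                 protein_id=f"rand{seed}", seed=rng)
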