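import numpy as np
import pytest

from ssefold.fixtures import ToyTopologySpec, generate_toy_protein
from ssefold.geometry import CA
from ssefold.metrics import kabsch_rmsd, rmsd100


@pytest.fixture(scope="session")
def toy():
    """Designed three-helix bundle with perfect predictions (seed-fixed)."""
    return generate_toy_protein(ToyTopologySpec.three_helix_bundle(), seed=3)


@pytest.fixture(scope="session")
def toy_strands():
    return generate_toy_protein(ToyTopologySpec.strand_pair(), seed=5)


def rmsd100_to_native(model, native):
    """Best-superposition RMSD100 over the residues present in both."""
    nat_idx = native.modeled_indices()
    idx = model.modeled_indices()
    common = np.intersect1d(idx, nat_idx)
    a = model.atom_coords(CA)[np.isin(idx, common)]
    b = native.atom_coords(CA)[np.isin(nat_idx, common)]
    return rmsd100(kabsch_rmsd(a, b), len(common))
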