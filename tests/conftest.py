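import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from rdkit import Chem

from admeprofiler import standardize
from admeprofiler.reference import STREPTOMYCIN_SMILES

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# small molecules covering varied chemistry, used across property tests
FIXTURE_SMILES = [
    "C",
    "CC",
    "CCO",
    "CC(=O)O",
    "CC(=O)OC",
    "c1ccccc1",
    "Cc1ccccc1",
    "c1ccncc1",
    "c1cc[nH]c1",
    "CC(=O)Nc1ccc(O)cc1",
    "CC(=O)Oc1ccccc1C(=O)O",
    "CN1CCC[C@H]1c1cccnc1",
    "OCC1OC(O)C(O)C(O)C1O",
    "CC(C)Cc1ccc(cc1)C(C)C(=O)O",
    "NS(=O)(=O)c1ccccc1",
    "O=C1CCCCCCCCCCC1",
    "C1CC2CCC1C2",
    "C1CC2(CC1)CCCC2",
]


@pytest.fixture(scope="session")
def streptomycin():
    return standardize(STREPTOMYCIN_SMILES, "streptomycin")


@pytest.fixture(scope="session")
def fixture_molecules():
    return [standardize(s, f"fx_{i}") for i, s in enumerate(FIXTURE_SMILES)]


def random_molecules(n, seed):
    """Generate n random valid molecules from a simple branching grammar."""
    rng = np.random.default_rng(seed)
    tokens = [
        "C", "CC", "N", "O", "C(C)", "C(=O)", "C(N)", "C(O)", "C(F)",
        "C(Cl)", "c1ccccc1", "C1CCCCC1", "C1CCNCC1", "c1ccncc1",
    ]
    out = []
    while len(out) < n:
        k = rng.integers(1, 7)
        smi = "".join(rng.choice(tokens) for _ in range(k))
        mol = Chem.MolFromSmiles(smi)
        if mol is not None and mol.GetNumHeavyAtoms() > 0:
            out.append(Chem.MolToSmiles(mol))
    return out
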