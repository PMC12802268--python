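import pytest
from rdkit import Chem, RDLogger

from rxnforge.examples import acylsulfonamide, suzuki_iodo
from rxnforge.generator import BuildingBlock
from rxnforge.io_cli import BlockFileSpec, make_fixtures, read_blocks
from rxnforge.pattern_engine import GroupLibrary

RDLogger.DisableLog("rdApp.*")

#: 50 small sanitizable molecules spanning aromatics, heterocycles, halides,
#: charged species, fused rings, and the functional groups the logic names.
PANEL_SMILES = [
    "C", "CC", "CCC", "CCCC", "C1CCCCC1",
    "c1ccccc1", "Cc1ccccc1", "Ic1ccccc1", "Ic1ccc(I)cc1", "Oc1ccccc1",
    "Nc1ccccc1", "NCc1ccccc1", "CCNCC", "CCN(CC)CC", "CS(N)(=O)=O",
    "NS(=O)(=O)c1ccccc1", "CC(O)=O", "OC(=O)c1ccccc1", "OB(O)c1ccccc1",
    "C#Cc1ccccc1", "CC#CC", "N(=[N+]=[N-])Cc1ccccc1", "ClCCl", "ClC(Cl)Cl",
    "Clc1ccccc1", "Brc1ccccc1", "Fc1ccccc1", "COC", "COCOC", "CCO",
    "CC(C)O", "CC(=O)C", "CC(=O)OC", "CC(=O)N", "CC(=O)NC",
    "c1ccncc1", "c1ccoc1", "c1ccsc1", "c1cc[nH]c1", "c1ccc2ccccc2c1",
    "c1ccc2[nH]ccc2c1", "C1CCNCC1", "C1CCOC1", "OCC(O)CO",
    "C[N+](C)(C)C", "[O-]C(=O)C", "CSC", "O=S(=O)(O)O", "N#Cc1ccccc1",
    "OCc1ccc(Cl)cc1",
]


@pytest.fixture(scope="session")
def panel():
    return [Chem.MolFromSmiles(s) for s in PANEL_SMILES]


@pytest.fixture(scope="session")
def group_library():
    return GroupLibrary.default()


@pytest.fixture(scope="session")
def suzuki():
    return suzuki_iodo()


@pytest.fixture(scope="session")
def acyl():
    return acylsulfonamide()


@pytest.fixture()
def block(request):
    def make(ident, smiles):
        return BuildingBlock(ident, smiles)
    return make


@pytest.fixture(scope="session")
def fixture_blocks(tmp_path_factory):
    """Seeded 10x10 fixture block sets for the toy transforms."""
    root = tmp_path_factory.mktemp("blocks")
    out = {}
    for cls in ("aryl_iodide", "boronic_acid", "sulfonamide", "carboxylic_acid"):
        spec = make_fixtures(seed=1, n_per_class=10, classes=[cls],
                             path=root / f"{cls}.tsv")
        out[cls] = read_blocks(spec)
    return out
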