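import numpy as np
import pytest

from ensdock import synthetic_fixtures as sf
from ensdock.structure_io import Atom, Structure


@pytest.fixture(scope="session")
def extended_peptide():
    return sf.make_toy_peptide(42, "extended", seed=0)


@pytest.fixture(scope="session")
def ligand_with_annotation():
    return sf.toy_ligand()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_atom(serial=1, name="CA", element="C", resname="ALA", resnum=1,
              chain="A", coords=(0.0, 0.0, 0.0), **kw):
    return Atom(serial=serial, name=name, element=element, residue_name=resname,
                residue_number=resnum, chain_id=chain,
                coords=np.asarray(coords, float), **kw)


def random_structure(rng, n_atoms=20, n_residues=5, spread=10.0, label="rand"):
    """Random heavy-atom structure spread over a box, for oracle tests."""
    atoms = []
    for i in range(n_atoms):
        atoms.append(make_atom(
            serial=i + 1, name=f"C{i % 9 + 1}", element="C",
            resname="ALA", resnum=i * n_residues // n_atoms + 1,
            coords=rng.uniform(-spread, spread, 3)))
    return Structure(atoms, label=label)
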