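import numpy as np
import pytest

from cystforge.fixtures import FixtureSpec, make_disulfide_pair, make_structure
from cystforge.structure import Atom, Residue, Structure


@pytest.fixture
def helix20():
    return make_structure(FixtureSpec(n_residues=20))


@pytest.fixture
def forged_pair():
    """Two-residue structure with textbook disulfide geometry."""
    return make_disulfide_pair()


def build_residue(seq, res_name, atoms, chain="A"):
    """Residue from a {atom_name: (element, xyz)} mapping."""
    return Residue(
        chain,
        seq,
        "",
        res_name,
        [
            Atom(chain, seq, "", res_name, name, element, np.asarray(xyz, float))
            for name, (element, xyz) in atoms.items()
        ],
    )


def build_structure(*residues, identifier="test", ssbonds=()):
    return Structure(identifier, residues, ssbonds)
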