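import numpy as np
import pytest

import caaxbind as cb


@pytest.fixture(scope="session")
def toy_template():
    return cb.make_toy_template()


@pytest.fixture(scope="session")
def toy_structure_and_anchors():
    return cb.make_toy_structure()


@pytest.fixture(scope="session")
def energy_fn():
    return cb.EnergyFunction.default()


@pytest.fixture(scope="session")
def constraints(toy_template):
    return cb.derive_constraints(toy_template)


@pytest.fixture(scope="session")
def native_pose(toy_template):
    """Template's own sequence threaded onto the template."""
    return cb.thread_sequence(toy_template, toy_template.peptide_sequence())


SINGLE_ATOM_PDB = (
    "ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00"
    "           N\n"
    "END\n"
)


@pytest.fixture()
def single_atom_pdb():
    return SINGLE_ATOM_PDB
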