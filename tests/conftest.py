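import numpy as np
import pytest

from mnmgbsa.fixtures import (FixtureSpec, hydration_shell_placements,
                              make_hydrated_frames, make_toy_dimer)
from mnmgbsa.interface import find_interface_residues, interface_com
from mnmgbsa.model import Trajectory


@pytest.fixture(scope="session")
def toy_dimer():
    """Two-chain pseudo-peptide with a designed contact (topology, frame,
    (contact residue A, contact residue B))."""
    return make_toy_dimer(FixtureSpec())


@pytest.fixture(scope="session")
def toy_interface(toy_dimer):
    top, frame, _ = toy_dimer
    spec = find_interface_residues(frame, top)
    return spec, interface_com(frame, top, spec)


@pytest.fixture(scope="session")
def hydrated_dimer(toy_dimer, toy_interface):
    """Toy dimer plus 40 clash-free waters at known distances from the
    interface center of mass; ground-truth ranking included."""
    top, frame, _ = toy_dimer
    _, com = toy_interface
    placements = hydration_shell_placements(frame, com, 40, seed=3)
    htop, hframe, ranking = make_hydrated_frames(top, frame, placements,
                                                 seed=2, origin=com)
    return htop, hframe, ranking, com


@pytest.fixture(scope="session")
def hydrated_trajectory(hydrated_dimer):
    htop, hframe, _, _ = hydrated_dimer
    return Trajectory(htop, [hframe])


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
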