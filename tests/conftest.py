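import numpy as np
import pytest

from hydracryst.core import Atom, Box, Structure, Trajectory


def water(residue_id, oxygen, h1=None, h2=None, start_serial=1, chain="W"):
    """Three-site water; hydrogens default to a standard geometry near +x/+y."""
    oxygen = np.asarray(oxygen, dtype=float)
    if h1 is None:
        h1 = oxygen + np.array([0.9572, 0.0, 0.0])
    if h2 is None:
        h2 = oxygen + np.array([-0.24, 0.927, 0.0])
    names = (("O", "O"), ("H1", "H"), ("H2", "H"))
    return [
        Atom(serial=start_serial + i, name=n, element=e, residue_name="HOH",
             residue_id=residue_id, chain_id=chain, position=p)
        for i, ((n, e), p) in enumerate(zip(names, (oxygen, h1, h2)))
    ]


def single_frame(structure: Structure) -> Trajectory:
    return Trajectory(topology=structure,
                      frames=[(structure.positions, structure.box)])


@pytest.fixture
def collinear_dimer() -> Structure:
    """Donor water at origin pointing +x at an acceptor water 2.8 A away."""
    atoms = water(1, [0.0, 0.0, 0.0])
    atoms += water(2, [2.8, 0.0, 0.0],
                   h1=[3.1, 0.9, 0.0], h2=[3.1, -0.9, 0.0], start_serial=4)
    return Structure(atoms=atoms)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_water_box(n_waters: int, box_edge: float, seed: int) -> Structure:
    """Waters with uniform random O positions and orientations in a box."""
    from hydracryst.watermodel import random_water_sites

    r = np.random.default_rng(seed)
    atoms = []
    for i in range(n_waters):
        sites = random_water_sites(r.random(3) * box_edge, r)
        atoms += [
            Atom(serial=3 * i + 1 + k, name=n, element=e, residue_name="HOH",
                 residue_id=i + 1, chain_id="W", position=sites[k])
            for k, (n, e) in enumerate((("O", "O"), ("H1", "H"), ("H2", "H")))
        ]
    return Structure(atoms=atoms, box=Box((box_edge,) * 3))
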