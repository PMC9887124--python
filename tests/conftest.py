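import numpy as np
import pytest

from cgbind import dynamics as dyn
from cgbind import forcefield as ff
from cgbind.topology import (
    FLEXIBLE,
    STATIC,
    CalphaStructure,
    Residue,
    RigidGroup,
    SystemTopology,
    build_system,
)


@pytest.fixture(scope="session")
def ff_params():
    return ff.ForceFieldParams()


@pytest.fixture(scope="session")
def pair_table(ff_params):
    return ff.default_pair_table(ff_params)


@pytest.fixture(scope="session")
def ffield(ff_params):
    return dyn.ForceField.default(ff_params)


def chain_structure(codes: str, coords, chain="A") -> CalphaStructure:
    residues = [
        Residue(chain, k + 1, "", codes[k], np.asarray(coords[k], dtype=float))
        for k in range(len(codes))
    ]
    return CalphaStructure({chain: residues}, [])


@pytest.fixture()
def dimer_topology():
    """Two glycine beads, fully flexible, bonded at the equilibrium length."""
    coords = [[25.0, 25.0, 25.0], [25.0, 25.0, 28.81]]
    return build_system(chain_structure("GG", coords), {}, ["A:1-2"], box=50.0)


def harmonic_trap_topology(k_trap: float, mass_code="G", box=60.0):
    """A flexible bead tethered to a static bead by a zero-length spring.

    The bond U = k·r² is an isotropic 3D harmonic trap about the static bead.
    """
    p = ff.residue_params(mass_code)
    n = 2
    return SystemTopology(
        codes=[mass_code] * n,
        chains=["A"] * n,
        resnums=np.array([1, 2]),
        positions=np.array([[box / 2] * 3, [box / 2] * 3]),
        masses=np.array([p.mass, p.mass]),
        charges=np.zeros(n),
        sigmas=np.array([p.sigma, p.sigma]),
        type_index=np.array([ff.AMINO_ACIDS.index(mass_code)] * n),
        mobility=np.array([STATIC, FLEXIBLE]),
        rigid_groups={},
        bonds=np.array([[0, 1]]),
        bond_r0=np.array([0.0]),
        bond_k=np.array([k_trap]),
        exclusions={(0, 1)},
        box=box,
    )


def rigid_tribead_topology(box=60.0):
    """A single rigid triangle of leucines, alone in a box."""
    coords = np.array([[0.0, 0.0, 0.0], [3.8, 0.0, 0.0], [1.9, 3.3, 0.0]]) + box / 2
    topo = build_system(
        chain_structure("LLL", coords), {"tri": ["A:1-3"]}, [], box=box
    )
    return topo
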