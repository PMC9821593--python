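import numpy as np
import pytest

from dendrikit import EllipsoidSpec, Frame, Topology, Trajectory, make_ellipsoid_cloud


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def rod_frame():
    """100 equal-mass beads at distinct positions on the x axis."""
    x = np.linspace(0.0, 5.0, 100)
    return Frame(np.column_stack([x, np.zeros(100), np.zeros(100)]))


@pytest.fixture
def sphere_cloud():
    """Dense uniform solid-sphere cloud of radius 2 nm (N = 10^4)."""
    return make_ellipsoid_cloud(EllipsoidSpec((2.0, 2.0, 2.0), n_beads=10_000, seed=7))


def two_group_topology(n_dend, lig_sizes, masses=None, **kw):
    """Topology with the first n_dend atoms as dendrimer and consecutive
    ligand molecules of the given sizes."""
    n = n_dend + sum(lig_sizes)
    mols, start = [], n_dend
    for s in lig_sizes:
        mols.append(np.arange(start, start + s))
        start += s
    return Topology(atom_count=n,
                    masses=np.ones(n) if masses is None else masses,
                    dendrimer_atoms=np.arange(n_dend),
                    ligand_molecules=mols, **kw)


def static_trajectory(coords_list, topology, dt=0.1):
    frames = [Frame(c, time=i * dt) for i, c in enumerate(coords_list)]
    return Trajectory(topology=topology, frames=frames, dt=dt)
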