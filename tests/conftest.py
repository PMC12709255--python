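import numpy as np
import pytest

from synfrap.geometry import (CYTOSOL, EXTERIOR, VESICLE, GeometryParams,
                              VoxelGrid, build_geometry)


def make_box_grid(nx=3, ny=3, nz=3, vesicles=(), sealed=True,
                  voxel_edge=25.0):
    """A rectangular all-cytosol test lattice.

    ``sealed=True`` pads the periodic axis with exterior voxels so no wrap
    can occur; the whole box counts as bouton (synapse mask covers it).
    """
    if sealed:
        labels = np.zeros((nx + 2, ny, nz), dtype=np.int8)
        labels[1:nx + 1] = CYTOSOL
        xoff = 1
    else:
        labels = np.full((nx, ny, nz), CYTOSOL, dtype=np.int8)
        xoff = 0
    for v in vesicles:
        labels[v[0] + xoff, v[1], v[2]] = VESICLE
    shape = labels.shape
    a = voxel_edge
    center = tuple(s * a / 2.0 for s in shape)
    big = 1e9  # ellipsoid covering the whole box -> everything is "synapse"
    return VoxelGrid(labels=labels, voxel_edge=a, center=center,
                     semi_axes=(big, big, big), axon_diameter=0.0,
                     axon_length=shape[0] * a)


@pytest.fixture(scope="session")
def small_bouton():
    """A modest bouton+axon geometry shared across tests."""
    params = GeometryParams(major_axis_length=500, aspect_ratio=1.5,
                            n_vesicles=600, n_mitochondria=1, n_vacuoles=1,
                            organelle_volume_fraction=0.10)
    return build_geometry(params, seed=7)


@pytest.fixture(scope="session")
def elongated_bouton():
    """A long thin bouton where a 400-nm spot bleaches only the center."""
    params = GeometryParams(major_axis_length=700, aspect_ratio=2.0,
                            n_vesicles=800, n_mitochondria=1, n_vacuoles=2,
                            organelle_volume_fraction=0.10)
    return build_geometry(params, seed=3)
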