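"""Shared fixtures: sphere meshes, conductors, transfer matrices.

The fine three-shell sphere (~50k tetrahedra, scalp/skull/brain at
0.33/0.0042/0.33 S/m, radii 92/86/80 mm) is the standard validation
conductor; expensive operators on it are session-scoped so the whole
suite assembles and factorizes them once.
"""

from __future__ import annotations

import numpy as np
import pytest

from ephysfem.analytic import SphereModel
from ephysfem.conductivity import default_isotropic
from ephysfem.fem import assemble_stiffness, attach_electrodes, eeg_transfer
from ephysfem.mesh import GM, SCALP, SKULL, _fibonacci_sphere, build_nested_sphere_mesh

RADII = (0.092, 0.086, 0.080)
SHELL_SIGMAS = (0.33, 0.0042, 0.33)  # scalp / skull / brain, S/m
SHELL_TISSUES = (SCALP, SKULL, GM)
FINE_EDGE = 0.009  # ~50k tetrahedra
SMALL_EDGE = 0.012


@pytest.fixture(scope="session")
def sphere_model():
    return SphereModel(center=[0.0, 0.0, 0.0], radii=RADII,
                       conductivities=SHELL_SIGMAS)


@pytest.fixture(scope="session")
def small_mesh():
    """Coarse three-shell ball for cheap unit tests (~20k tetra)."""
    return build_nested_sphere_mesh(RADII, SHELL_TISSUES, SMALL_EDGE, seed=3)


@pytest.fixture(scope="session")
def fine_mesh():
    """The ~50k-element validation mesh."""
    return build_nested_sphere_mesh(RADII, SHELL_TISSUES, FINE_EDGE, seed=7)


def shell_conductivity(mesh):
    return default_isotropic(
        mesh, overrides=dict(zip(SHELL_TISSUES, SHELL_SIGMAS)))


@pytest.fixture(scope="session")
def fine_cond(fine_mesh):
    return shell_conductivity(fine_mesh)


@pytest.fixture(scope="session")
def fine_stiffness(fine_mesh, fine_cond):
    return assemble_stiffness(fine_mesh, fine_cond)


@pytest.fixture(scope="session")
def electrodes60():
    """60 electrodes spread over the outer sphere surface."""
    return _fibonacci_sphere(60) * RADII[0]


@pytest.fixture(scope="session")
def fine_electrode_op(fine_mesh, electrodes60):
    return attach_electrodes(fine_mesh, electrodes60)


@pytest.fixture(scope="session")
def fine_transfer(fine_stiffness, fine_electrode_op):
    return eeg_transfer(fine_stiffness, fine_electrode_op)


@pytest.fixture(scope="session")
def fine_electrode_positions(fine_mesh, fine_electrode_op):
    """Actual scalp-vertex positions the electrodes snapped to."""
    return np.asarray(fine_electrode_op @ fine_mesh.vertices)


@pytest.fixture(scope="session")
def small_stiffness(small_mesh):
    return assemble_stiffness(small_mesh, shell_conductivity(small_mesh))
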