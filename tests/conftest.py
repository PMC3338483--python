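import numpy as np
import pytest

from geledge.fem import (
    ElasticMaterial,
    GelGeometry,
    IndenterSpec,
    MeshParams,
    build_axisym_mesh,
    solve_contact_indentation,
)

SEED = 1


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(SEED)


@pytest.fixture(scope="session")
def coarse_material():
    return ElasticMaterial(youngs_modulus=450.0, poisson_ratio=0.45)


@pytest.fixture(scope="session")
def coarse_mesh():
    """Small, fast mesh for unit tests (not converged)."""
    return build_axisym_mesh(
        GelGeometry(height=20.0, radius=100.0),
        MeshParams(refine_radius=6.0, fine_size=1.0, coarse_size=15.0),
    )


@pytest.fixture(scope="session")
def coarse_solve(coarse_mesh, coarse_material):
    """A cheap but genuine contact solve shared across unit tests."""
    indenter = IndenterSpec(radius=5.0, max_depth=2.0, n_steps=4)
    return solve_contact_indentation(coarse_mesh, coarse_material, indenter)
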