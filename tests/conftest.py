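import numpy as np
import pytest

from orthofem import fem
from orthofem.anatomy import AnatomyConfig, build_model
from orthofem.mesh import tetrahedralize


@pytest.fixture(scope="session")
def default_model():
    return build_model(AnatomyConfig())


@pytest.fixture(scope="session")
def default_mesh(default_model):
    return tetrahedralize(default_model, target_edge=0.9)


@pytest.fixture(scope="session")
def coarse_mesh(default_model):
    """Cheap mesh for tests that only need the structure, not accuracy."""
    return tetrahedralize(default_model, target_edge=1.6)


@pytest.fixture(scope="session")
def solved_default(default_model, default_mesh):
    """One retraction solve on the default anatomy, shared across tests."""
    op = fem.assemble(default_mesh)
    spec = fem.load_spec_from_model(default_mesh, default_model)
    result = fem.solve(op, spec)
    samples = fem.von_mises_at(result, default_mesh, default_model.landmark_set)
    return op, spec, result, samples


@pytest.fixture(scope="session")
def solved_coarse(default_model, coarse_mesh):
    op = fem.assemble(coarse_mesh)
    spec = fem.load_spec_from_model(coarse_mesh, default_model)
    result = fem.solve(op, spec)
    return op, spec, result
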