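import numpy as np
import pytest

from peddrs.forward_model import assemble_fem, build_system_matrix
from peddrs.phantom_mesh import TISSUE_OPTICS, build_structured_tet_mesh


@pytest.fixture(scope="session")
def small_mesh():
    """6x6x6 mm muscle box at 1 mm spacing (343 nodes) for FEM-level tests."""
    return build_structured_tet_mesh((6.0, 6.0, 6.0), 1.0)


@pytest.fixture(scope="session")
def small_fem(small_mesh):
    return assemble_fem(small_mesh, TISSUE_OPTICS)


@pytest.fixture(scope="session")
def small_system(small_fem):
    return build_system_matrix(small_fem)


@pytest.fixture(scope="session")
def study_runs():
    """Ten seeded reconstructions on the reference phantom (seeds 1-5 x
    {tikhonov, dsvd}), each paired with its one-step baseline.

    Session-scoped: these drive the accuracy-bound and improvement
    properties and take a few minutes in total.
    """
    from peddrs.inverse_solvers import SolverSpec
    from peddrs.study import default_phantom, run_study_case, simulate_measurements

    phantom = default_phantom()
    out = []
    for method in ("tikhonov", "dsvd"):
        for seed in range(1, 6):
            B = simulate_measurements(phantom, 0.05, seed)
            _, scores = run_study_case(phantom, B, SolverSpec(method))
            _, base = run_study_case(phantom, B, SolverSpec(method), one_step=True)
            out.append(
                {"method": method, "seed": seed, "peddrs": scores, "one_step": base}
            )
    return phantom, out
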