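"""Shared fixtures.

The default mesh and the baseline simulation are expensive enough (~10 s)
to be worth building once per session; tests that need small geometries
build their own coarse variants.
"""

import numpy as np
import pytest

from qrsim.activation import (
    ConductivitySet,
    baseline_roots,
    compute_activation,
)
from qrsim.forward import simulate_ecg
from qrsim.geometry import GeometryParams, build_biventricular_mesh


@pytest.fixture(scope="session")
def default_mesh():
    return build_biventricular_mesh()


@pytest.fixture(scope="session")
def small_mesh():
    """Coarser, smaller ventricles for fast unit tests."""
    return build_biventricular_mesh(
        GeometryParams(
            spacing=3.0,
            lv_cavity_radius=18.0,
            lv_wall_thickness=10.0,
            lv_apex_thickness=12.0,
            lv_inner_length=50.0,
            rv_center=(-17.0, 3.0, 0.0),
            rv_semiaxes=(32.0, 25.0, 42.0),
            rv_wall_thickness=4.0,
        )
    )


@pytest.fixture(scope="session")
def baseline_activation(default_mesh):
    return compute_activation(default_mesh, baseline_roots(), ConductivitySet())


@pytest.fixture(scope="session")
def baseline_ecg(default_mesh, baseline_activation):
    return simulate_ecg(
        default_mesh,
        baseline_roots(),
        ConductivitySet(),
        activation=baseline_activation,
    )
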