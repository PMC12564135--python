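"""Shared fixtures: fixed-seed pull ensembles and small scenes.

Pull ensembles are session-scoped because the steered-pull integrations
dominate the suite's runtime and several physics checks interrogate the
same study conditions.
"""

from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from ligmem.dynamics import LangevinParams, PullProtocol, simulate_smd_pull
from ligmem.potentials import PotentialSpec
from ligmem.scene import SceneSpec, build_bilayer_scene

settings.register_profile(
    "suite", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None,
)
settings.load_profile("suite")

#: acceptance-style double well: interior minima at 2 and 17 Å, 4 kcal/mol
#: barrier, domain padded beyond the pulled [0, 19] Å interval so the
#: reflecting edges never engage during a pull
DW = PotentialSpec.double_well(2.0, 17.0, 4.0, (-3.0, 22.0))
DW_PARAMS = LangevinParams(D=100.0, T=300.0, dt=4e-5)
FLAT = PotentialSpec.flat((-5.0, 24.0))


def make_pullset(potential, params, v, k, n_per_direction, seed_base, stride=500,
                 z_lo=0.0, z_hi=19.0):
    traces = []
    for i in range(n_per_direction):
        traces.append(simulate_smd_pull(
            potential, params, PullProtocol("F", v, k, z_lo, z_hi, stride),
            seed=seed_base + i))
        traces.append(simulate_smd_pull(
            potential, params, PullProtocol("R", v, k, z_hi, z_lo, stride),
            seed=seed_base + 1000 + i))
    return traces


@pytest.fixture(scope="session")
def dw_pullset():
    """20 F + 20 R pulls on the double well at v=0.1 Å/ns, k=10, D=100."""
    return make_pullset(DW, DW_PARAMS, v=0.1, k=10.0, n_per_direction=20, seed_base=41000)


@pytest.fixture(scope="session")
def flat_nullset():
    """20 F + 20 R pulls on a flat potential (zero-ΔU null)."""
    par = LangevinParams(D=50.0, T=300.0, dt=1e-4)
    return make_pullset(FLAT, par, v=0.5, k=10.0, n_per_direction=20,
                        seed_base=52000, stride=100)


@pytest.fixture(scope="session")
def small_scene():
    """Static 3×3 guaiacyl scene with a thin water slab (fast, boxed)."""
    spec = SceneSpec(
        box=(60.0, 60.0, 70.0), n_lipids_per_leaflet=36, leaflet_z=20.0,
        water_number_density=0.004, solute_grid=3, n_frames=5, seed=11,
    )
    topo, traj = build_bilayer_scene(spec)
    return spec, topo, traj
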