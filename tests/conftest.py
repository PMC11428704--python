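"""Shared fixtures: rheologies, meshes, and cached solver runs.

The solver runs (Poiseuille refinement ladder, Womersley pulsatile tube,
dissected two-lumen channel) are session-scoped so the oracle-equivalence,
mass-conservation and index tests reuse a single computation each.
"""

import numpy as np
import pytest

from hemoflow.geometry import VesselSpec, build_vessel
from hemoflow.rheology import RheologyParams
from hemoflow.solver import SolverConfig, solve_steady, solve_transient
from hemoflow.waveforms import womersley_velocity


@pytest.fixture(scope="session")
def blood():
    return RheologyParams()


@pytest.fixture(scope="session")
def newtonian():
    return RheologyParams.newtonian(0.0035)


TUBE_DIAMETER_MM = 4.0
TUBE_LENGTH_MM = 16.0
TUBE_RADIUS = TUBE_DIAMETER_MM / 2 * 1e-3
STEADY_INLET_VELOCITY = 0.05  # m/s mean


@pytest.fixture(scope="session")
def tube_spec():
    return VesselSpec(kind="straight", inlet_diameter=TUBE_DIAMETER_MM,
                      length=TUBE_LENGTH_MM)


@pytest.fixture(scope="session")
def poiseuille_ladder(tube_spec, newtonian):
    """(mesh, steady state) per refinement level of the straight tube."""
    out = []
    for res in (8, 16, 32):
        mesh = build_vessel(tube_spec, res)
        state = solve_steady(mesh, STEADY_INLET_VELOCITY, 0.0, newtonian)
        out.append((mesh, state))
    return out


#: pressure-gradient harmonics driving the Womersley verification flow
WOMERSLEY_G = np.array([-100.0, -200.0 + 0.0j])


@pytest.fixture(scope="session")
def womersley_run(tube_spec, newtonian):
    """Transient Newtonian tube driven by the exact Womersley inlet."""
    mesh = build_vessel(tube_spec, 32)

    def profile(yc, t):
        return womersley_velocity(TUBE_RADIUS, WOMERSLEY_G, newtonian, yc, t)

    cfg = SolverConfig(time_step=4e-4, cycles=3, inlet_profile=profile,
                       n_record=50)
    series = solve_transient(mesh, None, None, newtonian, cfg)
    return mesh, series


@pytest.fixture(scope="session")
def dissected_spec():
    return VesselSpec(kind="dissected", length=60.0, true_lumen_diameter=8.0,
                      false_lumen_diameter=8.0, septum_thickness=1.0,
                      tear_positions=((10.0, 8.0),))


@pytest.fixture(scope="session")
def dissected_run(dissected_spec, blood):
    """Pulsatile non-Newtonian flow in the two-lumen channel (3 cycles)."""
    from hemoflow.waveforms import WaveformSpec, synthesize_pulse

    mesh = build_vessel(dissected_spec, 8)
    inlet = synthesize_pulse(
        WaveformSpec(systolic_level=0.12, diastolic_level=0.02, unit="m/s"),
        n_samples=100)
    outlet = synthesize_pulse(WaveformSpec(), n_samples=100)
    cfg = SolverConfig(cycles=3, n_record=50)
    series = solve_transient(mesh, inlet, outlet, blood, cfg)
    return mesh, series
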