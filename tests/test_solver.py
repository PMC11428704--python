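"""Flow solver verification against analytic oracles and conservation laws."""

import numpy as np
import pytest

from hemoflow.geometry import VesselSpec, build_vessel
from hemoflow.rheology import RheologyParams
from hemoflow.solver import (ConvergenceError, SolverConfig, StepSizeError,
                             net_flux_imbalance, solve_steady,
                             solve_transient, wall_shear_stress, wall_y_plus)
from hemoflow.waveforms import (Waveform, poiseuille_wss, womersley_velocity,
                                womersley_wall_shear)

from conftest import (STEADY_INLET_VELOCITY, TUBE_RADIUS, WOMERSLEY_G)


def _tube_flow_rate(mesh, state) -> float:
    dy = mesh.y_faces[1] - mesh.y_faces[0]
    rc = (np.arange(mesh.shape[1]) + 0.5) * dy
    return float(np.sum(state.u[0] * 2 * np.pi * rc * dy))


class TestSteadyPoiseuille:
    def test_centreline_to_mean_ratio(self, poiseuille_ladder):
        mesh, state = poiseuille_ladder[-1]  # resolution 32
        imid = mesh.shape[0] // 2
        q = _tube_flow_rate(mesh, state)
        mean = q / (np.pi * TUBE_RADIUS**2)
        assert state.u[imid, 0] / mean == pytest.approx(2.0, rel=0.02)

    def test_wss_matches_oracle_within_2pct_on_finest(self, poiseuille_ladder,
                                                      newtonian):
        mesh, state = poiseuille_ladder[-1]
        q = _tube_flow_rate(mesh, state)
        exact = poiseuille_wss(q, TUBE_RADIUS, newtonian.mu_inf)
        wss = wall_shear_stress(state, mesh, newtonian)
        tau = np.linalg.norm(wss.vectors, axis=-1)[:, 0]
        assert np.max(np.abs(tau - exact)) / exact < 0.02

    def test_wss_error_decreases_over_refinement(self, poiseuille_ladder,
                                                 newtonian):
        errs = []
        for mesh, state in poiseuille_ladder:
            q = _tube_flow_rate(mesh, state)
            exact = poiseuille_wss(q, TUBE_RADIUS, newtonian.mu_inf)
            wss = wall_shear_stress(state, mesh, newtonian)
            tau = np.linalg.norm(wss.vectors, axis=-1)[:, 0]
            errs.append(abs(np.max(tau) - exact) / exact)
        assert errs[0] > errs[1] > errs[2]

    def test_zero_inflow_gives_zero_field(self, tube_spec, newtonian):
        mesh = build_vessel(tube_spec, 8)
        state = solve_steady(mesh, 0.0, 0.0, newtonian)
        assert np.allclose(state.u, 0.0)
        assert np.allclose(state.v, 0.0)
        assert np.allclose(state.p, 0.0)

    def test_mass_conservation(self, poiseuille_ladder):
        for mesh, state in poiseuille_ladder:
            assert net_flux_imbalance(state, mesh) < 1e-8

    def test_nonconvergence_raises_with_history(self, tube_spec, newtonian):
        mesh = build_vessel(tube_spec, 8)
        with pytest.raises(ConvergenceError) as err:
            solve_steady(mesh, STEADY_INLET_VELOCITY, 0.0, newtonian,
                         SolverConfig(max_steady_steps=12,
                                      residual_tolerance=1e-12))
        assert len(err.value.residual_history) == 12


class TestTransient:
    def test_womersley_profiles_within_3pct_l2(self, womersley_run,
                                               newtonian):
        mesh, series = womersley_run
        imid = mesh.shape[0] // 2
        dy = mesh.y_faces[1] - mesh.y_faces[0]
        yc = (np.arange(mesh.shape[1]) + 0.5) * dy
        num = series.u[:, imid, :]
        ana = np.stack([womersley_velocity(TUBE_RADIUS, WOMERSLEY_G,
                                           newtonian, yc, t)
                        for t in series.times])
        err = np.linalg.norm(num - ana) / np.linalg.norm(ana)
        assert err < 0.03

    def test_womersley_mass_conservation(self, womersley_run):
        mesh, series = womersley_run
        assert net_flux_imbalance(series, mesh) < 1e-8

    def test_cycle_drift_below_one_percent(self, womersley_run):
        _, series = womersley_run
        assert series.diagnostics["cycle_drift"] < 0.01

    def test_wss_sign_reverses_within_cycle(self, womersley_run, newtonian):
        # the oscillatory harmonic dominates off-peak: the analytic wall
        # shear changes sign over the cycle and the solver reproduces it
        mesh, series = womersley_run
        ana = womersley_wall_shear(TUBE_RADIUS, WOMERSLEY_G, newtonian,
                                   series.times)
        assert ana.min() < 0 < ana.max()
        wss = wall_shear_stress(series, mesh, newtonian)
        mid = wss.vectors.shape[0] // 2
        axial = wss.vectors[mid, :, 0]
        assert axial.min() < 0 < axial.max()
        # magnitude agreement with the analytic wall gradient
        # (sign convention: wall drag opposes the near-wall flow direction)
        assert np.corrcoef(np.abs(axial), np.abs(ana))[0, 1] > 0.99

    def test_constant_waveforms_converge_to_steady(self, tube_spec,
                                                   newtonian):
        mesh = build_vessel(tube_spec, 16)
        steady = solve_steady(mesh, STEADY_INLET_VELOCITY, 0.0, newtonian)
        n = 50
        inlet = Waveform(values=np.full(n, STEADY_INLET_VELOCITY),
                         period=1.0, unit="m/s")
        outlet = Waveform(values=np.zeros(n), period=1.0, unit="Pa")
        series = solve_transient(mesh, inlet, outlet, newtonian,
                                 SolverConfig(cycles=3, n_record=10))
        rel = np.max(np.abs(series.u[-1] - steady.u)) / np.max(steady.u)
        assert rel < 0.01

    def test_dissected_tear_feeds_false_lumen(self, dissected_run):
        mesh, series = dissected_run
        sep_j = np.nonzero(np.any(mesh.septum, axis=0))[0]
        dy = mesh.y_faces[1] - mesh.y_faces[0]
        u_out = series.u[:, -1, :]
        # brute-force flux integration over each lumen's outlet section
        q_true = float((u_out[:, :sep_j[0]] * dy).sum(axis=1).mean())
        q_false = float((u_out[:, sep_j[-1] + 1:] * dy).sum(axis=1).mean())
        assert q_true > 0
        assert q_false > 0  # fed only through the tear

    def test_dissected_mass_conservation(self, dissected_run):
        mesh, series = dissected_run
        assert net_flux_imbalance(series, mesh) < 1e-8

    def test_determinism(self, tube_spec, newtonian):
        mesh = build_vessel(tube_spec, 8)
        inlet = Waveform(values=0.05 + 0.02 * np.sin(2 * np.pi
                                                     * np.arange(50) / 50),
                         period=1.0, unit="m/s")
        cfg = SolverConfig(cycles=1, n_record=10)
        a = solve_transient(mesh, inlet, None, newtonian, cfg)
        b = solve_transient(mesh, inlet, None, newtonian, cfg)
        assert np.array_equal(a.u, b.u)
        assert np.array_equal(a.p, b.p)

    def test_excessive_time_step_rejected(self, tube_spec, newtonian):
        mesh = build_vessel(tube_spec, 16)
        inlet = Waveform(values=np.full(50, 0.05), period=1.0, unit="m/s")
        with pytest.raises(StepSizeError) as err:
            solve_transient(mesh, inlet, None, newtonian,
                            SolverConfig(time_step=0.1))
        assert err.value.suggested_dt < 0.1

    def test_tapered_mesh_rejected(self, newtonian):
        mesh = build_vessel(VesselSpec(kind="straight", inlet_diameter=10.0,
                                       outlet_diameter=6.0, length=50.0), 8)
        with pytest.raises(ValueError, match="rectilinear"):
            solve_steady(mesh, 0.05, 0.0, newtonian)


class TestWallYPlus:
    def test_zero_wss_gives_zero(self, tube_spec, newtonian):
        mesh = build_vessel(tube_spec, 8)
        state = solve_steady(mesh, 0.0, 0.0, newtonian)
        assert np.allclose(wall_y_plus(state, mesh, newtonian), 0.0)

    def test_square_root_scaling(self, poiseuille_ladder, newtonian):
        mesh, state = poiseuille_ladder[1]
        yp1 = wall_y_plus(state, mesh, newtonian)
        quadrupled = type(state)(u=4.0 * state.u, v=4.0 * state.v,
                                 p=state.p, time=0.0)
        yp4 = wall_y_plus(quadrupled, mesh, newtonian)
        assert np.allclose(yp4, 2.0 * yp1, rtol=1e-10)

    def test_hand_value_from_analytic_wss(self, poiseuille_ladder,
                                          newtonian):
        mesh, state = poiseuille_ladder[-1]
        q = _tube_flow_rate(mesh, state)
        tau = poiseuille_wss(q, TUBE_RADIUS, newtonian.mu_inf)
        dy = mesh.y_faces[1] - mesh.y_faces[0]
        nu = newtonian.mu_inf / newtonian.density
        expected = 0.5 * dy * np.sqrt(tau / newtonian.density) / nu
        yp = wall_y_plus(state, mesh, newtonian)
        assert np.median(yp) == pytest.approx(expected, rel=0.03)
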