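"""Synthetic vessel meshing: construction, tags, refinement, convergence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hemoflow.geometry import (POST_AD, PRE_AD, VesselSpec, build_vessel,
                               mesh_convergence_report, refine)


class TestVesselSpec:
    def test_dissected_without_tear_rejected(self):
        with pytest.raises(ValueError, match="tear"):
            VesselSpec(kind="dissected", true_lumen_diameter=10.0,
                       false_lumen_diameter=10.0, tear_positions=())

    def test_tear_outside_domain_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            VesselSpec(kind="dissected", length=50.0,
                       true_lumen_diameter=10.0, false_lumen_diameter=10.0,
                       tear_positions=((45.0, 10.0),))

    def test_presets_carry_measured_diameters(self):
        assert PRE_AD.inlet_diameter == 52.79
        assert PRE_AD.outlet_diameter == 28.44
        assert POST_AD.true_lumen_diameter == (23.17, 20.18)
        assert POST_AD.false_lumen_diameter == (44.55, 19.11)


class TestBuildVessel:
    def test_straight_channel_cell_counts(self):
        # 20 mm diameter x 100 mm: 10 radial cells -> 0.1 mm... resolution
        # 20 across the diameter = 10 across the radius, aspect-1 cells
        mesh = build_vessel(VesselSpec(kind="straight", inlet_diameter=20.0,
                                       length=100.0), 20)
        assert mesh.shape == (100, 10)
        tags = {f.tag for f in mesh.boundary_faces()}
        assert tags == {"inlet", "outlet", "wall", "axis"}

    def test_resolution_floor(self):
        with pytest.raises(ValueError):
            build_vessel(VesselSpec(), 4)

    def test_pre_ad_preset_tapers_linearly(self):
        mesh = build_vessel(PRE_AD, 16)
        radius = mesh.nodes[:, -1, 1]
        x = mesh.nodes[:, 0, 0]
        expected = (52.79 / 2 + (28.44 - 52.79) / 2 * x / x[-1]) * 1e-3
        assert np.allclose(radius, expected)
        assert not mesh.is_rectilinear

    def test_post_ad_preset_builds_and_validates(self):
        mesh = build_vessel(POST_AD, 10)
        mesh.validate()
        assert np.any(mesh.septum)
        tags = {f.tag for f in mesh.boundary_faces()}
        assert "septum" in tags

    def test_wall_distance_matches_diameter(self):
        spec = VesselSpec(kind="straight", inlet_diameter=7.0, length=30.0)
        mesh = build_vessel(spec, 14)
        width = mesh.nodes[:, -1, 1] - mesh.nodes[:, 0, 1]
        cell = 3.5e-3 / 7
        assert np.all(np.abs(width - 3.5e-3) <= cell)

    def test_septum_too_thin_for_resolution(self):
        spec = VesselSpec(kind="dissected", length=60.0,
                          true_lumen_diameter=20.0, false_lumen_diameter=20.0,
                          septum_thickness=0.5, tear_positions=((10.0, 10.0),))
        with pytest.raises(ValueError, match="coarse"):
            build_vessel(spec, 8)

    def test_dissected_false_lumen_sealed_at_inlet(self, dissected_spec):
        mesh = build_vessel(dissected_spec, 8)
        faces = mesh.boundary_faces()
        west = [f for f in faces if f.side == "W" and f.i == 0]
        inlet_js = {f.j for f in west if f.tag == "inlet"}
        wall_js = {f.j for f in west if f.tag == "wall"}
        sep_j = np.nonzero(np.any(mesh.septum, axis=0))[0]
        assert max(inlet_js) < sep_j[0]       # inlet feeds the true lumen
        assert min(wall_js) > sep_j[-1]       # false lumen sealed

    def test_arch_is_valid_but_curvilinear(self):
        mesh = build_vessel(VesselSpec(kind="arch", inlet_diameter=20.0,
                                       length=150.0, bend_angle=120.0), 12)
        mesh.validate()
        assert not mesh.is_rectilinear
        assert np.all(mesh.cell_areas() > 0)

    @given(st.sampled_from(["straight", "arch", "dissected"]),
           st.floats(min_value=8.0, max_value=40.0),
           st.floats(min_value=40.0, max_value=120.0),
           st.integers(min_value=8, max_value=14))
    @settings(max_examples=25, deadline=None)
    def test_randomized_specs_pass_validity_audit(self, kind, diameter,
                                                  length, resolution):
        if kind == "dissected":
            spec = VesselSpec(kind=kind, length=length,
                              true_lumen_diameter=diameter,
                              false_lumen_diameter=diameter,
                              septum_thickness=diameter / 6,
                              tear_positions=((length * 0.2, length * 0.3),))
        elif kind == "arch":
            spec = VesselSpec(kind=kind, inlet_diameter=diameter,
                              length=max(length, diameter * 3),
                              bend_angle=90.0)
        else:
            spec = VesselSpec(kind=kind, inlet_diameter=diameter,
                              length=length)
        mesh = build_vessel(spec, resolution)
        mesh.validate()
        # every boundary face carries exactly one tag by construction;
        # check the audit invariants explicitly
        assert np.all(mesh.cell_areas()[mesh.fluid] > 0)


class TestRefine:
    def test_cell_counts_scale(self):
        mesh = build_vessel(VesselSpec(kind="straight", inlet_diameter=20.0,
                                       length=100.0), 20)
        fine = refine(mesh, 2)
        assert fine.shape == (200, 20)

    def test_factor_validation(self):
        mesh = build_vessel(VesselSpec(), 8)
        with pytest.raises(ValueError):
            refine(mesh, 1)

    def test_tags_cover_same_curves(self, dissected_spec):
        mesh = build_vessel(dissected_spec, 8)
        fine = refine(mesh, 2)
        fine.validate()
        for tag in ("inlet", "outlet", "wall", "septum"):
            coarse_n = sum(f.tag == tag for f in mesh.boundary_faces())
            fine_n = sum(f.tag == tag for f in fine.boundary_faces())
            assert fine_n == 2 * coarse_n

    def test_twice_by_two_equals_once_by_four(self):
        mesh = build_vessel(VesselSpec(kind="arch", inlet_diameter=15.0,
                                       length=100.0, bend_angle=90.0), 10)
        a = refine(refine(mesh, 2), 2)
        b = refine(mesh, 4)
        assert np.allclose(a.nodes, b.nodes, rtol=0, atol=1e-15)
        assert np.array_equal(a.fluid, b.fluid)


class TestConvergenceReport:
    def test_poiseuille_ladder_converges(self, poiseuille_ladder, newtonian):
        from hemoflow.waveforms import poiseuille_wss

        table = mesh_convergence_report(poiseuille_ladder, newtonian)
        assert list(table["cells"]) == sorted(table["cells"])
        # WSS_max approaches the analytic value: error strictly decreases
        errs = []
        for (mesh, state), wss_max in zip(poiseuille_ladder,
                                          table["wss_max"]):
            dy = mesh.y_faces[1] - mesh.y_faces[0]
            rc = (np.arange(mesh.shape[1]) + 0.5) * dy
            q = float(np.sum(state.u[0] * 2 * np.pi * rc * dy))
            exact = poiseuille_wss(q, mesh.y_faces[-1], newtonian.mu_inf)
            errs.append(abs(wss_max - exact) / exact)
        assert errs[0] > errs[1] > errs[2]
        assert errs[2] < 0.02

    def test_single_level_rejected(self, poiseuille_ladder):
        with pytest.raises(ValueError):
            mesh_convergence_report(poiseuille_ladder[:1])

    def test_duplicated_levels_zero_change(self, poiseuille_ladder, newtonian):
        pair = [poiseuille_ladder[0], poiseuille_ladder[0]]
        table = mesh_convergence_report(pair, newtonian)
        assert table["wss_max_rel_change"].iloc[1] == pytest.approx(0.0)

    def test_mismatched_specs_rejected(self, poiseuille_ladder, newtonian):
        from hemoflow.geometry import VesselSpec, build_vessel
        from hemoflow.solver import solve_steady

        other = build_vessel(VesselSpec(kind="straight", inlet_diameter=6.0,
                                        length=16.0), 8)
        state = solve_steady(other, 0.05, 0.0, newtonian)
        with pytest.raises(ValueError):
            mesh_convergence_report([poiseuille_ladder[0], (other, state)],
                                    newtonian)
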