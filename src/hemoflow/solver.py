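"""Transient incompressible generalized-Newtonian flow on structured grids.

Discretization: a staggered (MAC) finite-volume grid — axial velocity u on
x-normal faces, cross velocity v on y-normal faces, pressure at cell
centres — advanced with an incremental pressure-correction (projection)
scheme.  Momentum uses the Laplacian diffusion form div(mu(gamma) grad u),
explicit advection (upwind or central), and the Carreau–Yasuda viscosity
lagged one Picard iteration within each step.  The pressure-correction
Poisson system is prefactorized (sparse LU), so every step projects onto a
discretely divergence-free space to linear-solver precision: the net
boundary flux of a converged state vanishes to round-off.

Boundary conditions: prescribed inlet velocity profile (flat, parabolic,
or a user callable), no-slip rigid walls (including the dissected septum,
which is a band of blocked cells), symmetry on the axis of an
axisymmetric tube, and a prescribed-pressure outlet with zero tangential
stress.  Pressure is solved as a gauge relative to the outlet waveform
value; the absolute outlet pressure is added back when probing, which is
exact for rigid-wall incompressible flow.

Only rectilinear meshes (uniform axis-aligned grids: untapered straight
tube, dissected channel) are solvable; curved or tapered meshes from the
geometry module are for meshing/export tooling and are rejected here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple, Union

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import presets
from .geometry import BoundaryFace, StructuredMesh
from .indices import WSSSeries
from .rheology import RheologyParams, apparent_viscosity
from .waveforms import Waveform

__all__ = [
    "SolverConfig",
    "FlowState",
    "FlowSeries",
    "ConvergenceError",
    "StepSizeError",
    "solve_steady",
    "solve_transient",
    "wall_shear_stress",
    "wall_y_plus",
    "net_flux_imbalance",
    "as_series",
    "cell_speed",
]


class ConvergenceError(RuntimeError):
    """Raised when residuals fail to meet tolerance; carries the history."""

    def __init__(self, message: str, residual_history: Sequence[float]):
        super().__init__(message)
        self.residual_history = list(residual_history)


class StepSizeError(ValueError):
    """Raised on a CFL/diffusion stability violation; carries a suggestion."""

    def __init__(self, message: str, suggested_dt: float):
        super().__init__(message)
        self.suggested_dt = suggested_dt


@dataclass(frozen=True)
class SolverConfig:
    """Numerical parameters of the projection solver.

    ``time_step=None`` picks 40% of the explicit stability limit.
    ``advection_scheme`` is 'upwind' (robust, first order) or 'central'.
    ``inlet_profile`` is 'auto' (parabolic for tubes, flat for channels),
    'flat', 'parabolic', or a callable ``f(y_centres, t) -> u`` giving the
    inlet axial velocity directly.
    """

    time_step: Optional[float] = None
    cycles: int = 3
    residual_tolerance: float = presets.RESIDUAL_TOLERANCE
    max_inner_iterations: int = 3
    advection_scheme: str = "upwind"
    inlet_profile: Union[str, Callable] = "auto"
    n_record: int = 100
    max_steady_steps: Optional[int] = None

    def __post_init__(self) -> None:
        if self.time_step is not None and self.time_step <= 0:
            raise ValueError("time_step must be positive")
        if self.cycles < 1:
            raise ValueError("cycles must be >= 1")
        if self.residual_tolerance <= 0:
            raise ValueError("residual_tolerance must be positive")
        if self.max_inner_iterations < 1:
            raise ValueError("max_inner_iterations must be >= 1")
        if self.advection_scheme not in ("upwind", "central"):
            raise ValueError("advection_scheme must be 'upwind' or 'central'")


@dataclass
class FlowState:
    """Velocity/pressure fields at one instant (staggered layout)."""

    u: np.ndarray  # (ni+1, nj) axial velocity at x-faces, m/s
    v: np.ndarray  # (ni, nj+1) cross velocity at y-faces, m/s
    p: np.ndarray  # (ni, nj) gauge pressure at cell centres, Pa
    time: float = 0.0


@dataclass
class FlowSeries:
    """Uniformly sampled states covering exactly one cardiac cycle."""

    times: np.ndarray          # (nt,) open grid over [0, period)
    u: np.ndarray              # (nt, ni+1, nj)
    v: np.ndarray              # (nt, ni, nj+1)
    p: np.ndarray              # (nt, ni, nj) gauge pressure, Pa
    period: float
    outlet_pressure: np.ndarray  # (nt,) absolute outlet pressure, Pa
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_times(self) -> int:
        return self.times.size

    def state(self, k: int) -> FlowState:
        return FlowState(u=self.u[k], v=self.v[k], p=self.p[k],
                         time=float(self.times[k]))


def as_series(sol: Union[FlowState, FlowSeries]) -> FlowSeries:
    """View a single steady state as a two-sample constant series."""
    if isinstance(sol, FlowSeries):
        return sol
    return FlowSeries(
        times=np.array([0.0, 0.5]),
        u=np.stack([sol.u, sol.u]), v=np.stack([sol.v, sol.v]),
        p=np.stack([sol.p, sol.p]), period=1.0,
        outlet_pressure=np.zeros(2))


# ----------------------------------------------------------------------
# grid machinery


class _Grid:
    """Precomputed staggered-grid masks, metrics and the Poisson factor."""

    def __init__(self, mesh: StructuredMesh, rho: float,
                 dt: Optional[float] = None):
        if not mesh.is_rectilinear:
            raise ValueError(
                "flow solver supports rectilinear meshes only (untapered "
                "straight tube or dissected channel); tapered/arch meshes "
                "are mesh-and-export only")
        self.mesh = mesh
        self.axisym = mesh.axisymmetric
        ni, nj = mesh.shape
        self.ni, self.nj = ni, nj
        x = mesh.x_faces
        y = mesh.y_faces
        self.dx = float(x[1] - x[0])
        self.dy = float(y[1] - y[0])
        self.y0 = float(y[0])
        if self.axisym and abs(self.y0) > 1e-12:
            raise ValueError("axisymmetric mesh must start at r = 0")
        self.rho = rho
        self.dt = dt

        fl = mesh.fluid
        self.fluid = fl
        # radii (metres); unity weights in planar mode
        j = np.arange(nj)
        self.rc = (self.y0 + (j + 0.5) * self.dy) if self.axisym else np.ones(nj)
        self.rf = (self.y0 + np.arange(nj + 1) * self.dy) if self.axisym \
            else np.ones(nj + 1)

        # --- u-face masks (ni+1, nj)
        fal = np.zeros((1, nj), dtype=bool)
        self.fl_L = np.vstack([fal, fl])       # cell west of u face
        self.fl_R = np.vstack([fl, fal])       # cell east of u face
        self.u_exists = self.fl_L | self.fl_R
        self.u_interior = self.fl_L & self.fl_R
        self.u_outlet = np.zeros((ni + 1, nj), dtype=bool)
        self.u_outlet[ni] = fl[ni - 1]
        self.u_active = self.u_interior | self.u_outlet
        self.u_inlet = np.zeros((ni + 1, nj), dtype=bool)
        self.u_inlet[0] = fl[0] & mesh.inlet_open

        pad = np.zeros((ni + 1, 1), dtype=bool)
        above_fluid = np.hstack([(self.fl_L | self.fl_R)[:, 1:], pad])
        below_fluid = np.hstack([pad, (self.fl_L | self.fl_R)[:, :-1]])
        self.uN_wall = ~above_fluid
        self.uS_wall = ~below_fluid
        self.uS_axis = np.zeros((ni + 1, nj), dtype=bool)
        if self.axisym:
            self.uS_axis[:, 0] = True

        # --- v-face masks (ni, nj+1)
        fav = np.zeros((ni, 1), dtype=bool)
        self.fl_D = np.hstack([fav, fl])       # cell south of v face
        self.fl_U = np.hstack([fl, fav])       # cell north of v face
        self.v_active = self.fl_D & self.fl_U
        col = np.zeros((1, nj + 1), dtype=bool)
        east_fluid = np.vstack([(self.fl_D | self.fl_U)[1:], col])
        west_fluid = np.vstack([col, (self.fl_D | self.fl_U)[:-1]])
        self.vE_wall = ~east_fluid
        self.vE_wall[ni - 1] = False  # outlet plane: zero-gradient, not wall
        self.vW_wall = ~west_fluid
        self.vW_wall[0] = True        # inlet plane: no tangential slip

        if dt is not None:
            self._assemble_poisson()

    def set_dt(self, dt: float) -> None:
        self.dt = dt
        self._assemble_poisson()

    # Poisson operator for the pressure increment, SPD up to sign, with
    # homogeneous Neumann on prescribed-velocity faces and Dirichlet 0 on
    # the outlet faces (gauge pressure pinned there).
    def _assemble_poisson(self) -> None:
        ni, nj, dx, dy = self.ni, self.nj, self.dx, self.dy
        fl = self.fluid
        idx = -np.ones((ni, nj), dtype=int)
        ii, jj = np.nonzero(fl)
        idx[ii, jj] = np.arange(ii.size)
        self.cell_index = idx
        self.cells_i, self.cells_j = ii, jj
        n = ii.size
        a = self.dt / self.rho
        cx = a / dx**2
        rows, cols, vals = [], [], []
        diag = np.zeros(n)
        for di, dj, horizontal in ((1, 0, True), (-1, 0, True),
                                   (0, 1, False), (0, -1, False)):
            ni2, nj2 = ii + di, jj + dj
            inside = (ni2 >= 0) & (ni2 < ni) & (nj2 >= 0) & (nj2 < nj)
            if horizontal:
                coeff = np.full(ii.size, cx)
            else:
                rf = self.rf[jj + (1 if dj == 1 else 0)]
                coeff = a * rf / (self.rc[jj] * dy**2)
            neigh_fluid = np.zeros(ii.size, dtype=bool)
            neigh_fluid[inside] = fl[ni2[inside], nj2[inside]]
            k = np.nonzero(neigh_fluid)[0]
            rows.append(idx[ii[k], jj[k]])
            cols.append(idx[ni2[k], nj2[k]])
            vals.append(coeff[k])
            diag[idx[ii[k], jj[k]]] -= coeff[k]
            if di == 1:  # outlet Dirichlet on the east domain boundary
                out = ni2 == ni
                ko = np.nonzero(out)[0]
                diag[idx[ii[ko], jj[ko]]] -= 2.0 * coeff[ko]
        rows.append(np.arange(n))
        cols.append(np.arange(n))
        vals.append(diag)
        mat = sp.csc_matrix(
            (np.concatenate(vals),
             (np.concatenate(rows), np.concatenate(cols))), shape=(n, n))
        self._lu = spla.splu(mat)

    # --- helpers -------------------------------------------------------

    def zero_state(self) -> FlowState:
        return FlowState(u=np.zeros((self.ni + 1, self.nj)),
                         v=np.zeros((self.ni, self.nj + 1)),
                         p=np.zeros((self.ni, self.nj)))

    def u_neighbors(self, u: np.ndarray):
        """(uW, uE, uS, uN) ghost-closed neighbour values for u faces.

        Wall ghosts use the one-sided quadratic no-slip closure
        ghost = -2 u1 + u2/3 (u1, u2 the first two interior values), which
        makes the wall viscous flux mu*(ghost - u1)/dy equal the quadratic
        wall-gradient estimate (9 u1 - u2)/(3 dy) — exact for a parabolic
        profile and consistent with the WSS extraction.
        """
        uW = np.vstack([u[:1], u[:-1]])
        uE = np.vstack([u[1:], u[-1:]])          # zero-gradient at outlet
        zc = np.zeros((self.ni + 1, 1))
        u_up = np.hstack([u[:, 1:], zc])
        u_dn = np.hstack([zc, u[:, :-1]])
        degen = self.uN_wall & self.uS_wall       # single row between walls
        uN = np.where(self.uN_wall, -2.0 * u + u_dn / 3.0, u_up)
        uS = np.where(self.uS_axis, u,
                      np.where(self.uS_wall, -2.0 * u + u_up / 3.0, u_dn))
        uN = np.where(degen, -u, uN)
        uS = np.where(degen & ~self.uS_axis, -u, uS)
        return uW, uE, uS, uN

    def v_neighbors(self, v: np.ndarray):
        vW_in = np.vstack([v[:1], v[:-1]])
        vE_in = np.vstack([v[1:], v[-1:]])
        vE = np.where(self.vE_wall, -v, vE_in)
        vW = np.where(self.vW_wall, -v, vW_in)
        zr = np.zeros((self.ni, 1))
        vS = np.hstack([zr, v[:, :-1]])
        vN = np.hstack([v[:, 1:], zr])
        return vW, vE, vS, vN

    def v_at_u(self, v: np.ndarray) -> np.ndarray:
        vp = np.vstack([v[:1], v, v[-1:]])
        return 0.25 * (vp[:-1, :-1] + vp[:-1, 1:] + vp[1:, :-1] + vp[1:, 1:])

    def u_at_v(self, u: np.ndarray) -> np.ndarray:
        up = np.hstack([u[:, :1], u, u[:, -1:]])
        return 0.25 * (up[:-1, :-1] + up[:-1, 1:] + up[1:, :-1] + up[1:, 1:])

    def cell_velocity(self, u: np.ndarray, v: np.ndarray):
        uc = 0.5 * (u[:-1] + u[1:])
        vc = 0.5 * (v[:, :-1] + v[:, 1:])
        return uc, vc

    def shear_rate_cells(self, u: np.ndarray, v: np.ndarray) -> np.ndarray:
        """Shear-rate magnitude sqrt(2 D:D) at cell centres."""
        dx, dy = self.dx, self.dy
        uc, vc = self.cell_velocity(u, v)
        dudx = (u[1:] - u[:-1]) / dx
        dvdy = (v[:, 1:] - v[:, :-1]) / dy
        dudy = np.gradient(uc, dy, axis=1)
        dvdx = np.gradient(vc, dx, axis=0)
        gg = 2.0 * (dudx**2 + dvdy**2) + (dudy + dvdx)**2
        if self.axisym:
            gg = gg + 2.0 * (vc / self.rc[None, :])**2
        return np.sqrt(gg)

    def viscosity_fields(self, u, v, rheology: RheologyParams):
        """(cell, node) apparent-viscosity arrays."""
        if rheology.is_newtonian:
            mu_c = np.full((self.ni, self.nj), rheology.mu_inf)
        else:
            mu_c = apparent_viscosity(self.shear_rate_cells(u, v), rheology)
        mp = np.pad(mu_c, 1, mode="edge")
        mu_n = 0.25 * (mp[:-1, :-1] + mp[1:, :-1] + mp[:-1, 1:] + mp[1:, 1:])
        return mu_c, mu_n

    def divergence(self, u: np.ndarray, v: np.ndarray) -> np.ndarray:
        div = (u[1:] - u[:-1]) / self.dx
        div = div + (self.rf[None, 1:] * v[:, 1:]
                     - self.rf[None, :-1] * v[:, :-1]) / (self.rc[None, :] * self.dy)
        return np.where(self.fluid, div, 0.0)

    def stability_dt(self, u, v, mu_max: float) -> float:
        nu = mu_max / self.rho
        # 1/3 rather than 1/2: the quadratic wall ghost increases the
        # diffusion-operator diagonal by up to 1.5x at wall-adjacent rows
        dt_visc = (1.0 / 3.0) / (nu * (1.0 / self.dx**2 + 1.0 / self.dy**2))
        umax = max(float(np.max(np.abs(u))), 1e-12)
        vmax = max(float(np.max(np.abs(v))), 1e-12)
        dt_adv = min(self.dx / umax, self.dy / vmax)
        return min(dt_visc, dt_adv)


def _inlet_spans(mesh: StructuredMesh) -> List[Tuple[int, int]]:
    """Contiguous open-column spans [j0, j1) of the inlet face."""
    open_j = mesh.inlet_open & mesh.fluid[0]
    spans, start = [], None
    for j, is_open in enumerate(open_j):
        if is_open and start is None:
            start = j
        elif not is_open and start is not None:
            spans.append((start, j))
            start = None
    if start is not None:
        spans.append((start, open_j.size))
    if not spans:
        raise ValueError("mesh has no open inlet columns")
    return spans


def _inlet_values(grid: _Grid, profile, value: float, t: float) -> np.ndarray:
    """Axial inlet velocity per open j-column at time t."""
    mesh = grid.mesh
    nj = grid.nj
    yc = grid.y0 + (np.arange(nj) + 0.5) * grid.dy
    out = np.zeros(nj)
    if callable(profile):
        out[:] = profile(yc, t)
        out[~(mesh.inlet_open & mesh.fluid[0])] = 0.0
        return out
    if profile == "auto":
        profile = "parabolic" if grid.axisym else "flat"
    for j0, j1 in _inlet_spans(mesh):
        ys = yc[j0:j1]
        if profile == "flat":
            out[j0:j1] = value
        elif profile == "parabolic":
            if grid.axisym and j0 == 0:
                radius = grid.y0 + j1 * grid.dy
                out[j0:j1] = 2.0 * value * (1.0 - (ys / radius) ** 2)
            else:
                lo = grid.y0 + j0 * grid.dy
                hi = grid.y0 + j1 * grid.dy
                mid, half = 0.5 * (lo + hi), 0.5 * (hi - lo)
                out[j0:j1] = 1.5 * value * (1.0 - ((ys - mid) / half) ** 2)
        else:
            raise ValueError(f"unknown inlet profile {profile!r}")
    return out


def _advance(grid: _Grid, state: FlowState, dt: float, t_new: float,
             rheology: RheologyParams, config: SolverConfig,
             inlet_value: float) -> Tuple[FlowState, float]:
    """One projection step; returns (new state, Picard residual)."""
    rho = grid.rho
    dx, dy = grid.dx, grid.dy
    u0, v0, p = state.u, state.v, state.p
    uin = _inlet_values(grid, config.inlet_profile, inlet_value, t_new)

    u_iter, v_iter = u0, v0
    residual = np.inf
    n_inner = 1 if rheology.is_newtonian else config.max_inner_iterations
    for inner in range(n_inner):
        mu_c, mu_n = grid.viscosity_fields(u_iter, v_iter, rheology)

        # ---- u momentum
        uW, uE, uS, uN = grid.u_neighbors(u0)
        vau = grid.v_at_u(v0)
        if config.advection_scheme == "central":
            adv_u = u0 * (uE - uW) / (2 * dx) + vau * (uN - uS) / (2 * dy)
        else:
            adv_u = (u0 * np.where(u0 > 0, (u0 - uW) / dx, (uE - u0) / dx)
                     + vau * np.where(vau > 0, (u0 - uS) / dy, (uN - u0) / dy))
        mu_W = np.vstack([mu_c[:1], mu_c])
        mu_E = np.vstack([mu_c, mu_c[-1:]])
        flux_e = mu_E * (uE - u0) / dx
        flux_e[grid.ni] = 0.0                       # zero-stress outflow
        flux_w = mu_W * (u0 - uW) / dx
        diff_u = (flux_e - flux_w) / dx
        mu_s = mu_n[:, :-1]
        mu_nn = mu_n[:, 1:]
        if grid.axisym:
            rcu = grid.rc[None, :]
            diff_u = diff_u + (grid.rf[None, 1:] * mu_nn * (uN - u0)
                               - grid.rf[None, :-1] * mu_s * (u0 - uS)) \
                / (rcu * dy**2)
        else:
            diff_u = diff_u + (mu_nn * (uN - u0) - mu_s * (u0 - uS)) / dy**2
        dpdx = np.zeros_like(u0)
        dpdx[1:grid.ni] = (p[1:] - p[:-1]) / dx
        dpdx[grid.ni] = -2.0 * p[grid.ni - 1] / dx
        u_star = u0 + dt * (-adv_u + diff_u / rho - dpdx / rho)
        u_star[~grid.u_active] = 0.0
        u_star[grid.u_inlet] = np.broadcast_to(uin, u0.shape)[grid.u_inlet]

        # ---- v momentum
        vW, vE, vS, vN = grid.v_neighbors(v0)
        uav = grid.u_at_v(u0)
        if config.advection_scheme == "central":
            adv_v = uav * (vE - vW) / (2 * dx) + v0 * (vN - vS) / (2 * dy)
        else:
            adv_v = (uav * np.where(uav > 0, (v0 - vW) / dx, (vE - v0) / dx)
                     + v0 * np.where(v0 > 0, (v0 - vS) / dy, (vN - v0) / dy))
        mu_e = mu_n[1:, :]
        mu_w = mu_n[:-1, :]
        diff_v = (mu_e * (vE - v0) - mu_w * (v0 - vW)) / dx**2
        mu_S = np.hstack([mu_c[:, :1], mu_c])
        mu_N = np.hstack([mu_c, mu_c[:, -1:]])
        if grid.axisym:
            rfv = grid.rf[None, :]
            # v face j: north cell centre rc[j], south cell centre rc[j-1]
            rcS = np.concatenate([[grid.rc[0] - dy], grid.rc])[None, :]
            rcN = np.concatenate([grid.rc, [grid.rc[-1] + dy]])[None, :]
            # radial vector-Laplacian: (1/r) d/dr(r mu dv/dr) - mu v/r^2
            with np.errstate(divide="ignore", invalid="ignore"):
                hoop = np.where(rfv > 0,
                                0.5 * (mu_S + mu_N) * v0 / rfv**2, 0.0)
            rad = np.where(rfv > 0,
                           (rcN * mu_N * (vN - v0) - rcS * mu_S * (v0 - vS))
                           / (np.where(rfv > 0, rfv, 1.0) * dy**2), 0.0)
            diff_v = diff_v + rad - hoop
        else:
            diff_v = diff_v + (mu_N * (vN - v0) - mu_S * (v0 - vS)) / dy**2
        dpdy = np.zeros_like(v0)
        dpdy[:, 1:grid.nj] = (p[:, 1:] - p[:, :-1]) / dy
        v_star = v0 + dt * (-adv_v + diff_v / rho - dpdy / rho)
        v_star[~grid.v_active] = 0.0

        # ---- projection
        rhs = grid.divergence(u_star, v_star)[grid.cells_i, grid.cells_j]
        phi_flat = grid._lu.solve(rhs)
        phi = np.zeros((grid.ni, grid.nj))
        phi[grid.cells_i, grid.cells_j] = phi_flat
        a = dt / rho
        u_new = u_star.copy()
        gx = np.zeros_like(u_star)
        gx[1:grid.ni] = (phi[1:] - phi[:-1]) / dx
        gx[grid.ni] = -2.0 * phi[grid.ni - 1] / dx
        u_new[grid.u_active] -= a * gx[grid.u_active]
        v_new = v_star.copy()
        gy = np.zeros_like(v_star)
        gy[:, 1:grid.nj] = (phi[:, 1:] - phi[:, :-1]) / dy
        v_new[grid.v_active] -= a * gy[grid.v_active]

        uref = max(float(np.max(np.abs(u_new))), 1e-12)
        residual = max(float(np.max(np.abs(u_new - u_iter))),
                       float(np.max(np.abs(v_new - v_iter)))) / uref
        u_iter, v_iter = u_new, v_new
        if rheology.is_newtonian or residual < config.residual_tolerance:
            break

    p_new = p + phi
    return FlowState(u=u_iter, v=v_iter, p=p_new, time=t_new), residual


def _pick_dt(grid: _Grid, config: SolverConfig, u_scale: float,
             rheology: RheologyParams) -> float:
    mu_max = rheology.mu_zero if not rheology.is_newtonian else rheology.mu_inf
    nu = mu_max / grid.rho
    dt_visc = (1.0 / 3.0) / (nu * (1.0 / grid.dx**2 + 1.0 / grid.dy**2))
    dt_adv = min(grid.dx, grid.dy) / max(2.0 * abs(u_scale), 1e-9)
    limit = min(dt_visc, dt_adv)
    if config.time_step is None:
        return 0.4 * limit
    if config.time_step > limit:
        raise StepSizeError(
            f"time_step {config.time_step:g} exceeds the explicit stability "
            f"limit {limit:g} s; suggested dt = {0.4 * limit:g} s",
            suggested_dt=0.4 * limit)
    return config.time_step


def solve_steady(mesh: StructuredMesh, inlet_velocity: float,
                 outlet_pressure: float, rheology: RheologyParams,
                 config: Optional[SolverConfig] = None) -> FlowState:
    """Steady solution by pseudo-time marching to a residual-controlled stop.

    The scaled residual is the velocity change per step normalized by the
    viscous relaxation time of the cross-section; convergence requires it
    to fall below ``config.residual_tolerance``.  The returned state's
    pressure is gauge (outlet = 0); add ``outlet_pressure`` for absolute
    values.
    """
    config = config or SolverConfig()
    grid = _Grid(mesh, rheology.density)
    dt = _pick_dt(grid, config, inlet_velocity, rheology)
    grid.set_dt(dt)
    height = grid.dy * grid.nj
    tau = rheology.density * height**2 / rheology.mu_inf
    state = grid.zero_state()
    max_steps = config.max_steady_steps or int(np.ceil(30.0 * tau / dt))
    history: List[float] = []
    uref = max(abs(inlet_velocity), 1e-12)
    for n in range(max_steps):
        new, _ = _advance(grid, state, dt, (n + 1) * dt, rheology, config,
                          inlet_velocity)
        res = float(np.max(np.abs(new.u - state.u))) / uref * (tau / dt)
        history.append(res)
        state = new
        if inlet_velocity == 0.0 and res == 0.0:
            break
        if n > 10 and res < config.residual_tolerance:
            break
    else:
        raise ConvergenceError(
            f"steady solve did not reach residual "
            f"{config.residual_tolerance:g} in {max_steps} steps "
            f"(last {history[-1]:.3g})", history)
    state.time = 0.0
    return state


def solve_transient(mesh: StructuredMesh,
                    inlet_waveform: Optional[Waveform],
                    outlet_waveform: Optional[Waveform],
                    rheology: RheologyParams,
                    config: Optional[SolverConfig] = None) -> FlowSeries:
    """Pulsatile solve: washout cycles, then one recorded cardiac cycle.

    The inlet waveform (m/s, mean velocity scaled by the inlet profile) is
    applied for ``config.cycles`` cycles; the final cycle is recorded on a
    uniform grid of ``config.n_record`` samples.  The outlet waveform
    (mmHg or Pa) sets the absolute outlet pressure trace stored alongside
    the gauge fields.  Cycle-to-cycle drift of the velocity field between
    the last two cycles is reported in ``diagnostics['cycle_drift']``.
    """
    config = config or SolverConfig()
    if inlet_waveform is None:
        if not callable(config.inlet_profile):
            raise ValueError("inlet_waveform may be omitted only with a "
                             "callable inlet_profile")
        period = presets.CARDIAC_PERIOD
        # estimate the velocity scale by sampling the callable profile
        _g = _Grid(mesh, rheology.density)
        _yc = _g.y0 + (np.arange(_g.nj) + 0.5) * _g.dy
        u_scale = max(float(np.max(np.abs(config.inlet_profile(_yc, t))))
                      for t in np.linspace(0.0, period, 21)) / 2.0
    else:
        if inlet_waveform.unit != "m/s":
            raise ValueError("inlet waveform must be in m/s")
        period = inlet_waveform.period
        u_scale = float(np.max(np.abs(inlet_waveform.values)))
    if outlet_waveform is not None and not np.isclose(
            outlet_waveform.period, period):
        raise ValueError("inlet/outlet waveform periods differ")

    grid = _Grid(mesh, rheology.density)
    dt0 = _pick_dt(grid, config, u_scale, rheology)
    steps_per_cycle = int(np.ceil(period / dt0))
    # snap so that a cycle is a whole number of steps and the recording
    # stride divides it
    stride = max(1, steps_per_cycle // config.n_record)
    n_rec = int(np.ceil(steps_per_cycle / stride))
    steps_per_cycle = n_rec * stride
    dt = period / steps_per_cycle
    grid.set_dt(dt)

    def inlet_value(t: float) -> float:
        if inlet_waveform is None:
            return 1.0
        return float(inlet_waveform.sample_at(t))

    state = grid.zero_state()
    residuals: List[float] = []
    prev_cycle_u: Optional[np.ndarray] = None
    drift = np.nan
    rec_t = np.empty(n_rec)
    rec_u = np.empty((n_rec, grid.ni + 1, grid.nj))
    rec_v = np.empty((n_rec, grid.ni, grid.nj + 1))
    rec_p = np.empty((n_rec, grid.ni, grid.nj))

    for cycle in range(config.cycles):
        cycle_u_sum = np.zeros_like(state.u)
        for s in range(steps_per_cycle):
            t_new = cycle * period + (s + 1) * dt
            limit = grid.stability_dt(
                state.u, state.v,
                rheology.mu_zero if not rheology.is_newtonian
                else rheology.mu_inf)
            if dt > limit:
                raise StepSizeError(
                    f"dt {dt:g} s violates stability at t = {t_new:g} s; "
                    f"suggested dt = {0.4 * limit:g} s", 0.4 * limit)
            state, res = _advance(grid, state, dt, t_new, rheology, config,
                                  inlet_value(t_new))
            residuals.append(res)
            cycle_u_sum += state.u
            if cycle == config.cycles - 1 and (s % stride) == stride - 1:
                k = s // stride
                # sample k corresponds to phase (s+1)*dt; shift so the
                # recorded grid is the open grid k*stride*dt
                rec_t[k] = ((s + 1) * dt) % period
                rec_u[k], rec_v[k], rec_p[k] = state.u, state.v, state.p
        cycle_mean = cycle_u_sum / steps_per_cycle
        if prev_cycle_u is not None:
            scale = max(float(np.max(np.abs(cycle_mean))), 1e-12)
            drift = float(np.max(np.abs(cycle_mean - prev_cycle_u))) / scale
        prev_cycle_u = cycle_mean

    # roll so times start at the beginning of the cycle (sample at t=dt*stride
    # ... period wraps to 0)
    order = np.argsort(rec_t)
    times = rec_t[order]
    rec_u, rec_v, rec_p = rec_u[order], rec_v[order], rec_p[order]

    if outlet_waveform is None:
        pout = np.zeros(n_rec)
    else:
        vals = outlet_waveform.sample_at(times)
        pout = (vals * presets.MMHG_TO_PA
                if outlet_waveform.unit == "mmHg" else vals)
    return FlowSeries(times=times, u=rec_u, v=rec_v, p=rec_p, period=period,
                      outlet_pressure=pout,
                      diagnostics={"cycle_drift": drift,
                                   "residuals": residuals,
                                   "dt": dt,
                                   "steps_per_cycle": steps_per_cycle})


# ----------------------------------------------------------------------
# wall quantities


def _wall_faces(mesh: StructuredMesh) -> List[BoundaryFace]:
    return [f for f in mesh.boundary_faces() if f.tag in ("wall", "septum")]


def wall_shear_stress(series: Union[FlowState, FlowSeries],
                      mesh: StructuredMesh,
                      rheology: RheologyParams) -> WSSSeries:
    """Wall shear stress vectors along the wall polylines over the cycle.

    Per wall face the tangential velocity gradient normal to the wall is
    evaluated with a one-sided quadratic fit through the first two
    interior cell values (exact for a parabolic profile), multiplied by
    the Carreau–Yasuda viscosity at the wall shear rate.  The WSS vector
    points along the wall tangent (+x for horizontal walls, +y for
    vertical); its sign encodes the instantaneous flow direction.
    """
    series = as_series(series)
    faces = _wall_faces(mesh)
    if not faces:
        raise ValueError("mesh has no wall-tagged boundary faces")
    grid_dx = float(mesh.x_faces[1] - mesh.x_faces[0])
    grid_dy = float(mesh.y_faces[1] - mesh.y_faces[0])
    ni, nj = mesh.shape
    nt = series.n_times
    npts = len(faces)
    vectors = np.zeros((npts, nt, 2))
    arc = np.zeros(npts)
    positions = np.zeros((npts, 2))
    xc = 0.5 * (mesh.x_faces[:-1] + mesh.x_faces[1:])
    yc = 0.5 * (mesh.y_faces[:-1] + mesh.y_faces[1:])

    for k in range(nt):
        u, v = series.u[k], series.v[k]
        uc = 0.5 * (u[:-1] + u[1:])      # (ni, nj) cell-centre axial vel
        vc = 0.5 * (v[:, :-1] + v[:, 1:])
        for m, f in enumerate(faces):
            i, j = f.i, f.j
            if f.side in ("N", "S"):
                # horizontal wall, tangential velocity = u
                j2 = j - 1 if f.side == "N" else j + 1
                u1 = uc[i, j]
                u2 = uc[i, j2] if 0 <= j2 < nj and mesh.fluid[i, j2] else -u1
                a = (9.0 * u1 - u2) / (3.0 * grid_dy)
                if k == 0:
                    arc[m] = xc[i]
                    positions[m] = (xc[i], mesh.y_faces[j + 1]
                                    if f.side == "N" else mesh.y_faces[j])
                mu = apparent_viscosity(abs(a), rheology)
                vectors[m, k] = (mu * a, 0.0)
            else:
                # vertical wall, tangential velocity = v
                i2 = i + 1 if f.side == "W" else i - 1
                v1 = vc[i, j]
                v2 = vc[i2, j] if 0 <= i2 < ni and mesh.fluid[i2, j] else -v1
                a = (9.0 * v1 - v2) / (3.0 * grid_dx)
                if k == 0:
                    arc[m] = yc[j]
                    positions[m] = (mesh.x_faces[f.i]
                                    if f.side == "W" else mesh.x_faces[f.i + 1],
                                    yc[j])
                mu = apparent_viscosity(abs(a), rheology)
                vectors[m, k] = (0.0, mu * a)
    if nt < 2:
        vectors = np.repeat(vectors, 2, axis=1)
    return WSSSeries(arc_length=arc, vectors=vectors,
                     period=series.period, positions=positions)


def wall_y_plus(state: Union[FlowState, FlowSeries], mesh: StructuredMesh,
                rheology: RheologyParams) -> np.ndarray:
    """Dimensionless first-node wall distance y+ = y u_tau / nu per wall point.

    y is the first cell-centre distance from the wall (half a cell),
    u_tau = sqrt(|tau_w| / rho), and nu the apparent kinematic viscosity
    at the wall shear rate.  Point order matches
    :func:`wall_shear_stress`.
    """
    wss = wall_shear_stress(state, mesh, rheology)
    tau = np.linalg.norm(wss.vectors, axis=-1)[:, 0]
    faces = _wall_faces(mesh)
    dx = float(mesh.x_faces[1] - mesh.x_faces[0])
    dy = float(mesh.y_faces[1] - mesh.y_faces[0])
    dist = np.array([0.5 * (dy if f.side in ("N", "S") else dx)
                     for f in faces])
    if np.any(dist <= 0):
        raise ValueError("degenerate wall spacing")
    u_tau = np.sqrt(tau / rheology.density)
    gamma = tau / apparent_viscosity(0.0, rheology)  # first estimate
    mu = apparent_viscosity(gamma, rheology)
    nu = mu / rheology.density
    return dist * u_tau / nu


def net_flux_imbalance(sol: Union[FlowState, FlowSeries],
                       mesh: StructuredMesh,
                       rho: float = presets.BLOOD_DENSITY) -> float:
    """Worst relative net boundary flux over the series.

    The discrete divergence telescopes to the boundary flux, so this
    equals the largest cell-divergence sum normalized by the peak inlet
    flux; a converged projection state gives round-off-level values.
    """
    series = as_series(sol)
    grid = _Grid(mesh, rho)
    net = []
    influx = []
    w = grid.rc * grid.dy
    for k in range(series.n_times):
        div = grid.divergence(series.u[k], series.v[k])
        vol = grid.rc[None, :] * grid.dx * grid.dy
        net.append(abs(float(np.sum(div * vol))))
        influx.append(abs(float(np.sum(series.u[k][0] * w))))
    scale = max(max(influx), 1e-300)
    return max(net) / scale


def cell_speed(series: Union[FlowState, FlowSeries],
               mesh: StructuredMesh) -> np.ndarray:
    """(nt, ni, nj) velocity magnitude at cell centres."""
    s = as_series(series)
    uc = 0.5 * (s.u[:, :-1] + s.u[:, 1:])
    vc = 0.5 * (s.v[:, :, :-1] + s.v[:, :, 1:])
    return np.sqrt(uc**2 + vc**2)
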