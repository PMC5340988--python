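"""Sagittal-plane incompressible flow solver on a moving boundary-fitted grid.

The 3-D lumen is reduced to the 2-D sagittal plane: the fluid domain is the
strip between the anterior and posterior wall polylines.  The solver is a
finite-volume fractional-step (projection) scheme on a structured grid whose
columns are vertical (x uniform) and whose rows follow the walls; wall motion
displaces nodes vertically only.  The momentum equation is written in ALE
form -- advection uses the fluid flux minus the mesh flux, with mesh fluxes
computed from swept volumes so the discrete geometric conservation law holds
exactly and a uniform free stream is preserved on a moving grid.

Discretization: explicit hybrid central/upwind advection, explicit
over-relaxed central diffusion, exact discrete projection (deferred
non-orthogonal correction iterated to a divergence tolerance), prescribed
parabolic inlet velocity, prescribed outlet pressure, no-slip moving walls.
Rigid-wall operation is the study's CFD technique.

Units are SI (m, s, Pa); wall profiles from the geometry module arrive in mm
and are converted by the scenario layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .errors import GridError, LookupError_, SolverDivergenceError, StabilityError
from .waveforms import FluidProperties

_DIV_TOL = 1e-9      # relative divergence target of the projection
_MAX_PROJ_ITERS = 60
_MAX_SUBSTEPS = 16


# --------------------------------------------------------------------------
# Grid


class FluidGrid:
    """Structured boundary-fitted grid between two wall polylines.

    Node columns are vertical; ``zn[i, j]`` interpolates linearly between the
    posterior wall (j = 0) and the anterior wall (j = nz).  All lengths in
    metres.
    """

    def __init__(self, x: np.ndarray, z_anterior: np.ndarray, z_posterior: np.ndarray,
                 nx: int, nz: int):
        x = np.asarray(x, dtype=float)
        za = np.asarray(z_anterior, dtype=float)
        zp = np.asarray(z_posterior, dtype=float)
        if np.any(za - zp <= 0):
            raise GridError("wall polylines cross: anterior must stay above posterior")
        self.nx, self.nz = int(nx), int(nz)
        self.xn = np.linspace(x[0], x[-1], nx + 1)
        self.eta = np.linspace(0.0, 1.0, nz + 1)
        self._za_nodes = np.interp(self.xn, x, za)
        self._zp_nodes = np.interp(self.xn, x, zp)
        self.zn = self._zp_nodes[:, None] + self.eta[None, :] * (
            self._za_nodes - self._zp_nodes)[:, None]
        self.dx = float(self.xn[1] - self.xn[0])
        self._check_quality()

    def set_walls(self, z_anterior_nodes: np.ndarray, z_posterior_nodes: np.ndarray) -> None:
        """Move the walls (values at the grid's node columns) and regrid the
        interior by the same linear blend."""
        if np.any(z_anterior_nodes - z_posterior_nodes <= 0):
            raise GridError("wall motion tangles the grid")
        self._za_nodes = np.asarray(z_anterior_nodes, dtype=float).copy()
        self._zp_nodes = np.asarray(z_posterior_nodes, dtype=float).copy()
        self.zn = self._zp_nodes[:, None] + self.eta[None, :] * (
            self._za_nodes - self._zp_nodes)[:, None]
        self._check_quality()

    def _check_quality(self) -> None:
        if np.any(np.diff(self.zn, axis=1) <= 0):
            raise GridError("grid tangled: non-positive cell heights")

    # -- derived geometry ---------------------------------------------------

    @property
    def cell_volumes(self) -> np.ndarray:
        """Cell areas (unit depth), shape (nx, nz)."""
        dz = np.diff(self.zn, axis=1)  # (nx+1, nz) column heights
        return 0.5 * self.dx * (dz[:-1, :] + dz[1:, :])

    @property
    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        xc = 0.5 * (self.xn[:-1] + self.xn[1:])
        zc = 0.25 * (self.zn[:-1, :-1] + self.zn[1:, :-1] + self.zn[:-1, 1:] + self.zn[1:, 1:])
        return np.broadcast_to(xc[:, None], zc.shape).copy(), zc

    @property
    def iface_area(self) -> np.ndarray:
        """Vertical (x-normal) face areas, shape (nx+1, nz)."""
        return np.diff(self.zn, axis=1)

    @property
    def jface_S(self) -> tuple[np.ndarray, np.ndarray]:
        """Eta-face area vectors (Sx, Sz), each (nx, nz+1), oriented +eta."""
        dze = np.diff(self.zn, axis=0)  # (nx, nz+1)
        Sx = -dze
        Sz = np.full_like(dze, self.dx)
        return Sx, Sz

    def quality(self) -> float:
        """Minimum-to-maximum corner Jacobian ratio over all cells (1 for
        rectangles; <= 0 means tangled)."""
        dz = np.diff(self.zn, axis=1)
        jac = np.stack([dz[:-1, :], dz[1:, :]]) * self.dx
        return float(jac.min() / jac.max())


def make_grid(profile_anterior: np.ndarray, profile_posterior: np.ndarray,
              nx: int, nz: int, units_mm: bool = True) -> FluidGrid:
    """Grid the sagittal fluid domain between two (x, z) polylines.

    Polylines are (N, 2) arrays as produced by :func:`geometry.sagittal_profile`
    (mm by default; converted to metres).
    """
    ant = np.asarray(profile_anterior, dtype=float)
    post = np.asarray(profile_posterior, dtype=float)
    scale = 1e-3 if units_mm else 1.0
    if not np.allclose(ant[:, 0], post[:, 0]):
        raise GridError("profiles must share axial stations")
    return FluidGrid(ant[:, 0] * scale, ant[:, 1] * scale, post[:, 1] * scale, nx, nz)


# --------------------------------------------------------------------------
# State


@dataclass
class FluidState:
    """Velocity (cell centers), pressure (cells) and face fluxes at time t."""

    u: np.ndarray        # (nx, nz, 2)
    p: np.ndarray        # (nx, nz), Pa
    Ui: np.ndarray       # (nx+1, nz) x-face volume fluxes
    Uj: np.ndarray       # (nx, nz+1) eta-face volume fluxes
    t: float
    zn: np.ndarray       # grid nodes at this time (nx+1, nz+1)
    div_max: float = 0.0

    def copy(self) -> "FluidState":
        return FluidState(self.u.copy(), self.p.copy(), self.Ui.copy(),
                          self.Uj.copy(), self.t, self.zn.copy(), self.div_max)


# --------------------------------------------------------------------------
# Solver


class FluidSolver:
    """Projection solver bound to a grid, fluid properties and boundary data.

    ``inlet_velocity(t)`` gives the mean inlet velocity (parabolic profile is
    imposed); ``outlet_pressure(t)`` the outlet pressure level.
    """

    def __init__(self, grid: FluidGrid, props: FluidProperties,
                 inlet_velocity, outlet_pressure,
                 inlet_profile: str = "parabolic", inlet_uz=None):
        self.grid = grid
        self.props = props
        self.nu = props.viscosity / props.density
        self.inlet_velocity = inlet_velocity
        self.outlet_pressure = outlet_pressure
        self.inlet_uz = inlet_uz  # optional vertical inlet velocity (ALE tests)
        if inlet_profile not in ("parabolic", "flat"):
            raise GridError(f"unknown inlet profile {inlet_profile!r}")
        self.inlet_profile = inlet_profile
        self.t = 0.0
        nx, nz = grid.nx, grid.nz
        self.u = np.zeros((nx, nz, 2))
        self.p = np.zeros((nx, nz))
        self.Ui = np.zeros((nx + 1, nz))
        self.Uj = np.zeros((nx, nz + 1))
        self.div_max = 0.0
        self._assemble_poisson()
        self._init_fluxes()

    # -- helpers ------------------------------------------------------------

    def _inlet_shape(self) -> np.ndarray:
        """Profile shape at inlet face centers (unit mean)."""
        etac = 0.5 * (self.grid.eta[:-1] + self.grid.eta[1:])
        if self.inlet_profile == "flat":
            return np.ones_like(etac)
        xi = 2.0 * etac - 1.0
        return 1.5 * (1.0 - xi * xi)

    def _inlet_value(self, comp: int, t: float) -> np.ndarray:
        if comp == 0:
            return float(self.inlet_velocity(t)) * self._inlet_shape()
        if self.inlet_uz is None:
            return np.zeros(self.grid.nz)
        return np.full(self.grid.nz, float(self.inlet_uz(t)))

    def _init_fluxes(self) -> None:
        """Start from the inlet profile advected uniformly (divergence-free
        after an initial projection)."""
        self._project(dt=1.0)

    def _assemble_poisson(self) -> None:
        """Two-point part of div(grad phi) with outlet Dirichlet; LU factors."""
        g = self.grid
        nx, nz = g.nx, g.nz
        xc, zc = g.cell_centers
        Ai = g.iface_area
        Sjx, Sjz = g.jface_S
        idx = np.arange(nx * nz).reshape(nx, nz)

        rows, cols, vals = [], [], []
        diag = np.zeros(nx * nz)

        # interior x-faces (i = 1..nx-1)
        a = Ai[1:-1, :] / g.dx  # (nx-1, nz)
        P, N = idx[:-1, :], idx[1:, :]
        for r, c, v in ((P, N, a), (N, P, a)):
            rows.append(r.ravel()); cols.append(c.ravel()); vals.append(v.ravel())
        np.add.at(diag, P.ravel(), -a.ravel())
        np.add.at(diag, N.ravel(), -a.ravel())

        # interior eta-faces (j = 1..nz-1)
        dzc = zc[:, 1:] - zc[:, :-1]  # (nx, nz-1)
        S2 = Sjx[:, 1:-1] ** 2 + Sjz[:, 1:-1] ** 2
        aj = S2 / (Sjz[:, 1:-1] * dzc)
        P, N = idx[:, :-1], idx[:, 1:]
        for r, c, v in ((P, N, aj), (N, P, aj)):
            rows.append(r.ravel()); cols.append(c.ravel()); vals.append(v.ravel())
        np.add.at(diag, P.ravel(), -aj.ravel())
        np.add.at(diag, N.ravel(), -aj.ravel())

        # outlet faces: Dirichlet phi at face centre, distance dx/2
        a_out = Ai[-1, :] / (0.5 * g.dx)
        np.add.at(diag, idx[-1, :], -a_out)
        self._a_out = a_out

        rows.append(np.arange(nx * nz)); cols.append(np.arange(nx * nz)); vals.append(diag)
        A = sp.csc_matrix((np.concatenate(vals),
                           (np.concatenate(rows), np.concatenate(cols))),
                          shape=(nx * nz, nx * nz))
        self._poisson_lu = splu(A)
        # cached geometry for corrections
        self._dzc_i = zc[1:, :] - zc[:-1, :]          # center z-offset across x-faces
        self._dzc_j = zc[:, 1:] - zc[:, :-1]

    # -- gradient machinery --------------------------------------------------

    def _cell_gradient(self, phi: np.ndarray, outlet_value: np.ndarray | None = None
                       ) -> np.ndarray:
        """Green-Gauss gradient, shape (nx, nz, 2).  Boundary face values:
        zero-gradient everywhere except an optional outlet Dirichlet level."""
        g = self.grid
        Ai = g.iface_area
        Sjx, Sjz = g.jface_S
        fi = np.empty((g.nx + 1, g.nz))
        fi[1:-1] = 0.5 * (phi[:-1] + phi[1:])
        fi[0] = phi[0]
        fi[-1] = phi[-1] if outlet_value is None else outlet_value
        fj = np.empty((g.nx, g.nz + 1))
        fj[:, 1:-1] = 0.5 * (phi[:, :-1] + phi[:, 1:])
        fj[:, 0] = phi[:, 0]
        fj[:, -1] = phi[:, -1]
        V = g.cell_volumes
        gx = (fi[1:] * Ai[1:] - fi[:-1] * Ai[:-1]
              + fj[:, 1:] * Sjx[:, 1:] - fj[:, :-1] * Sjx[:, :-1]) / V
        gz = (fj[:, 1:] * Sjz[:, 1:] - fj[:, :-1] * Sjz[:, :-1]) / V
        return np.stack([gx, gz], axis=-1)

    def _divergence(self, Ui: np.ndarray, Uj: np.ndarray) -> np.ndarray:
        return (Ui[1:] - Ui[:-1]) + (Uj[:, 1:] - Uj[:, :-1])

    # -- projection -----------------------------------------------------------

    def _project(self, dt: float) -> None:
        """Project current cell velocities onto a divergence-free flux field
        honouring the instantaneous boundary conditions; sets p = rho*phi/dt."""
        g = self.grid
        nx, nz = g.nx, g.nz
        Ai = g.iface_area
        Sjx, Sjz = g.jface_S
        t_new = self.t

        # provisional face fluxes from interpolated velocities
        Ui = np.empty((nx + 1, nz))
        ui = 0.5 * (self.u[:-1, :, 0] + self.u[1:, :, 0])
        Ui[1:-1] = ui * Ai[1:-1]
        vin = float(self.inlet_velocity(t_new))
        Ui[0] = vin * self._inlet_shape() * Ai[0]
        Ui[-1] = self.u[-1, :, 0] * Ai[-1]
        Uj = np.empty((nx, nz + 1))
        uxf = 0.5 * (self.u[:, :-1, :] + self.u[:, 1:, :])
        Uj[:, 1:-1] = uxf[..., 0] * Sjx[:, 1:-1] + uxf[..., 1] * Sjz[:, 1:-1]
        Uj[:, 0] = self._wall_flux_bottom
        Uj[:, -1] = self._wall_flux_top

        p_out = float(self.outlet_pressure(t_new))
        phi_out = np.full(nz, dt / self.props.density * p_out)

        scale = max(np.abs(Ui).max(), np.abs(Uj).max(), 1e-30)
        phi = np.full((nx, nz), phi_out[0])

        def phi_fluxes(phi):
            dUi = np.zeros_like(Ui)
            dUj = np.zeros_like(Uj)
            corr_i = np.zeros_like(Ui)
            corr_j = np.zeros_like(Uj)
            dUi[1:-1] = (phi[1:] - phi[:-1]) * (Ai[1:-1] / g.dx)
            dUi[-1] = (phi_out - phi[-1]) * self._a_out
            dUj[:, 1:-1] = (phi[:, 1:] - phi[:, :-1]) * (
                (Sjx[:, 1:-1] ** 2 + Sjz[:, 1:-1] ** 2) / (Sjz[:, 1:-1] * self._dzc_j))
            gphi = self._cell_gradient(phi, outlet_value=phi_out)
            gz_f = 0.5 * (gphi[:-1, :, 1] + gphi[1:, :, 1])
            corr_i[1:-1] = gz_f * (-Ai[1:-1] * self._dzc_i / g.dx)
            gf = 0.5 * (gphi[:, :-1, :] + gphi[:, 1:, :])
            kx = Sjx[:, 1:-1]
            kz = -(Sjx[:, 1:-1] ** 2) / Sjz[:, 1:-1]
            corr_j[:, 1:-1] = gf[..., 0] * kx + gf[..., 1] * kz
            return dUi, dUj, corr_i, corr_j

        best = np.inf
        stagnant = 0
        for it in range(_MAX_PROJ_ITERS):
            dUi, dUj, corr_i, corr_j = phi_fluxes(phi)
            div = self._divergence(Ui - dUi - corr_i, Uj - dUj - corr_j)
            dmax = np.abs(div).max()
            if dmax <= _DIV_TOL * scale:
                break
            # deferred corrections converge linearly; a residual no longer
            # improving on the best seen means the round-off floor of the
            # flux arithmetic has been reached
            stagnant = stagnant + 1 if dmax > 0.9 * best else 0
            best = min(best, dmax)
            if stagnant >= 2:
                break
            phi += self._poisson_lu.solve(div.ravel()).reshape(nx, nz)
        else:
            raise SolverDivergenceError("projection failed to reach divergence tolerance")

        self.Ui = Ui - dUi - corr_i
        self.Uj = Uj - dUj - corr_j
        self.div_max = float(np.abs(self._divergence(self.Ui, self.Uj)).max() / scale)
        self.p = self.props.density / dt * phi
        # velocity correction from the cell-centred phi gradient
        gphi = self._cell_gradient(phi, outlet_value=phi_out)
        self.u = self.u - gphi

    # wall fluxes (set per step from wall motion; zero when rigid)
    _wall_flux_bottom = 0.0
    _wall_flux_top = 0.0

    # -- time stepping --------------------------------------------------------

    def step(self, dt: float,
             za_target: np.ndarray | None = None,
             zp_target: np.ndarray | None = None) -> FluidState:
        """Advance one time step; optionally move the walls to target node
        positions (reached at the end of the step).  Substeps automatically
        if the CFL limit would be exceeded."""
        umax = float(np.abs(self.u).max())
        dz_min = float(np.diff(self.grid.zn, axis=1).min())
        h = min(self.grid.dx, dz_min)
        cfl = umax * dt / h
        visc = 2.0 * self.nu * dt * (1.0 / self.grid.dx ** 2 + 1.0 / dz_min ** 2)
        n_sub = max(1, int(np.ceil(max(cfl / 0.9, visc / 0.9))))
        if n_sub > _MAX_SUBSTEPS:
            raise StabilityError(
                f"time step dt={dt} needs {n_sub} substeps (CFL={cfl:.2f}); reduce dt")

        za0, zp0 = self.grid._za_nodes.copy(), self.grid._zp_nodes.copy()
        for k in range(1, n_sub + 1):
            if za_target is not None:
                frac = k / n_sub
                za_k = za0 + frac * (za_target - za0)
                zp_k = zp0 + frac * (zp_target - zp0)
            else:
                za_k = zp_k = None
            self._substep(dt / n_sub, za_k, zp_k)
        if not np.isfinite(self.u).all():
            raise SolverDivergenceError("velocity field became non-finite")
        return self.state()

    def _substep(self, dt: float, za_new, zp_new) -> None:
        g = self.grid
        nx, nz = g.nx, g.nz
        V_old = g.cell_volumes
        zn_old = g.zn.copy()

        # mesh fluxes (swept volumes / dt) through eta-faces; x-faces sweep none
        if za_new is not None:
            g.set_walls(za_new, zp_new)
            self._assemble_poisson()
            zdot = (g.zn - zn_old) / dt  # (nx+1, nz+1)
            Wj = 0.5 * self.grid.dx * (zdot[:-1, :] + zdot[1:, :])  # (nx, nz+1)
        else:
            Wj = np.zeros((nx, nz + 1))
        self._wall_flux_bottom = Wj[:, 0]
        self._wall_flux_top = Wj[:, -1]

        # ALE advecting fluxes: previous solenoidal fluid fluxes minus mesh flux
        Urel_i = self.Ui
        Urel_j = self.Uj - Wj

        Ai = g.iface_area
        Sjx, Sjz = g.jface_S
        rhs = np.zeros_like(self.u)

        # ---- advection (hybrid central/upwind by face Peclet)
        D_i = self.nu * Ai / g.dx
        D_j = self.nu * (Sjx ** 2 + Sjz ** 2)
        D_j[:, 1:-1] /= (Sjz[:, 1:-1] * self._dzc_j)
        for comp in range(2):
            q = self.u[..., comp]
            # x-faces
            Fi = np.zeros((nx + 1, nz))
            central = 0.5 * (q[:-1] + q[1:])
            upw = np.where(Urel_i[1:-1] >= 0, q[:-1], q[1:])
            use_up = np.abs(Urel_i[1:-1]) > 2.0 * D_i[1:-1]
            qi = np.where(use_up, upw, central)
            Fi[1:-1] = qi * Urel_i[1:-1]
            q_in = self._inlet_value(comp, self.t)
            Fi[0] = q_in * Urel_i[0]
            Fi[-1] = q[-1] * Urel_i[-1]  # outflow upwinded
            # eta-faces
            Fj = np.zeros((nx, nz + 1))
            centralj = 0.5 * (q[:, :-1] + q[:, 1:])
            upwj = np.where(Urel_j[:, 1:-1] >= 0, q[:, :-1], q[:, 1:])
            use_upj = np.abs(Urel_j[:, 1:-1]) > 2.0 * D_j[:, 1:-1]
            qj = np.where(use_upj, upwj, centralj)
            Fj[:, 1:-1] = qj * Urel_j[:, 1:-1]
            # walls: relative flux is zero by construction (no-slip, impermeable)
            rhs[..., comp] -= (Fi[1:] - Fi[:-1]) + (Fj[:, 1:] - Fj[:, :-1])

        # ---- diffusion (over-relaxed central, explicit)
        grad = [self._cell_gradient(self.u[..., c]) for c in range(2)]
        wall_u_bot, wall_u_top = self._wall_velocities(Wj)
        for comp in range(2):
            q = self.u[..., comp]
            gq = grad[comp]
            Fd_i = np.zeros((nx + 1, nz))
            Fd_i[1:-1] = D_i[1:-1] * (q[1:] - q[:-1])
            gz_f = 0.5 * (gq[:-1, :, 1] + gq[1:, :, 1])
            Fd_i[1:-1] += self.nu * gz_f * (-Ai[1:-1] * self._dzc_i / g.dx)
            # inlet Dirichlet (distance dx/2)
            q_in = self._inlet_value(comp, self.t)
            Fd_i[0] = self.nu * Ai[0] / (0.5 * g.dx) * (q[0] - q_in)
            Fd_i[-1] = 0.0  # outlet: zero normal gradient
            Fd_j = np.zeros((nx, nz + 1))
            Fd_j[:, 1:-1] = D_j[:, 1:-1] * (q[:, 1:] - q[:, :-1])
            gf = 0.5 * (gq[:, :-1, :] + gq[:, 1:, :])
            kx = Sjx[:, 1:-1]
            kz = -(Sjx[:, 1:-1] ** 2) / Sjz[:, 1:-1]
            Fd_j[:, 1:-1] += self.nu * (gf[..., 0] * kx + gf[..., 1] * kz)
            # walls: Dirichlet via second-order one-sided normal gradient
            # (exact for a parabolic profile, so plane Poiseuille is a steady
            # state of the discretization)
            _, zc = g.cell_centers
            zfb = 0.5 * (g.zn[:-1, 0] + g.zn[1:, 0])
            zft = 0.5 * (g.zn[:-1, -1] + g.zn[1:, -1])
            qwb = wall_u_bot[..., comp]
            qwt = wall_u_top[..., comp]
            d1, d2 = zc[:, 0] - zfb, zc[:, 1] - zfb
            dqdz_b = (d2 ** 2 * (q[:, 0] - qwb) - d1 ** 2 * (q[:, 1] - qwb)) / (
                d1 * d2 * (d2 - d1))
            Fd_j[:, 0] = self.nu * (Sjx[:, 0] ** 2 + Sjz[:, 0] ** 2) / Sjz[:, 0] * dqdz_b
            d1, d2 = zft - zc[:, -1], zft - zc[:, -2]
            dqds_t = (d2 ** 2 * (q[:, -1] - qwt) - d1 ** 2 * (q[:, -2] - qwt)) / (
                d1 * d2 * (d2 - d1))
            Fd_j[:, -1] = -self.nu * (Sjx[:, -1] ** 2 + Sjz[:, -1] ** 2) / Sjz[:, -1] * dqds_t
            rhs[..., comp] += (Fd_i[1:] - Fd_i[:-1]) + (Fd_j[:, 1:] - Fd_j[:, :-1])

        V_new = self.grid.cell_volumes
        self.u = (V_old[..., None] * self.u + dt * rhs) / V_new[..., None]
        self.t += dt
        self._project(dt)

    def _wall_velocities(self, Wj: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """No-slip wall velocities (vertical motion only), (nx, 2) each."""
        g = self.grid
        wb = np.zeros((g.nx, 2))
        wt = np.zeros((g.nx, 2))
        wb[:, 1] = Wj[:, 0] / g.dx
        wt[:, 1] = Wj[:, -1] / g.dx
        return wb, wt

    def state(self) -> FluidState:
        return FluidState(self.u.copy(), self.p.copy(), self.Ui.copy(), self.Uj.copy(),
                          self.t, self.grid.zn.copy(), self.div_max)

    def load_state(self, s: FluidState) -> None:
        """Restore a saved state (used by the FSI subiteration loop)."""
        self.u = s.u.copy()
        self.p = s.p.copy()
        self.Ui = s.Ui.copy()
        self.Uj = s.Uj.copy()
        self.t = s.t
        za = s.zn[:, -1].copy()
        zp = s.zn[:, 0].copy()
        if not (np.array_equal(za, self.grid._za_nodes)
                and np.array_equal(zp, self.grid._zp_nodes)):
            self.grid.set_walls(za, zp)
            self._assemble_poisson()


# --------------------------------------------------------------------------
# Wall diagnostics


def wall_shear_stress(state: FluidState, grid: FluidGrid, mu: float,
                      wall_velocity_bottom: np.ndarray | None = None,
                      wall_velocity_top: np.ndarray | None = None
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Signed WSS (Pa) per axial station on (posterior, anterior) walls.

    One-sided second-order normal derivative of the wall-tangential velocity
    through the wall value and the two adjacent cell rows; positive for
    forward (+x) flow.
    """
    nx = grid.nx
    zc = 0.25 * (state.zn[:-1, :-1] + state.zn[1:, :-1]
                 + state.zn[:-1, 1:] + state.zn[1:, 1:])
    out = []
    for side in (0, 1):
        j0, j1 = (0, 1) if side == 0 else (-1, -2)
        zw = 0.5 * (state.zn[:-1, 0 if side == 0 else -1]
                    + state.zn[1:, 0 if side == 0 else -1])
        dzw = np.diff(state.zn[:, 0 if side == 0 else -1])
        tx = grid.dx / np.hypot(grid.dx, dzw)
        tz = dzw / np.hypot(grid.dx, dzw)
        wvel = np.zeros((nx, 2))
        if side == 0 and wall_velocity_bottom is not None:
            wvel = wall_velocity_bottom
        if side == 1 and wall_velocity_top is not None:
            wvel = wall_velocity_top
        ut1 = (state.u[:, j0, 0] - wvel[:, 0]) * tx + (state.u[:, j0, 1] - wvel[:, 1]) * tz
        ut2 = (state.u[:, j1, 0] - wvel[:, 0]) * tx + (state.u[:, j1, 1] - wvel[:, 1]) * tz
        d1 = np.abs((zc[:, j0] - zw)) * tx  # normal distance = dz * cos(slope)
        d2 = np.abs((zc[:, j1] - zw)) * tx
        dudn = (d2 ** 2 * ut1 - d1 ** 2 * ut2) / (d1 * d2 * (d2 - d1))
        out.append(mu * dudn)
    return out[0], out[1]


def wall_pressure(state: FluidState, grid: FluidGrid) -> tuple[np.ndarray, np.ndarray]:
    """Pressure (Pa) on wall-adjacent cells per station: (posterior, anterior)."""
    return state.p[:, 0].copy(), state.p[:, -1].copy()


@dataclass(frozen=True)
class RecirculationRegion:
    """Contiguous reversed-flow region on one wall."""

    wall: str        # 'anterior' | 'posterior'
    x_start: float   # m
    x_end: float     # m
    strength: float  # Pa*m, integral of |negative WSS| over the run


def detect_recirculation(state: FluidState, grid: FluidGrid, mu: float,
                         min_length: float = 5e-3) -> list[RecirculationRegion]:
    """Reversed-flow (negative-WSS) regions longer than ``min_length`` (m)."""
    wss_p, wss_a = wall_shear_stress(state, grid, mu)
    xc, _ = grid.cell_centers
    x = xc[:, 0]
    regions = []
    for name, wss in (("posterior", wss_p), ("anterior", wss_a)):
        neg = wss < 0
        i = 0
        while i < len(neg):
            if neg[i]:
                k = i
                while k + 1 < len(neg) and neg[k + 1]:
                    k += 1
                extent = x[k] - x[i] + grid.dx
                if extent >= min_length:
                    strength = float(np.sum(-wss[i:k + 1]) * grid.dx)
                    regions.append(RecirculationRegion(name, float(x[i]), float(x[k]),
                                                       strength))
                i = k + 1
            else:
                i += 1
    return regions


# --------------------------------------------------------------------------
# Histories


@dataclass
class FlowHistory:
    """Wall-traction time series plus full snapshots at selected times."""

    x_stations: np.ndarray                  # (nx,) cell-column x, m
    times: list = field(default_factory=list)
    wss_posterior: list = field(default_factory=list)
    wss_anterior: list = field(default_factory=list)
    p_posterior: list = field(default_factory=list)
    p_anterior: list = field(default_factory=list)
    p_inlet: list = field(default_factory=list)
    p_outlet: list = field(default_factory=list)
    snapshots: dict = field(default_factory=dict)   # t -> FluidState
    meta: dict = field(default_factory=dict)

    def record(self, state: FluidState, grid: FluidGrid, mu: float,
               keep_snapshot: bool = False) -> None:
        wss_p, wss_a = wall_shear_stress(state, grid, mu)
        pw_p, pw_a = wall_pressure(state, grid)
        self.times.append(state.t)
        self.wss_posterior.append(wss_p)
        self.wss_anterior.append(wss_a)
        self.p_posterior.append(pw_p)
        self.p_anterior.append(pw_a)
        self.p_inlet.append(float(np.mean(state.p[0, :])))
        self.p_outlet.append(float(np.mean(state.p[-1, :])))
        if keep_snapshot:
            self.snapshots[round(state.t, 9)] = state.copy()

    def nearest_time_index(self, t: float, tol: float | None = None) -> int:
        times = np.asarray(self.times)
        i = int(np.argmin(np.abs(times - t)))
        if tol is not None and abs(times[i] - t) > tol:
            raise LookupError_(f"no record within {tol} s of t={t}")
        return i

    def finalize(self) -> None:
        self.times = np.asarray(self.times)
        self.wss_posterior = np.asarray(self.wss_posterior)
        self.wss_anterior = np.asarray(self.wss_anterior)
        self.p_posterior = np.asarray(self.p_posterior)
        self.p_anterior = np.asarray(self.p_anterior)
        self.p_inlet = np.asarray(self.p_inlet)
        self.p_outlet = np.asarray(self.p_outlet)
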