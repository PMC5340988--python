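"""Partitioned staggered fluid-structure coupling and the run drivers.

One exchange window (default 5 ms) follows the serial staggered sequence:
(1) advance the fluid over the window (five 1 ms steps), (2) pass the
time-averaged wall pressures to the solid as external loads, (3) solve the
quasi-static wall for one solid step, (4) pass the wall displacements back
to the fluid as the new boundary position and grid velocity.  The window is
subiterated with under-relaxation on the interface displacement until the
displacement update falls below tolerance, so each accepted exchange is a
converged two-way step.

``run_cfd`` is the same time loop with a rigid wall; ``css`` runs live in
:mod:`aaafsi.wall`.  ``run`` dispatches on the scenario mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import fluid as fl
from . import wall as wl
from .errors import CouplingError, InterfaceError
from .scenario import CouplingConfig, Scenario, resample_geometry

MM = 1e-3


# --------------------------------------------------------------------------
# Exchange operators


def exchange_pressure(p_posterior: np.ndarray, p_anterior: np.ndarray,
                      n_stations: int) -> tuple[np.ndarray, np.ndarray]:
    """Fluid wall pressures -> solid loads, station to station (conforming
    grids; a count mismatch is an interface error).  The transfer is the
    identity, so the interface force integral is conserved exactly."""
    p_p = np.asarray(p_posterior, dtype=float)
    p_a = np.asarray(p_anterior, dtype=float)
    if len(p_p) != n_stations or len(p_a) != n_stations:
        raise InterfaceError(
            f"station mismatch: fluid has {len(p_p)}, solid expects {n_stations}")
    return p_a.copy(), p_p.copy()


def exchange_displacement(disp_anterior_mm: np.ndarray, disp_posterior_mm: np.ndarray,
                          x_stations_m: np.ndarray, x_nodes_m: np.ndarray,
                          za_ref_nodes_m: np.ndarray, zp_ref_nodes_m: np.ndarray,
                          dt_exchange: float
                          ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Wall displacements -> fluid boundary node positions and velocities.

    Displacements (mm, outward per side, zero at the tethered ends) are
    interpolated from the solid stations (fluid cell columns) to the grid
    nodes; the grid velocity is the node displacement increment over the
    exchange interval.
    """
    da = np.interp(x_nodes_m, x_stations_m, np.asarray(disp_anterior_mm) * MM)
    dp = np.interp(x_nodes_m, x_stations_m, np.asarray(disp_posterior_mm) * MM)
    za_new = za_ref_nodes_m + da
    zp_new = zp_ref_nodes_m - dp
    vz_a = da / dt_exchange
    vz_p = -dp / dt_exchange
    return za_new, zp_new, vz_a, vz_p


# --------------------------------------------------------------------------
# Results container


@dataclass
class RunResult:
    """Output of one run: flow and/or wall histories plus provenance."""

    mode: str
    fingerprint: str
    material: str
    flow: fl.FlowHistory | None = None
    wall: wl.WallHistory | None = None
    subiteration_counts: list = field(default_factory=list)
    residual_traces: list = field(default_factory=list)


# --------------------------------------------------------------------------
# Drivers


def _setup(scenario: Scenario):
    from . import geometry as geo

    geom = scenario.build_geometry()
    ant, post = geo.sagittal_profile(geom)
    grid = fl.make_grid(ant, post, scenario.nx, scenario.nz)
    props = scenario.build_props()
    vin = scenario.build_inlet_velocity()
    pout = scenario.build_outlet_pressure()
    solver = fl.FluidSolver(grid, props, vin, pout)
    xc = grid.cell_centers[0][:, 0]
    wall_geom = resample_geometry(geom, xc / MM)
    return geom, grid, props, vin, pout, solver, wall_geom


def run_cfd(scenario: Scenario) -> RunResult:
    """Rigid-wall (CFD) run over the scenario's cardiac cycles."""
    scenario = scenario.with_(mode="cfd")
    _, grid, props, _, _, solver, _ = _setup(scenario)
    hist = fl.FlowHistory(x_stations=grid.cell_centers[0][:, 0],
                          meta={"mode": "cfd"})
    dt = scenario.coupling.dt_fluid
    n_steps = int(round(scenario.t_end / dt))
    save_every = max(1, int(round(scenario.save_interval / dt)))
    snaps = {round(t, 9) for t in scenario.absolute_snapshot_times}
    for k in range(1, n_steps + 1):
        st = solver.step(dt)
        if k % save_every == 0:
            hist.record(st, grid, props.viscosity,
                        keep_snapshot=round(st.t, 9) in snaps)
    hist.finalize()
    return RunResult(mode="cfd", fingerprint=scenario.fingerprint(),
                     material=scenario.material, flow=hist)


def run_css(scenario: Scenario) -> RunResult:
    """Wall-only (CSS) run: uniform outlet-pressure loading.

    The wall model is evaluated on the fluid grid's cell columns so CSS and
    FSI histories share their stations.
    """
    scenario = scenario.with_(mode="css")
    _, _, _, _, pout, _, wall_geom = _setup(scenario)
    material = scenario.build_material()
    hist = wl.css_run(wall_geom, pout, material=material, t_end=scenario.t_end,
                      dt=scenario.coupling.dt_solid, thickness=scenario.thickness,
                      influence_mm=scenario.influence_mm)
    return RunResult(mode="css", fingerprint=scenario.fingerprint(),
                     material=scenario.material, wall=hist)


def fsi_run(scenario: Scenario, config: CouplingConfig | None = None) -> RunResult:
    """Two-way staggered FSI run."""
    scenario = scenario.with_(mode="fsi")
    cfg = config or scenario.coupling
    _, grid, props, _, pout, solver, wall_geom = _setup(scenario)
    material = scenario.build_material()
    wall_model = wl.WallModel(wall_geom, material, scenario.thickness,
                              scenario.influence_mm)
    nx = grid.nx
    x_stations = grid.cell_centers[0][:, 0]
    x_nodes = grid.xn
    za_ref = grid._za_nodes.copy()
    zp_ref = grid._zp_nodes.copy()

    flow_hist = fl.FlowHistory(x_stations=x_stations, meta={"mode": "fsi"})
    wall_times = []
    wall_snaps = []
    sub_counts = []
    res_traces = []

    n_sub_steps = int(round(cfg.exchange / cfg.dt_fluid))
    n_windows = int(round(scenario.t_end / cfg.exchange))
    save_every = max(1, int(round(scenario.save_interval / cfg.dt_fluid)))
    snaps = {round(t, 9) for t in scenario.absolute_snapshot_times}

    # pre-inflate to the static diastolic state so the first exchange window
    # does not carry an artificial pressurization transient
    p0 = float(pout(0.0))
    snap0 = wall_model.respond(np.full(nx, p0))
    d_a = snap0.disp_anterior.copy()  # accepted interface displacement, mm
    d_p = snap0.disp_posterior.copy()
    za0, zp0, _, _ = exchange_displacement(d_a, d_p, x_stations, x_nodes,
                                           za_ref, zp_ref, cfg.exchange)
    solver.grid.set_walls(za0, zp0)
    solver._assemble_poisson()
    solver._init_fluxes()
    wall_times.append(0.0)
    wall_snaps.append(snap0)

    for w in range(n_windows):
        t0 = w * cfg.exchange
        state0 = solver.state()
        za_start = solver.grid._za_nodes.copy()
        zp_start = solver.grid._zp_nodes.copy()
        d_a_k, d_p_k = d_a.copy(), d_p.copy()
        trace = []
        for it in range(1, cfg.max_subiters + 1):
            solver.load_state(state0)
            za_t, zp_t, _, _ = exchange_displacement(
                d_a_k, d_p_k, x_stations, x_nodes, za_ref, zp_ref, cfg.exchange)
            p_acc_bot = np.zeros(nx)
            p_acc_top = np.zeros(nx)
            records = []
            for s in range(1, n_sub_steps + 1):
                frac = s / n_sub_steps
                za_s = za_start + frac * (za_t - za_start)
                zp_s = zp_start + frac * (zp_t - zp_start)
                st = solver.step(cfg.dt_fluid, za_target=za_s, zp_target=zp_s)
                pw_p, pw_a = fl.wall_pressure(st, solver.grid)
                p_acc_bot += pw_p
                p_acc_top += pw_a
                global_step = w * n_sub_steps + s
                if global_step % save_every == 0:
                    records.append(st.copy())
            p_bot = p_acc_bot / n_sub_steps
            p_top = p_acc_top / n_sub_steps
            if scenario.uniform_pressure:
                p_load_a = p_load_p = np.full(nx, float(pout(t0 + cfg.exchange)))
            else:
                p_load_a, p_load_p = exchange_pressure(p_bot, p_top, nx)
            snap = wall_model.respond(p_load_a, p_load_p)
            r = float(max(np.abs(snap.disp_anterior - d_a_k).max(),
                          np.abs(snap.disp_posterior - d_p_k).max()))
            trace.append(r)
            if r < cfg.tol_mm:
                break
            d_a_k = d_a_k + cfg.omega * (snap.disp_anterior - d_a_k)
            d_p_k = d_p_k + cfg.omega * (snap.disp_posterior - d_p_k)
        else:
            raise CouplingError(
                f"FSI subiteration did not converge in window {w} "
                f"(last residual {trace[-1]:.3g} mm)", residual_trace=trace)

        d_a, d_p = d_a_k, d_p_k
        sub_counts.append(it)
        res_traces.append(trace)
        for st in records:
            flow_hist.record(st, solver.grid, props.viscosity,
                             keep_snapshot=round(st.t, 9) in snaps)
        wall_times.append(t0 + cfg.exchange)
        wall_snaps.append(snap)

    flow_hist.finalize()
    wall_hist = wl.WallHistory(times=np.asarray(wall_times), x=wall_model.x,
                               ap_semi0=wall_model.b0, snapshots=wall_snaps)
    return RunResult(mode="fsi", fingerprint=scenario.fingerprint(),
                     material=scenario.material, flow=flow_hist, wall=wall_hist,
                     subiteration_counts=sub_counts, residual_traces=res_traces)


def run(scenario: Scenario) -> RunResult:
    """Dispatch on the scenario's mode."""
    return {"fsi": fsi_run, "cfd": run_cfd, "css": run_css}[scenario.mode](scenario)
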