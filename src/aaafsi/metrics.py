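"""Cross-mode comparison metrics and the study report.

Computes the quantities the three modeling techniques are compared on:
axial wall-shear-stress profiles at the four snapshot times, maximum-diameter
and centre-drift histories, peak von Mises history, the inlet-outlet pressure
drop, the proximal-neck WSS ratio between the rigid-wall (CFD) and compliant
(FSI) runs, and the recirculation inventory.  ``compare_models`` assembles a
single report with a pass/fail table of the study's directional findings.

"Average WSS" at a station is the mean of the two wall-side values (the 2-D
sagittal reduction has no circumferential direction to average over).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

from . import fluid as fl
from .coupling import RunResult
from .errors import ComparisonError, LookupError_
from .wall import WallHistory

#: Proximal-neck axial window, fractions of the vessel length.  The window
#: starts past the inlet-adjacent margin -- both techniques share the
#: prescribed inflow there, so wall shear in that segment is equal by
#: construction -- and extends over the neck-to-sac junction where the
#: proximal vortices sit.
NECK_WINDOW = (0.05, 0.30)
#: |WSS| floor (Pa) below which ratios are reported as undefined.
WSS_NOISE_FLOOR = 1e-4


def axial_wss_profile(history: fl.FlowHistory, t: float,
                      tol: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """(x, mean WSS) profile at the stored time nearest ``t``."""
    i = history.nearest_time_index(t, tol=tol)
    prof = 0.5 * (history.wss_anterior[i] + history.wss_posterior[i])
    return history.x_stations, prof


def pressure_drop(history: fl.FlowHistory, t: float,
                  tol: float | None = None) -> tuple[float, float]:
    """Inlet-minus-outlet mean pressure (Pa) at time ``t`` and its fraction
    of the instantaneous outlet pressure."""
    i = history.nearest_time_index(t, tol=tol)
    drop = float(history.p_inlet[i] - history.p_outlet[i])
    return drop, drop / float(history.p_outlet[i])


def neck_wss_ratio(cfd: fl.FlowHistory, fsi: fl.FlowHistory, t: float,
                   window: tuple[float, float] = NECK_WINDOW,
                   noise_floor: float = WSS_NOISE_FLOOR) -> float:
    """CFD-over-FSI overestimation factor of |WSS| in the proximal-neck
    window at time ``t``.

    The factor is the median of the station-wise ratios
    |WSS_cfd(x)| / |WSS_fsi(x)| over the window, i.e. the representative
    pointwise overestimation of the rigid-wall model in that region.
    Stations whose FSI |WSS| falls below the noise floor are excluded; if
    none remain the ratio is NaN (undefined-ratio flag).
    """
    if len(cfd.x_stations) != len(fsi.x_stations):
        raise ComparisonError("histories do not share a station grid")
    nsta = len(cfd.x_stations)
    lo = max(0, int(window[0] * nsta))
    hi = max(lo + 1, int(window[1] * nsta))

    def wss(h):
        i = h.nearest_time_index(t)
        return 0.5 * (np.abs(h.wss_anterior[i]) + np.abs(h.wss_posterior[i]))[lo:hi]

    wc, wf = wss(cfd), wss(fsi)
    ok = wf >= noise_floor
    if not np.any(ok):
        return float("nan")
    return float(np.median(wc[ok] / wf[ok]))


def max_diameter_history(wall: WallHistory) -> tuple[np.ndarray, np.ndarray]:
    """(t, max inner diameter in mm) series."""
    return wall.max_diameter_history()


def _snapshot_grid(flow: fl.FlowHistory, state: fl.FluidState) -> fl.FluidGrid:
    """Minimal FluidGrid rebuilt from a stored snapshot's node positions."""
    zn = state.zn
    g = fl.FluidGrid.__new__(fl.FluidGrid)
    g.nx, g.nz = zn.shape[0] - 1, zn.shape[1] - 1
    g.zn = zn
    g.dx = float(flow.x_stations[1] - flow.x_stations[0])
    x0 = float(flow.x_stations[0]) - 0.5 * g.dx
    g.xn = x0 + g.dx * np.arange(g.nx + 1)
    g.eta = np.linspace(0.0, 1.0, g.nz + 1)
    g._za_nodes = zn[:, -1]
    g._zp_nodes = zn[:, 0]
    return g


def _nearest_snapshot(flow: fl.FlowHistory, t: float, tol: float = 0.5):
    if not flow.snapshots:
        raise LookupError_("flow history holds no snapshots")
    key = min(flow.snapshots, key=lambda k: abs(k - t))
    if abs(key - t) > tol:
        raise LookupError_(f"no snapshot near t={t}")
    return flow.snapshots[key]


def recirculation_inventory(result: RunResult, mu: float,
                            min_length: float = 5e-3) -> dict:
    """Recirculation regions per stored snapshot time."""
    out = {}
    for t, st in sorted(result.flow.snapshots.items()):
        grid = _snapshot_grid(result.flow, st)
        out[t] = fl.detect_recirculation(st, grid, mu, min_length)
    return out


def recirculation_strength(result: RunResult, t: float, mu: float,
                           min_length: float = 5e-3) -> float:
    """Total reversed-flow strength (Pa*m) at the snapshot nearest ``t``."""
    st = _nearest_snapshot(result.flow, t)
    grid = _snapshot_grid(result.flow, st)
    regions = fl.detect_recirculation(st, grid, mu, min_length)
    return float(sum(r.strength for r in regions))


def css_fsi_peak_stress_gap(fsi: RunResult, css: RunResult) -> float:
    """|peak von Mises (CSS) - peak von Mises (FSI)| (MPa), peaks over the
    respective histories."""
    _, vf = fsi.wall.peak_von_mises_history()
    _, vc = css.wall.peak_von_mises_history()
    return abs(float(np.max(vc)) - float(np.max(vf)))


@dataclass
class ComparisonReport:
    """All cross-mode metrics plus the directional-findings table."""

    snapshot_times: tuple
    wss_profiles: dict          # (mode, t_rel) -> np.ndarray
    x_stations: np.ndarray
    max_diameter: dict          # mode -> (t, series) in mm
    center_drift: dict          # mode -> (t, series) in mm
    peak_von_mises: dict        # mode -> (t, series) in MPa
    pressure_drop_pa: float
    pressure_drop_fraction: float
    neck_wss_ratio: dict        # t_rel -> ratio
    recirc_strength: dict       # t_rel -> Pa*m (FSI run)
    findings: dict              # name -> bool
    meta: dict = field(default_factory=dict)

    def summary_text(self) -> str:
        """Deterministic key-value summary (fixed float formatting)."""
        buf = io.StringIO()
        w = lambda k, v: buf.write(f"{k} = {v}\n")
        fmt = lambda v: f"{v:.6g}"
        modes = sorted({m for m, _ in self.wss_profiles} | set(self.max_diameter))
        w("report.modes", ",".join(modes))
        w("pressure_drop.pa", fmt(self.pressure_drop_pa))
        w("pressure_drop.fraction_of_outlet", fmt(self.pressure_drop_fraction))
        for t in sorted(self.neck_wss_ratio):
            w(f"neck_wss_ratio.cfd_over_fsi.t{t:.2f}", fmt(self.neck_wss_ratio[t]))
        for t in sorted(self.recirc_strength):
            w(f"recirculation_strength.t{t:.2f}", fmt(self.recirc_strength[t]))
        for mode in sorted(self.max_diameter):
            tt, dd = self.max_diameter[mode]
            w(f"max_diameter.{mode}.peak_mm", fmt(float(np.max(dd))))
            w(f"max_diameter.{mode}.peak_time_s", fmt(float(tt[np.argmax(dd)])))
        for mode in sorted(self.peak_von_mises):
            _, vv = self.peak_von_mises[mode]
            w(f"peak_von_mises.{mode}.mpa", fmt(float(np.max(vv))))
        for name in sorted(self.findings):
            w(f"finding.{name}", "pass" if self.findings[name] else "fail")
        return buf.getvalue()

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.summary_text())

    def write_csv(self, directory) -> None:
        """One CSV per metric family under ``directory``."""
        import os

        import pandas as pd

        os.makedirs(directory, exist_ok=True)
        prof = pd.DataFrame({"x_m": self.x_stations})
        for (mode, t), p in sorted(self.wss_profiles.items()):
            prof[f"wss_{mode}_t{t:.2f}"] = p
        prof.to_csv(os.path.join(directory, "wss_profiles.csv"), index=False)
        for name, series in (("max_diameter_mm", self.max_diameter),
                             ("center_drift_mm", self.center_drift),
                             ("peak_von_mises_mpa", self.peak_von_mises)):
            frames = {}
            for mode, (tt, vv) in series.items():
                frames[f"t_{mode}"] = pd.Series(tt)
                frames[mode] = pd.Series(vv)
            pd.DataFrame(frames).to_csv(os.path.join(directory, f"{name}.csv"), index=False)


def compare_models(fsi: RunResult, cfd: RunResult, css: RunResult,
                   fsi_iso: RunResult | None = None,
                   mu: float = 0.0035, period: float = 1.0, cycles: int = 3,
                   snapshot_times: tuple = (0.2, 0.3, 0.45, 0.5),
                   diameter_closeness_mm: float = 0.5) -> ComparisonReport:
    """Assemble the cross-technique comparison report.

    All runs must share the study conditions (checked via the scenario
    fingerprint).  ``fsi_iso`` enables the material-comparison findings.
    """
    for r in (cfd, css) + ((fsi_iso,) if fsi_iso is not None else ()):
        if r.fingerprint != fsi.fingerprint:
            raise ComparisonError("runs were produced under different scenarios")

    t0 = (cycles - 1) * period
    abs_times = [t0 + t for t in snapshot_times]

    wss_profiles = {}
    for t_rel, t_abs in zip(snapshot_times, abs_times):
        for mode, r in (("fsi", fsi), ("cfd", cfd)):
            _, prof = axial_wss_profile(r.flow, t_abs)
            wss_profiles[(mode, t_rel)] = prof

    drop, frac = pressure_drop(fsi.flow, t0 + 0.4)

    ratios = {t_rel: neck_wss_ratio(cfd.flow, fsi.flow, t_abs)
              for t_rel, t_abs in zip(snapshot_times, abs_times)}
    strengths = {t_rel: recirculation_strength(fsi, t_abs, mu)
                 for t_rel, t_abs in zip(snapshot_times, abs_times)}

    max_d = {"fsi": fsi.wall.max_diameter_history(),
             "css": css.wall.max_diameter_history()}
    drift = {"fsi": (fsi.wall.times, fsi.wall.center_offset_at_max()),
             "css": (css.wall.times, css.wall.center_offset_at_max())}
    vm = {"fsi": fsi.wall.peak_von_mises_history(),
          "css": css.wall.peak_von_mises_history()}
    if fsi_iso is not None:
        max_d["fsi_iso"] = fsi_iso.wall.max_diameter_history()
        drift["fsi_iso"] = (fsi_iso.wall.times, fsi_iso.wall.center_offset_at_max())
        vm["fsi_iso"] = fsi_iso.wall.peak_von_mises_history()

    findings = {}
    findings["vortex_growth_in_deceleration"] = bool(strengths[0.45] > strengths[0.3])
    r45 = ratios[0.45]
    findings["cfd_overestimates_neck_wss"] = bool(np.isfinite(r45) and r45 >= 1.0)
    tf, df = max_d["fsi"]
    tc, dc = max_d["css"]
    dc_i = np.interp(tf, tc, dc)
    rms = float(np.sqrt(np.mean((df - dc_i) ** 2)))
    findings["fsi_css_diameters_coincide"] = bool(rms < diameter_closeness_mm)
    if fsi_iso is not None:
        findings["isotropic_larger_diameter"] = bool(
            np.max(max_d["fsi_iso"][1]) > np.max(max_d["fsi"][1]))
        findings["isotropic_smaller_von_mises"] = bool(
            np.max(vm["fsi_iso"][1]) < np.max(vm["fsi"][1]))

    return ComparisonReport(
        snapshot_times=snapshot_times,
        wss_profiles=wss_profiles,
        x_stations=fsi.flow.x_stations,
        max_diameter=max_d,
        center_drift=drift,
        peak_von_mises=vm,
        pressure_drop_pa=drop,
        pressure_drop_fraction=frac,
        neck_wss_ratio=ratios,
        recirc_strength=strengths,
        findings=findings,
        meta={"fingerprint": fsi.fingerprint,
              "fsi_css_diameter_rms_mm": rms},
    )
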