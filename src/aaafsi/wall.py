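"""Reduced-order structural model of the AAA wall.

Each axial station is an incompressible hyperelastic membrane ring (thin-wall
Laplace equilibrium) with the axial stretch fixed at 1 (tethered artery, both
ends fully constrained) so incompressibility gives the current thickness
h = h0 / lam_theta.  Equilibrium at a station of reference radius r0:

    sigma_theta(lam) * h0 / (lam^2 * r0) = p_transmural.

Anterior and posterior wall sides are solved separately: each side's
effective pressure is corrected by the axial-curvature membrane support
p_eff = p - sigma_z * h * kappa_z (two-curvature Laplace), which is what
turns the anterior/posterior asymmetry of the reference shape into a drift
of the cross-section centre.  A smooth tethering projection enforces the
both-ends-fixed boundary condition on the displacement profiles.

Driving every station with the (spatially uniform) outlet-pressure waveform
is the CSS modeling technique; the FSI mode drives the same model with the
station-wise fluid wall pressures instead.

Units: geometry in mm, pressures in Pa, stresses returned in MPa.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import constitutive as co
from .errors import EquilibriumError
from .geometry import AAAGeometry

MM = 1e-3  # mm -> m


def von_mises(sig_theta, sig_z):
    """Plane-stress membrane von Mises equivalent stress (same units as input)."""
    st = np.asarray(sig_theta, dtype=float)
    sz = np.asarray(sig_z, dtype=float)
    out = np.sqrt(st * st - st * sz + sz * sz)
    return out if np.ndim(out) else float(out)


def _membrane_stress_clipped(model, lam, lam_z=1.0):
    """Closed-form membrane stresses with the fiber exponential clipped (not
    raised) so the root bracketing may probe arbitrarily large stretches."""
    lt = np.asarray(lam, dtype=float)
    lr2 = 1.0 / (lt * lam_z) ** 2
    lt2 = lt * lt
    lz2 = lam_z * lam_z
    if isinstance(model, co.IsotropicModel):
        I1 = lt2 + lz2 + lr2
        W1 = model.c10_kpa + 2.0 * model.c20_kpa * (I1 - 3.0)
        return 2.0 * W1 * (lt2 - lr2), 2.0 * W1 * (lz2 - lr2)
    th = np.deg2rad(model.theta_deg)
    c2, s2 = np.cos(th) ** 2, np.sin(th) ** 2
    I4 = lt2 * c2 + lz2 * s2
    e = I4 - 1.0
    W4 = model.k1 * e * np.exp(np.minimum(model.k2 * e * e, co.EXP_CAP))
    W6 = model.k3 * e * np.exp(np.minimum(model.k4 * e * e, co.EXP_CAP))
    sig_t = 2.0 * model.c10 * (lt2 - lr2) + 2.0 * (W4 + W6) * lt2 * c2
    sig_z = 2.0 * model.c10 * (lz2 - lr2) + 2.0 * (W4 + W6) * lz2 * s2
    return sig_t, sig_z


def _solve_rings(model, r0_mm: np.ndarray, h0_mm: float, p_pa: np.ndarray,
                 lam_lo: float = 0.5, lam_hi: float = 2.0, iters: int = 80
                 ) -> np.ndarray:
    """Vectorized thin-wall equilibrium solve: lam_theta per station.

    Bisection on the monotone residual f(lam) = sigma_theta(lam) h0/(lam^2 r0) - p,
    bracketed on [lam_lo, lam_hi]; raises EquilibriumError if no root exists
    there (over-pressurization).
    """
    r0 = np.asarray(r0_mm, dtype=float)
    p = np.broadcast_to(np.asarray(p_pa, dtype=float), r0.shape).copy()

    def residual(lam):
        # overflow to +inf in the clipped fiber term is harmless here: it only
        # drives the bisection downward
        with np.errstate(over="ignore"):
            sig_t, _ = _membrane_stress_clipped(model, lam)
            return sig_t * 1e3 * h0_mm / (lam * lam * r0) - p

    lo = np.full_like(r0, lam_lo)
    hi = np.full_like(r0, lam_hi)
    f_lo, f_hi = residual(lo), residual(hi)
    if np.any(f_lo * f_hi > 0):
        raise EquilibriumError(
            "no membrane equilibrium in lam in (%.2g, %.2g): over-pressurization"
            % (lam_lo, lam_hi))
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        f_mid = residual(mid)
        take_lo = f_lo * f_mid <= 0
        hi = np.where(take_lo, mid, hi)
        f_hi = np.where(take_lo, f_mid, f_hi)
        lo = np.where(take_lo, lo, mid)
        f_lo = np.where(take_lo, f_lo, f_mid)
    lam = 0.5 * (lo + hi)
    return np.where(p == 0.0, 1.0, lam)


@dataclass(frozen=True)
class WallSection:
    """One membrane ring: reference radius, thickness and material."""

    r0: float  # mm, reference inner radius
    thickness: float = 1.5  # mm
    material: co.Model = field(default_factory=co.AnisotropicModel)
    curv_axial_anterior: float = 0.0   # 1/mm, signed (+ bulging outward)
    curv_axial_posterior: float = 0.0  # 1/mm

    def __post_init__(self):
        if self.r0 <= 0 or self.thickness <= 0:
            raise EquilibriumError("section radius and thickness must be positive")


def ring_equilibrium(section: WallSection, p: float) -> tuple[float, float, float]:
    """Solve one ring: returns (lam_theta, sigma_theta, sigma_z) in (-, MPa, MPa)."""
    lam = float(_solve_rings(section.material, np.array([section.r0]),
                             section.thickness, np.array([float(p)]))[0])
    sig_t, sig_z = co.membrane_stress(section.material, lam)
    return lam, float(sig_t) / 1e3, float(sig_z) / 1e3


def apply_end_constraints(displacements: np.ndarray, x: np.ndarray,
                          influence_mm: float = 20.0) -> np.ndarray:
    """Project a displacement profile onto {zero at both end stations}.

    Subtracts Gaussian influence functions anchored at the two ends, with
    coefficients solved so the end values vanish exactly; interior stations
    are left essentially untouched beyond the influence length.  The map is
    a projection (idempotent).
    """
    d = np.asarray(displacements, dtype=float)
    x = np.asarray(x, dtype=float)
    L = x[-1] - x[0]
    g0 = np.exp(-(((x - x[0]) / influence_mm) ** 2))
    g1 = np.exp(-(((x[-1] - x) / influence_mm) ** 2))
    A = np.array([[g0[0], g1[0]], [g0[-1], g1[-1]]])
    coef = np.linalg.solve(A, np.array([d[0], d[-1]]))
    return d - coef[0] * g0 - coef[1] * g1


@dataclass(frozen=True)
class WallSnapshot:
    """Wall response at one load state (per axial station)."""

    lam_anterior: np.ndarray
    lam_posterior: np.ndarray
    disp_anterior: np.ndarray   # mm, outward (+z)
    disp_posterior: np.ndarray  # mm, outward (-z)
    sig_theta: np.ndarray  # MPa, side-averaged
    sig_z: np.ndarray      # MPa
    von_mises: np.ndarray  # MPa
    center_offset: np.ndarray  # mm, + toward anterior


@dataclass
class WallHistory:
    """Time series of wall snapshots on the solid time grid."""

    times: np.ndarray
    x: np.ndarray          # mm, axial stations
    ap_semi0: np.ndarray   # mm, reference AP semi-chord per station
    snapshots: list[WallSnapshot]

    def inner_diameter(self) -> np.ndarray:
        """AP inner diameter (mm), shape (n_times, n_stations)."""
        return np.array([2.0 * self.ap_semi0 + s.disp_anterior + s.disp_posterior
                         for s in self.snapshots])

    def max_diameter_history(self) -> tuple[np.ndarray, np.ndarray]:
        return self.times, self.inner_diameter().max(axis=1)

    def peak_von_mises_history(self) -> tuple[np.ndarray, np.ndarray]:
        return self.times, np.array([s.von_mises.max() for s in self.snapshots])

    def center_offset_at_max(self) -> np.ndarray:
        """Centre-point offset (mm) at the station of maximum diameter."""
        d = self.inner_diameter()
        idx = d.argmax(axis=1)
        return np.array([s.center_offset[i] for s, i in zip(self.snapshots, idx)])


class WallModel:
    """Per-station membrane wall bound to a generated geometry.

    The station radius is the anterior-posterior semi-chord b(x) (the wall
    response is reported in the sagittal plane); the per-side axial curvature
    of the reference profiles supplies the asymmetry descriptor.
    """

    def __init__(self, geom: AAAGeometry, material: co.Model | None = None,
                 thickness: float | None = None, influence_mm: float = 20.0,
                 curvature_correction: bool = True):
        self.geom = geom
        self.material = material if material is not None else co.AnisotropicModel()
        self.thickness = thickness if thickness is not None else geom.thickness
        self.influence_mm = influence_mm
        self.curvature_correction = curvature_correction
        self.x = geom.x
        self.b0 = geom.ap_semi  # mm
        # signed axial curvatures of the two wall lines, + when bulging outward
        self.kappa_a = -_second_derivative(geom.anterior, geom.x)
        self.kappa_p = _second_derivative(geom.posterior, geom.x)

    def respond(self, p_anterior, p_posterior=None) -> WallSnapshot:
        """Static wall response to transmural pressures (Pa) per station."""
        p_a = np.broadcast_to(np.asarray(p_anterior, dtype=float), self.x.shape)
        p_p = p_a if p_posterior is None else np.broadcast_to(
            np.asarray(p_posterior, dtype=float), self.x.shape)

        h0 = self.thickness
        if self.curvature_correction:
            # symmetric pre-solve for the axial stress entering the
            # two-curvature correction p_eff = p - sigma_z * h * kappa_z
            lam0 = _solve_rings(self.material, self.b0, h0, 0.5 * (p_a + p_p))
            _, sz0 = _membrane_stress_clipped(self.material, lam0)
            sz0_pa = sz0 * 1e3
            h_cur = h0 * MM / lam0
            p_a = p_a - sz0_pa * h_cur * (self.kappa_a / MM)
            p_p = p_p - sz0_pa * h_cur * (self.kappa_p / MM)

        lam_a = _solve_rings(self.material, self.b0, h0, p_a)
        lam_p = _solve_rings(self.material, self.b0, h0, p_p)
        d_a = apply_end_constraints((lam_a - 1.0) * self.b0, self.x, self.influence_mm)
        d_p = apply_end_constraints((lam_p - 1.0) * self.b0, self.x, self.influence_mm)
        # stresses evaluated at the tethered stretches so the constrained ends
        # carry (near-)zero membrane stress
        lam_at = 1.0 + d_a / self.b0
        lam_pt = 1.0 + d_p / self.b0
        sig = [np.asarray(v) for v in co.membrane_stress(
            self.material, 0.5 * (lam_at + lam_pt))]
        sig_t, sig_z = sig[0] / 1e3, sig[1] / 1e3  # kPa -> MPa
        return WallSnapshot(
            lam_anterior=lam_at, lam_posterior=lam_pt,
            disp_anterior=d_a, disp_posterior=d_p,
            sig_theta=sig_t, sig_z=sig_z, von_mises=von_mises(sig_t, sig_z),
            center_offset=0.5 * (d_a - d_p),
        )


def _second_derivative(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    return np.gradient(np.gradient(y, x), x)


def css_run(geom: AAAGeometry, pressure_waveform, material: co.Model | None = None,
            t_end: float = 3.0, dt: float = 0.005, thickness: float | None = None,
            influence_mm: float = 20.0, curvature_correction: bool = True
            ) -> WallHistory:
    """CSS technique: every station loaded by the uniform outlet-pressure
    waveform; quasi-static response at the solid time step (default 5 ms)."""
    model = WallModel(geom, material, thickness, influence_mm, curvature_correction)
    times = np.arange(0.0, t_end + 0.5 * dt, dt)
    snaps = [model.respond(float(pressure_waveform(t))) for t in times]
    return WallHistory(times=times, x=geom.x, ap_semi0=model.b0, snapshots=snaps)


def export_wall_history_csv(hist: WallHistory, path) -> None:
    """Long-format CSV: one row per (time, station)."""
    import pandas as pd

    rows = []
    diam = hist.inner_diameter()
    for k, (t, s) in enumerate(zip(hist.times, hist.snapshots)):
        rows.append(pd.DataFrame({
            "t_s": t, "x_mm": hist.x, "inner_diameter_mm": diam[k],
            "lam_anterior": s.lam_anterior, "lam_posterior": s.lam_posterior,
            "sig_theta_mpa": s.sig_theta, "sig_z_mpa": s.sig_z,
            "von_mises_mpa": s.von_mises, "center_offset_mm": s.center_offset,
        }))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)
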