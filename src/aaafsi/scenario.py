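"""Scenario configuration: geometry, material, waveforms and run settings.

A :class:`Scenario` bundles everything a run mode needs -- the parametric
geometry, the wall material, the boundary waveforms, fluid properties, grid
resolution and time stepping -- and can round-trip through YAML so runs are
reproducible from a plain-text config.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import yaml

from . import constitutive as co
from . import geometry as geo
from . import waveforms as wf
from .errors import ConfigurationError


@dataclass(frozen=True)
class CouplingConfig:
    """Staggered-coupling settings (time steps follow the study's protocol:
    fluid 1 ms, solid 5 ms, exchange every 5 ms)."""

    dt_fluid: float = 1e-3       # s
    dt_solid: float = 5e-3       # s
    exchange: float = 5e-3       # s
    omega: float = 0.3           # under-relaxation on interface displacement
    tol_mm: float = 1e-3         # convergence tolerance on displacement, mm
    max_subiters: int = 40

    def __post_init__(self):
        n = self.exchange / self.dt_fluid
        if abs(n - round(n)) > 1e-9:
            raise ConfigurationError("exchange interval must be a multiple of dt_fluid")
        if not (0 < self.omega <= 1):
            raise ConfigurationError("under-relaxation omega must lie in (0, 1]")


@dataclass(frozen=True)
class Scenario:
    """Complete run description for any of the three modeling techniques."""

    mode: str = "fsi"                     # 'fsi' | 'cfd' | 'css'
    material: str = "anisotropic"         # 'anisotropic' | 'isotropic'
    stiffness_scale: float = 1.0          # multiplies all stiffness constants
    stretch_factor: float = 1.0           # axial lengthening of the vessel
    n_stations: int = 201                 # geometry sampling
    nx: int = 96                          # fluid cells, streamwise
    nz: int = 24                          # fluid cells, cross-stream
    cycles: int = 3                       # cardiac cycles simulated
    period: float = 1.0                   # s
    velocity_mean: float = wf.DEFAULT_MEAN_VELOCITY   # m/s
    velocity_peak: float = 0.20           # m/s
    velocity_peak_time: float = 0.3       # s
    pressure_peak_time: float = 0.4       # s
    diastolic_mmhg: float = 80.0
    systolic_mmhg: float = 120.0
    density: float = 1035.0               # kg/m^3
    viscosity: float = 0.0035             # Pa s
    thickness: float = 1.5                # mm
    influence_mm: float = 20.0            # end-tethering influence length
    save_interval: float = 5e-3           # s, wall-traction series cadence
    snapshot_times: tuple = (0.2, 0.3, 0.45, 0.5)  # within the final cycle
    coupling: CouplingConfig = field(default_factory=CouplingConfig)
    uniform_pressure: bool = False        # FSI degenerate mode: load the wall
                                          # with the uniform outlet pressure

    def __post_init__(self):
        if self.mode not in ("fsi", "cfd", "css"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if self.material not in ("anisotropic", "isotropic"):
            raise ConfigurationError(f"unknown material {self.material!r}")

    # -- builders -----------------------------------------------------------

    def build_material(self) -> co.Model:
        s = self.stiffness_scale
        if self.material == "anisotropic":
            m = co.AnisotropicModel()
            return co.AnisotropicModel(c10=m.c10 * s, k1=m.k1 * s, k2=m.k2,
                                       k3=m.k3 * s, k4=m.k4, theta_deg=m.theta_deg)
        m = co.IsotropicModel()
        return co.IsotropicModel(C10=m.C10 * s, C20=m.C20 * s)

    def build_geometry(self) -> geo.AAAGeometry:
        g = geo.build_geometry(n_stations=self.n_stations)
        if self.stretch_factor != 1.0:
            g = geo.axially_stretched(g, self.stretch_factor)
        return g

    def build_props(self) -> wf.FluidProperties:
        return wf.FluidProperties(density=self.density, viscosity=self.viscosity)

    def build_inlet_velocity(self) -> wf.Waveform:
        return wf.inlet_velocity_waveform(period=self.period, t_peak=self.velocity_peak_time,
                                          mean=self.velocity_mean, peak=self.velocity_peak)

    def build_outlet_pressure(self) -> wf.Waveform:
        return wf.outlet_pressure_waveform(period=self.period, t_peak=self.pressure_peak_time,
                                           diastolic_mmhg=self.diastolic_mmhg,
                                           systolic_mmhg=self.systolic_mmhg)

    @property
    def t_end(self) -> float:
        return self.cycles * self.period

    @property
    def absolute_snapshot_times(self) -> tuple:
        t0 = (self.cycles - 1) * self.period
        return tuple(t0 + t for t in self.snapshot_times)

    # -- identity -----------------------------------------------------------

    def fingerprint(self, ignore: tuple = ("mode", "material", "stiffness_scale",
                                           "uniform_pressure")) -> str:
        """Hash of the shared study conditions; runs are comparable when their
        fingerprints match (mode/material intentionally excluded)."""
        d = asdict(self)
        for k in ignore:
            d.pop(k, None)
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]

    def with_(self, **kw) -> "Scenario":
        return replace(self, **kw)

    # -- YAML ---------------------------------------------------------------

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["snapshot_times"] = list(self.snapshot_times)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "Scenario":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "coupling" in d and isinstance(d["coupling"], dict):
            d["coupling"] = CouplingConfig(**d["coupling"])
        if "snapshot_times" in d:
            d["snapshot_times"] = tuple(d["snapshot_times"])
        return cls(**d)


def resample_geometry(geom: geo.AAAGeometry, x_new: np.ndarray) -> geo.AAAGeometry:
    """Geometry with boundary arrays interpolated onto new axial stations
    (used to conform the wall model to the fluid grid's cell columns)."""
    return replace(
        geom,
        x=np.asarray(x_new, dtype=float),
        lateral=np.interp(x_new, geom.x, geom.lateral),
        anterior=np.interp(x_new, geom.x, geom.anterior),
        posterior=np.interp(x_new, geom.x, geom.posterior),
    )
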