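"""Synthetic pulsatile boundary waveforms and flow-regime diagnostics.

The published study drives the vessel with a pulsatile inlet velocity peaking
at t = 0.3 s and an outlet pressure peaking at t = 0.4 s over a cardiac cycle;
the numeric series behind those figures is not tabulated, so this module
provides a smooth parametric stand-in with the same qualitative structure:
systolic rise over 0.2-0.3 s, a slower deceleration over 0.3-0.5 s, and a
low-flow diastole.  The cardiac period defaults to 1.0 s.

The waveform family is a skew-warped periodic bump

    B(t) = exp(kappa * (cos(phi) - 1)),
    phi  = omega*(t - t_peak) + skew * (1 - cos(omega*(t - t_peak))),

which is exactly periodic, infinitely smooth, and attains its maximum exactly
at ``t_peak`` (phi is strictly monotone for |skew| < 1, so phi = 0 only at
the peak).  Negative skew slows the phase after the peak, giving the faster
acceleration / slower deceleration shape of a systolic pulse.

Diagnostics: Reynolds number Re = rho*v*dh/mu and the fully developed
turbulence-intensity estimate I = 0.16 * Re^(-1/8).  At the study's inlet
conditions Re = 191 (deeply laminar); the intensity formula is retained as a
diagnostic only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError

MMHG_TO_PA = 133.322

#: Default characteristic (cycle-mean) inlet velocity, m/s.  Chosen so that
#: Re = rho*v*dh/mu reproduces the study's printed inlet Reynolds number 191
#: with the default blood properties and the 21.6 mm inlet diameter.
DEFAULT_MEAN_VELOCITY = 0.0299


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian blood: density (kg/m^3) and dynamic viscosity (Pa s)."""

    density: float = 1035.0
    viscosity: float = 0.0035

    def __post_init__(self):
        if self.density <= 0 or self.viscosity <= 0:
            raise DomainError("fluid properties must be positive")


def _skewed_bump(t, period: float, t_peak: float, kappa: float, skew: float) -> np.ndarray:
    """Normalized periodic bump in [0, 1], maximum 1 exactly at t_peak."""
    t = np.asarray(t, dtype=float)
    omega = 2.0 * np.pi / period
    d = omega * (t - t_peak)
    phi = d + skew * (1.0 - np.cos(d))
    raw = np.exp(kappa * (np.cos(phi) - 1.0))
    lo = np.exp(-2.0 * kappa)  # exact minimum: phi sweeps a full circle
    return (raw - lo) / (1.0 - lo)


@dataclass(frozen=True)
class Waveform:
    """Smooth periodic scalar waveform ``value = lo + (hi - lo) * bump(t)``.

    ``kind`` is 'velocity' (m/s) or 'pressure' (Pa).  ``hi`` is attained
    exactly at ``t_peak``; ``lo`` is the minimum over the cycle.
    """

    period: float
    t_peak: float
    lo: float
    hi: float
    kind: str
    kappa: float = 12.0
    skew: float = -0.45

    def __post_init__(self):
        if self.period <= 0 or not (0 <= self.t_peak < self.period):
            raise DomainError("invalid period or peak time")
        if not abs(self.skew) < 1:
            raise DomainError("|skew| must be < 1 for a single-peaked cycle")

    def __call__(self, t) -> np.ndarray:
        b = _skewed_bump(t, self.period, self.t_peak, self.kappa, self.skew)
        out = self.lo + (self.hi - self.lo) * b
        return out if np.ndim(out) else float(out)

    def cycle_mean(self, n: int = 20000) -> float:
        t = np.linspace(0.0, self.period, n, endpoint=False)
        return float(np.mean(self(t)))

    def sample(self, n: int = 1000) -> tuple[np.ndarray, np.ndarray]:
        t = np.linspace(0.0, self.period, n, endpoint=False)
        return t, self(t)


def inlet_velocity_waveform(period: float = 1.0, t_peak: float = 0.3,
                            mean: float = DEFAULT_MEAN_VELOCITY, peak: float = 0.20,
                            kappa: float = 12.0, skew: float = -0.45) -> Waveform:
    """Pulsatile inlet-velocity waveform (m/s) with prescribed cycle mean.

    The bump amplitude is scaled so that the cycle mean equals ``mean`` and
    the maximum equals ``peak`` (for ``peak == mean`` the waveform is the
    constant mean level).
    """
    shape = Waveform(period, t_peak, 0.0, 1.0, "velocity", kappa, skew)
    bbar = shape.cycle_mean()
    amp = (peak - mean) / (1.0 - bbar)
    lo = mean - amp * bbar
    return Waveform(period, t_peak, lo, lo + amp, "velocity", kappa, skew)


def outlet_pressure_waveform(period: float = 1.0, t_peak: float = 0.4,
                             diastolic_mmhg: float = 80.0, systolic_mmhg: float = 120.0,
                             kappa: float = 7.0, skew: float = -0.30) -> Waveform:
    """Outlet pressure waveform (Pa) spanning the diastolic-systolic range."""
    return Waveform(period, t_peak, diastolic_mmhg * MMHG_TO_PA,
                    systolic_mmhg * MMHG_TO_PA, "pressure", kappa, skew)


@dataclass(frozen=True)
class SampledWaveform:
    """Periodic waveform defined by samples (t, value), linearly interpolated.

    Lets users substitute digitized or measured data for the parametric
    defaults.
    """

    t: np.ndarray
    value: np.ndarray
    period: float
    kind: str = "velocity"

    def __call__(self, t) -> np.ndarray:
        tm = np.mod(np.asarray(t, dtype=float), self.period)
        tt = np.concatenate([self.t, [self.t[0] + self.period]])
        vv = np.concatenate([self.value, [self.value[0]]])
        out = np.interp(tm, tt, vv)
        return out if np.ndim(out) else float(out)

    @classmethod
    def from_csv(cls, path, period: float, kind: str = "velocity") -> "SampledWaveform":
        df = pd.read_csv(path)
        return cls(df["t_s"].to_numpy(), df["value"].to_numpy(), period, kind)


def export_waveform_csv(w, path, n: int = 1000, period: float | None = None) -> None:
    """Write (t_s, value) samples of one cycle to CSV."""
    period = period if period is not None else w.period
    t = np.linspace(0.0, period, n, endpoint=False)
    pd.DataFrame({"t_s": t, "value": np.asarray(w(t))}).to_csv(path, index=False)


# --------------------------------------------------------------------------
# Flow-regime diagnostics


def reynolds_number(props: FluidProperties, velocity: float, dh: float) -> float:
    """Re = rho * v * dh / mu (characteristic length = inlet diameter)."""
    if velocity <= 0 or dh <= 0:
        raise DomainError("velocity and characteristic length must be positive")
    return props.density * velocity * dh / props.viscosity


def turbulence_intensity(re: float) -> float:
    """Fully developed pipe-flow turbulence-intensity estimate 0.16 Re^(-1/8)."""
    if re <= 0:
        raise DomainError("Reynolds number must be positive")
    return 0.16 * re ** (-1.0 / 8.0)


@dataclass(frozen=True)
class FlowConditions:
    """Flow-regime summary at the inlet."""

    dh: float = 21.6e-3  # m, inlet diameter
    velocity: float = DEFAULT_MEAN_VELOCITY  # m/s
    props: FluidProperties = field(default_factory=FluidProperties)

    @property
    def reynolds(self) -> float:
        return reynolds_number(self.props, self.velocity, self.dh)

    @property
    def intensity(self) -> float:
        return turbulence_intensity(self.reynolds)
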