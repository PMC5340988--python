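"""Pulsatile boundary waveforms and the inlet flow regime.

The inlet velocity peaks at t = 0.3 s and the outlet pressure at t = 0.4 s
of a 1 s cardiac cycle.  The Reynolds number at the 21.6 mm inlet is 191 --
deeply laminar; the fully developed turbulence-intensity estimate is kept
as a diagnostic.
"""

import numpy as np

from aaafsi import (FlowConditions, inlet_velocity_waveform,
                    outlet_pressure_waveform, turbulence_intensity)

v = inlet_velocity_waveform()          # mean 0.0299 m/s, peak 0.20 m/s
p = outlet_pressure_waveform()         # 80/120 mmHg

t = np.arange(0.0, 1.0, 0.001)
vt, pt = v(t), p(t)
print(f"Velocity: peak {vt.max():.3f} m/s at t = {t[np.argmax(vt)]:.3f} s, "
      f"cycle mean {vt.mean():.4f} m/s")
print(f"Pressure: {pt.min()/1e3:.2f}-{pt.max()/1e3:.2f} kPa, "
      f"peak at t = {t[np.argmax(pt)]:.3f} s")

fc = FlowConditions()
print(f"\nInlet Reynolds number: {fc.reynolds:.0f}  (rho v d / mu)")
print(f"Turbulence intensity 0.16 Re^(-1/8): {100 * fc.intensity:.1f}%")
print(f"At Re = 256 the estimate is exactly {turbulence_intensity(256):.3f}.")
print("\nAt Re ~ 191 the flow is laminar; the solver treats it as such.")
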