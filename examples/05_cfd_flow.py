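"""CFD technique: rigid-wall pulsatile flow through the AAA.

Runs a shortened (two-cycle, coarse-grid) rigid-wall simulation and reports
the axial wall-shear-stress profile and the recirculation inventory at peak
systole and in the deceleration phase.
"""

import numpy as np

from aaafsi import Scenario, axial_wss_profile, run_cfd
from aaafsi.metrics import recirculation_inventory

sc = Scenario(nx=64, nz=16, cycles=2)
result = run_cfd(sc)

t0 = (sc.cycles - 1) * sc.period
for t_rel in (0.3, 0.45):
    x, prof = axial_wss_profile(result.flow, t0 + t_rel)
    print(f"t = {t_rel} s: WSS at proximal neck {prof[5]:+.2f} Pa, "
          f"bulge {prof[len(x)//2]:+.2f} Pa, distal neck {prof[-5]:+.2f} Pa")

inv = recirculation_inventory(result, sc.viscosity)
for t, regions in sorted(inv.items()):
    desc = ", ".join(f"{r.wall}[{1e3*r.x_start:.0f}-{1e3*r.x_end:.0f} mm]"
                     for r in regions) or "none"
    print(f"t = {t - t0:.2f} s: reversed-flow regions: {desc}")

print("\nWall shear is high at the narrow necks and collapses over the")
print("bulge; vortices (reversed near-wall flow) appear during the")
print("deceleration phase after peak systole, not during acceleration.")
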