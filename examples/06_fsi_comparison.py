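"""Full comparison of the three modeling techniques (scaled-down run).

Runs FSI (two-way coupled), CFD (rigid wall) and CSS (uniform pressure) on
a coarse grid over two cardiac cycles, plus an isotropic-wall FSI run, and
prints the cross-technique comparison report.  Takes a couple of minutes.
"""

from aaafsi import Scenario, compare_models, fsi_run, run_cfd, run_css

sc = Scenario(nx=48, nz=12, cycles=2)

print("running FSI (anisotropic wall) ...")
fsi = fsi_run(sc)
print("running CFD (rigid wall) ...")
cfd = run_cfd(sc)
print("running CSS (uniform pressure) ...")
css = run_css(sc)
print("running FSI (isotropic wall) ...")
fsi_iso = fsi_run(sc.with_(material="isotropic"))

report = compare_models(fsi, cfd, css, fsi_iso=fsi_iso,
                        mu=sc.viscosity, period=sc.period, cycles=sc.cycles)
print("\n" + report.summary_text())
print("Findings marked 'pass' reproduce the cross-technique study")
print("directionally; 'isotropic_smaller_von_mises' is expected to fail:")
print("a load-controlled membrane wall necessarily carries more stress when")
print("softer (larger radius, thinner wall) -- the published ordering stems")
print("from 3-D shell bending that this reduced model deliberately omits.")
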