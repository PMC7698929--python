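"""Fit the three functional-assay curves: Hill pCa-velocity, NEM load line
and co-sedimentation saturation.

All inputs are synthetic with known ground truth, emulating in vitro motility
and binding experiments (3 noisy replicates for the velocity data).
"""
import numpy as np
import pandas as pd

from tpmflex import (fit_hill, fit_load_line, fit_saturation,
                     gen_motility_curve, gen_nem_line, velocity_ratio)

# calcium dependence of sliding velocity, truth vmax 9.4 um/s, pCa50 6.30
data = gen_motility_curve(9.4, 6.30, 3.5, np.arange(4.0, 7.01, 0.25),
                          noise_sd=0.15, replicates=3, seed=8)
hill = fit_hill(data)
print(f"Hill fit:  vmax = {hill.vmax:.2f} um/s, pCa50 = {hill.pCa50:.3f}, "
      f"n = {hill.n:.2f}")

control = fit_hill(gen_motility_curve(5.8, 6.13, 3.1,
                                      np.arange(4.0, 7.01, 0.25)))
print(f"velocity ratio vs control: {velocity_ratio(hill, control):.1f}x")

# frictional load: NEM-modified myosin fraction that stops sliding
nem = gen_nem_line(8.0, 15.0, np.arange(0.0, 12.6, 2.5), noise_sd=0.2, seed=8)
load = fit_load_line(nem)
print(f"NEM load line: stop fraction = {load.stop_fraction:.1f}% "
      f"(v0 = {load.v0:.2f} um/s)")

# co-sedimentation binding curve, truth K50 = 1.68 uM
c = np.array([0.2, 0.5, 1.0, 1.68, 2.5, 4.0, 6.0, 10.0])
bound = 1.0 * c**2 / (1.68**2 + c**2)
sat = fit_saturation(pd.DataFrame({"concentration": c, "bound": bound}))
print(f"saturation fit: K50 = {sat.K50:.2f} uM, hill slope h = {sat.h:.2f}")
# pCa50 measures calcium sensitivity; the stop fraction is a relative force
# scale; K50 is the concentration at which the filament is half-decorated.
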