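"""Fit a Boltzmann sigmoid to a thermal dissociation (light-scattering) melt.

Generates a noisy normalized light-scattering decay with midpoint 46.14 C
and recovers the dissociation temperature — the temperature at which half
of the complex has fallen apart.
"""
import numpy as np

from tpmflex import fit_dissociation, gen_dissociation_curve

curve = gen_dissociation_curve(46.14, 1.0, np.arange(35.0, 60.01, 0.25),
                               noise_sd=0.02, seed=8)
fit = fit_dissociation(curve)
print(f"ground truth Tdiss = 46.14 C")
print(f"fitted       Tdiss = {fit.Tdiss:.2f} C, width = {fit.width:.2f} C")
print(f"plateaus: {fit.lower:.3f} .. {fit.upper:.3f} "
      f"(residual norm {fit.residual_norm:.3f})")
# A higher Tdiss means the complex survives to higher temperature, i.e. a
# more thermostable filament-protein interaction.
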