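"""Continuum removal and band-depth arithmetic on a single spectrum.

Applies pigment troughs to a flat background, removes the convex-hull
continuum, and evaluates RABD620 / RABA620 on the result.
"""

import numpy as np

import phycospec as ps

axis = ps.default_axis()
flat = ps.Spectrum(axis, np.full(axis.band_count, 0.6))
spiked = ps.apply_pigment_troughs(flat, pc_mass=150.0, chla_mass=10.0,
                                  spec=ps.MATRIX_SPECS["organic"])

cr = ps.continuum_removed(spiked)
depth_620 = 1.0 - cr.at(620.0)
print(f"continuum-removed trough depth at 620 nm: {depth_620:.3f}")

t = ps.TROUGH_PROFILES["RABD620"]
print(f"RABD620 = {ps.rabd(spiked, t):.4f}  (1 = no trough)")
print(f"RABA620 = {ps.raba(spiked, t):.4f}  (0 = no trough area)")

# The continuum-removed depth is the fractional reflectance deficit below
# the hull; RABD is the local two-point continuum at 620 nm divided by the
# measured reflectance there, and RABA integrates the deficit over the window.
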