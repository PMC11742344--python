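"""Downcore pigment profile of a synthetic varved core.

Builds a cube whose rows alternate between phycocyanin-rich and -poor
laminae (emulating seasonal varves) and extracts the per-row RABD620 and
RABD660 profiles on an 80 um depth axis, round-tripped through ENVI files.
"""

import tempfile
from pathlib import Path

import numpy as np

import phycospec as ps

spec = ps.MATRIX_SPECS["organic"]
axis = ps.default_axis()
bg = ps.make_background(spec, axis)
rich = ps.apply_pigment_troughs(bg, pc_mass=150.0, chla_mass=10.0, spec=spec).values
poor = ps.apply_pigment_troughs(bg, pc_mass=20.0, chla_mass=10.0, spec=spec).values

values = np.empty((10, 6, axis.band_count))
values[0::2] = rich
values[1::2] = poor
cube = ps.HyperspectralCube(axis, values, pixel_size_um=80.0)

with tempfile.TemporaryDirectory() as tmp:
    hdr = ps.write_envi(cube, Path(tmp) / "varves.hdr", interleave="bil")
    cube = ps.read_envi(hdr)  # lossless round-trip through the ENVI format

profile = ps.downcore_profile(
    cube, [ps.TROUGH_PROFILES["RABD620"], ps.TROUGH_PROFILES["RABD660"]]
)
print(profile[["depth_mm", "RABD620_mean", "RABD660_mean"]].round(4).to_string(index=False))

# RABD620 alternates with a 2-row (0.16 mm) period tracking the simulated
# seasonal laminae; RABD660 stays nearly constant because the chlorophyll
# load does not alternate.
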