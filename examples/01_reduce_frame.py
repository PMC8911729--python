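"""Reduce a detector frame to radial and azimuthal profiles.

Simulates one Pilatus-like frame of a collagenous tissue volume (D-period
65 nm, fibril angle 161 deg, broad interfibrillar ring) and reduces it to
I(q) and I(chi).
"""

import numpy as np

import saxsdic as sx
from saxsdic.pipeline import reduce_frame

geometry = sx.synthetic_geometry((256, 256))
truth = sx.FibrilGroundTruth()
frame = sx.simulate_frame(truth, geometry, seed=7)

radial, azimuthal = reduce_frame(frame, geometry)

q5 = radial.grid[np.nanargmax(np.where(radial.grid > 0.4, radial.intensity, 0))]
chi_peak = azimuthal.grid[np.nanargmax(azimuthal.intensity)]
print(f"frame: {frame.counts.sum():.0f} photons, "
      f"{frame.mask.sum()} beamstop-masked pixels")
print(f"brightest radial bin above 0.4 nm^-1: q = {q5:.4f} nm^-1 "
      f"(5th collagen order of D = {10 * np.pi / q5:.2f} nm)")
print(f"brightest azimuthal bin: chi = {chi_peak:.0f} deg "
      f"(true fibril angle {truth.chi0:.0f} deg)")
print(f"total SAXS intensity I_total = {sx.total_intensity(radial):.3f}")
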