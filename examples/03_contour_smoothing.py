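"""Smooth a follicle outline by truncating its Fourier descriptors.

A component boundary is resampled to N equispaced points (N a power of two)
and encoded as the complex sequence s[n] = x[n] + j y[n].  Keeping only the
P = 4 lowest-frequency DFT coefficients and inverting reconstructs the
overall shape without the boundary roughness.
"""

import numpy as np

from octseg import PhantomSpec, generate_phantom, refine_mask
from octseg.postproc import fourier_descriptors, reconstruct_contour

_, mask, _ = generate_phantom(PhantomSpec(height_px=200, width_px=512,
                                          n_follicles=1, seed=3))
_, follicles, _ = refine_mask(mask)
comp = follicles.components[0]

s = comp.contour
S = fourier_descriptors(s)
smooth = reconstruct_contour(S, p=4)

perim = lambda z: float(np.abs(np.diff(np.r_[z, z[0]])).sum())
print(f"component area:        {comp.area} px")
print(f"contour points N:      {s.size} (power of two)")
print(f"retained descriptors:  P = {comp.retained}")
print(f"perimeter raw:         {perim(s):.1f} px")
print(f"perimeter smoothed:    {perim(smooth):.1f} px")
print(f"centroid (x, y):       ({(S[0] / s.size).real:.1f}, {(S[0] / s.size).imag:.1f})")
# the smoothed perimeter is shorter: high-frequency roughness is gone
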