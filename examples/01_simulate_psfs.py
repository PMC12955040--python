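"""Simulate the point-spread functions of both light-field arms.

Builds the desk-scale LFM and FLFM PSFs and prints their key properties:
the 5D LFM tensor dimensions (depths, sub-lenslet source offsets, sensor
pixels per lenslet), and the FLFM depth-weight array whose complex phases
encode defocus.
"""

import numpy as np

from lffusion import optics

lcfg, lmla = optics.lfm_desk_config()
lpsf = optics.compute_lfm_psf(lcfg, lmla, n_offsets=12)
print("LFM PSF tensor (z, s_y, s_x, u, v):", lpsf.data.shape)
print("  depth range: %.0f to %.0f um" % (lcfg.depth_grid_um[0], lcfg.depth_grid_um[-1]))
print("  each depth slice sums to %.6f (unit flux)" % lpsf.data[0].sum())

fcfg, fmla = optics.flfm_desk_config()
fpsf = optics.compute_flfm_psf(fcfg, fmla, view_spacing_px=36.0)
print("FLFM depth weights w(z):", fpsf.weights.shape)
w = fpsf.weights[:, 0, 0]
print("  |Im w| at focus vs 10 um defocus: %.3f vs %.3f"
      % (abs(w[fcfg.n_depths // 2].imag), abs(w[0].imag)))
print("  parallax: %.2f px per um of depth per unit view offset"
      % fpsf.disparity_px_per_um)
print("  2-3-2 view centres (px):")
print(np.round(fpsf.view_centers_px, 1))
# The LFM tensor stores, per depth, how a point at each sub-lenslet offset
# lights up the pixels of the central lenslet; the FLFM arm compresses each
# depth into one Hermitian frequency response times a complex weight.
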