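"""Stray-light resistance of coincidence imaging.

Adds a static speckle field with mean intensity 8x the classical signal to
both detector regions and compares the contrast-to-noise ratio of the
classical image (signal-arm temporal mean) with that of the coincidence
reconstruction, at matched frames.  Because the speckle is uncorrelated
between the two regions, its covariance vanishes in expectation and the
coincidence image is almost unaffected.
"""

import numpy as np

import qmcscope as q

shape = (24, 24)
obj = np.zeros(shape)
obj[:, :12] = 1.0
mask_obj = np.zeros(shape, bool)
mask_obj[4:20, 2:10] = True
mask_bg = np.zeros(shape, bool)
mask_bg[4:20, 14:22] = True

base = q.default_config(n_frames=20_000, region_shape=shape, object_map=obj, seed=0)
table = q.cnr_vs_stray(base, [0.0, 8.0], mask_obj, mask_bg, n_repeats=5, seed=7)
print(table.round(3).to_string(index=False))
ratio = table.qmc_cnr_mean[1] / table.classical_cnr_mean[1]
print()
print(f"at 8x stray light, coincidence CNR / classical CNR = {ratio:.1f}")
print("the speckle swamps the classical image (CNR < 1) but cancels from")
print("the covariance, which only sees left/right-correlated photons")
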