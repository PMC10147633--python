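"""CNR growth with frame count, and resolution through focus.

The coincidence estimate is a sample covariance, so its standard error
shrinks as 1/sqrt(N) and the CNR grows as sqrt(N).  Through focus, both
arms broaden by the same empirical factor sqrt(1 + (z/z_R)^2), so the
coincidence arm stays twice as sharp at every z.
"""

import qmcscope as q
import numpy as np

shape = (16, 16)
obj = np.zeros(shape)
obj[:, :8] = 1.0
mask_obj = np.zeros(shape, bool)
mask_obj[3:13, 1:6] = True
mask_bg = np.zeros(shape, bool)
mask_bg[3:13, 10:15] = True

base = q.default_config(n_frames=2000, region_shape=shape, object_map=obj, seed=0)
table = q.cnr_vs_frames(base, [2000, 8000, 32000], mask_obj, mask_bg, n_repeats=5, seed=1)
print(table.round(2).to_string(index=False))
print(f"log-log slope of CNR vs N: {q.loglog_slope(table.n_frames, table.cnr_mean):.3f}"
      "  (sqrt(N) scaling -> 0.5)")
print()

cfg = q.OpticalConfig(na_effective=0.25, pixel_pitch_um=0.15, defocus_zr_um=8.0)
zt = q.resolution_vs_z(cfg, [-8.0, -4.0, 0.0, 4.0, 8.0])
zt["ratio"] = zt.R_qmc_um / zt.R_classical_um
print(zt.round(3).to_string(index=False))
print("the coincidence arm resolves ~2x finer at every axial position")
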