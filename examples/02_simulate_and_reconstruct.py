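"""Simulate an EMCCD acquisition and reconstruct the coincidence image.

Generates left/right frame stacks at the experimental operating point
(0.49 photons per pixel per frame, 60% carried by entangled pairs), then
estimates the coincidence image as the covariance of inversely registered
pixel pairs, cov(I^L(p), I^R(S-p)) = mean coincidence intensity.
"""

import numpy as np

import qmcscope as q

shape = (24, 24)
obj = np.zeros(shape)
obj[4:20, 4:12] = 1.0  # transparent bar on an opaque background

cfg = q.default_config(n_frames=20_000, region_shape=shape, object_map=obj, seed=1)
left, right, truth = q.simulate_stacks(cfg)

center = q.estimate_center(left, right)
print(f"estimated symmetric center sum: {center} (true {cfg.center_sum})")

img = q.covariance_coincidence(left, right, q.RegisteredPairMap(center, shape))
inside = img.values[obj.astype(bool)]
outside = img.values[~obj.astype(bool)]
print(f"frames used                   : {img.n_frames}")
print(f"true coincidence rate (bar)   : {cfg.mu_coin.max():.4f} photons/px/frame")
print(f"reconstructed rate (bar)      : {inside.mean():.4f} +/- {img.std_error.max():.4f}")
print(f"reconstructed rate (backgrnd) : {outside.mean():.5f}")
z = (img.values - cfg.mu_coin) / img.std_error
print(f"pixels within 3 standard errs : {np.mean(np.abs(z) < 3) * 100:.1f}%")
print()
print("The covariance recovers the coincidence rate; uncorrelated detector")
print("noise (0.196 photons/px/frame here) contributes nothing on average.")
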