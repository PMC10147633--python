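"""Point-spread functions at lambda and lambda/2, and knife-edge resolution.

Builds Airy intensity PSFs for the classical arm (532 nm) and the
coincidence arm (266 nm equivalent biphoton wavelength) at the same
effective NA, images a knife edge through each, and fits the edge spread
function ESF(x) = a erf((x - x0)/w) + b.  The reported resolution is the
FWHM of the Gaussian line spread function, R = 2 sqrt(ln 2) w.
"""

import qmcscope as q

cfg = q.OpticalConfig(na_effective=0.25, pixel_pitch_um=0.1)

fit_c = q.knife_edge_resolution(cfg, "classical")
fit_q = q.knife_edge_resolution(cfg, "qmc")
print(f"effective NA                 : {cfg.na_effective}")
print(f"classical resolution R       : {fit_c.R:.3f} um  (532 nm)")
print(f"coincidence resolution R     : {fit_q.R:.3f} um  (266 nm equivalent)")
print(f"classical / coincidence ratio: {fit_c.R / fit_q.R:.3f}")
print()

# Calibrate the effective NA so the classical arm measures 2.9 um — the
# pupil is underfilled in practice, so the effective NA is fitted to the
# measured classical resolution — then read off the coincidence resolution.
cal = q.calibrate_na(2.9)
print(f"calibrated effective NA      : {cal.na_effective:.4f}")
print(f"classical R after calibration: {q.knife_edge_resolution(cal, 'classical').R:.3f} um")
print(f"coincidence R at same optics : {q.knife_edge_resolution(cal, 'qmc').R:.3f} um")
print()
print("The ratio ~2 is the Heisenberg-limit gain: the entangled pair acts")
print("as one photon at half the wavelength, halving every PSF length scale.")
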