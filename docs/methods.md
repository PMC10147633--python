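# Methods

This note documents the models behind `qmcscope`, the defaults and why they
were chosen, what the synthetic data do and do not emulate, and the
numerical choices a user should know before trusting a number.

## Coincidence estimator

The estimator is the population covariance (1/N normalization) of the
temporally aligned intensities at mirrored pixel pairs. Identities used:

- coincidence counts are Poisson, so var(I_coin) = mean(I_coin); the
  covariance image estimates the mean coincidence intensity directly;
- detector noise and stray light are uncorrelated between the left and
  right regions, so their covariance vanishes in expectation whatever their
  magnitude — they only inflate the estimator's variance.

The per-pixel standard error reported with every reconstruction is
SE = sqrt((m22 − cov²)/N), where m22 is the sample central mixed moment
E[ΔL²ΔR²]. The simpler Gaussian formula (σ_L²σ_R² + cov²)/N underestimates
the error for Poisson data by the shot term mean(I_coin)/N, which is not
negligible at low flux; the m22 form is distribution-free to leading order.
m22 is accumulated from shifted power sums (shift = first-chunk mean) so
streaming over 1000-frame files loses no precision; the covariance itself
uses exact per-chunk comoments merged by the pairwise-update formulas and
matches a naive two-pass computation to ~1e-12 relative.

Negative covariance values are retained in the output (they carry noise
information and keep the estimator unbiased); clipping, if desired, belongs
to display-time normalization only.

**Centre registration.** The symmetric centre is found by computing the
total pair covariance for *every* candidate integer centre sum S at once:
the landscape Σ_p cov(I^L(p), I^R(S−p)) is the frame-summed full
convolution of the demeaned stacks, so one FFT pass yields it exactly, and
the landscape index is S itself. Landscape cells sum different numbers of
pixel pairs, so for the no-signal test each cell is normalized by the
square root of its pair count; the peak must stand 6 robust standard
deviations (1.4826·MAD) above the landscape median or a
"no symmetric correlation found" error is raised. Six sigmas rather than
three because a landscape of a few thousand independent noise cells
routinely produces 3.5–4 sigma extremes; six keeps the false-alarm rate
negligible while any real coincidence peak exceeds it by orders of
magnitude. Only integer centre sums are searched (the simulator deposits
at integer mirrors); sub-pixel registration is out of scope.

## Image formation

Both arms use the incoherent imaging law: the detected image is
|t|²·envelope convolved with the intensity PSF. The printed image-formation
laws are pointwise products with h(ρ, Mρ); a literal pointwise product
cannot blur an object, whereas measured line-spread functions exist, so the
product is read as shorthand for convolution with the PSF — consistent with
standard wide-field theory. Choices:

- **PSF**: Airy pattern of a circular pupil, |2J₁(v)/v|² with
  v = 2πNA·r/λ, normalized to unit discrete sum; kernel radius 12 FWHM
  (the Airy tails decay as r⁻³, so a tight kernel biases edge fits).
  A Gaussian option (σ = 0.21·λ/NA) exists for closed-form checks.
  Grid sampling coarser than λ/(4NA) raises an error rather than aliasing
  silently.
- **Effective NA** is a free parameter: real systems underfill the pupil,
  so the nominal objective NA (0.4) overestimates resolution. It is
  calibrated by root-finding the NA at which the classical knife-edge
  pipeline returns the measured classical resolution (2.9 µm → NA ≈ 0.104);
  the coincidence arm is then fully determined and lands at ≈ 1.41 µm.
- **Defocus**: FWHM(z) = FWHM(0)·sqrt(1 + (z/z_R)²) with a single z_R
  (default 10 µm, configurable) shared by both arms. No defocus law is
  available from first principles here; the measured depth-of-field curves
  of the two arms track each other, and a shared empirical z_R preserves
  the factor-2 ratio through focus, which a wavelength-dependent z_R would
  not.
- **Envelopes**: when one field-intensity envelope is supplied, the
  classical arm sees it directly and the coincidence arm sees its
  elementwise square ("distribution of squared intensity"), which narrows a
  Gaussian envelope by √2. Both can also be supplied explicitly.
- Images stay on the object-plane grid; magnification M only rescales
  coordinates (resampling belongs to I/O, not the model).

## Synthetic frame stacks

Per frame, each left pixel draws C ~ Poisson(mu_coin) and the same count is
deposited at the pixel and at its mirror in the right region — perfect
momentum anticorrelation, which is what the covariance derivation assumes.
A finite momentum-correlation width can be emulated with a Gaussian jitter
of the mirror position (default off). On top: independent Poisson detector
noise per region; optionally a static speckle stray-light field
(exponential-intensity random field, i.e. |smoothed complex Gaussian|²,
grain size 2 px) whose spatial mean is stray_ratio × the classical signal
mean I₀ = mean(mu_coin + mu_noise_left), with per-frame Poisson shot noise
and independent left/right realizations — this makes its L/R covariance
vanish in expectation, which is exactly the suppression mechanism under
test; a temporally fluctuating speckle option exists for stress tests.
An EM-register stage can replace each count k with a Gamma(k, gain) draw
(the standard cascade model, excess noise factor √2 in amplitude).

Defaults are the experimental operating point: 0.49 mean photons per pixel
per frame, with a **coincidence fraction of 0.6** of that budget. The
split between coincident and uncorrelated photons is not measurable from a
single arm; 0.6 is inferred from the reported stray-light endurance
(coincidence CNR still above unity at ~120× stray with 10⁵ frames):
inverting CNR ≈ mu_coin·√N / (√2·σ_L·σ_R) with σ² ≈ (1+120)·0.49 shows the
coincident share must be ≳ 0.55 of the budget for that to hold. Frames are
generated in 1000-frame chunks with counter-based seed splitting
(`default_rng((seed, stream, chunk))`), so stacks are bit-reproducible
under any chunking. Default frames are in calibrated photon units (EM gain
off): covariance analysis of real data operates on gain-calibrated counts,
and simulating the gain stage only to divide it out again adds nothing but
its excess noise, which can be enabled when that is the point.

The simulator does *not* emulate: clock-induced charge, readout smearing
or direction, spectral structure of the down-converted light, or the pump
beam profile beyond the illumination envelope handed in from the optics
model. Passing tests therefore demonstrate estimator correctness under the
stated statistical assumptions, not end-to-end camera fidelity.

## Metrology

- `ResolutionFit.R` is the identity 2√(ln 2)·w, never a separate fit.
- ESF fits initialize a, b from the profile extremes, x0 from the half
  crossing, and w from the 16–84% rise distance (erf reaches 0.68 at
  (x−x0)/w = 0.7063); w is bounded by the profile span and a fit pinned at
  that bound is an error, not a number.
- Knife-edge profiles are averaged over a 14-line strip along the edge and
  fitted over a window of ±8 FWHM of the *measured arm's* PSF: both arms'
  profiles are then analyzed self-similarly, which keeps the fitted ratio
  at the geometric value 2 (a fixed-size window weights the Airy ring
  oscillations of the two arms differently and biases the ratio by ~3%).
  The image grid is sized so the convolution kernel never touches the
  fitted region.
- CNR masks are explicit inputs everywhere (the object/background regions
  used in any published number are generally not recoverable from text).
- Cubic-spline display interpolation (not-a-knot ends) is provided for
  visualization only and is never applied before fitting.
- Experiment sweeps (`cnr_vs_frames`, `cnr_vs_stray`) repeat each point
  with derived seeds (default n = 10) and report mean ± SEM. Sweep sizes
  used in the test suite (regions of 16²–24² pixels, 10⁴–1.6×10⁵ frames)
  were chosen as the smallest geometries whose mask statistics are stable;
  the scaling laws under test are region-size invariant.

## Known limitations

- Only primary-HDU FITS image cubes are read/written (16-bit with the
  BZERO=32768 unsigned convention, or float32/float64); this covers the
  acquisition layout but not general FITS.
- The stray-light CNR endurance depends directly on the assumed coincidence
  fraction; with a fraction well below ~0.5 the 120× endurance shrinks
  accordingly. The fraction is a single explicit parameter.
- No coherent/phase imaging, polarization, vectorial high-NA PSFs, or
  crystal phase-matching physics; the pair source is reduced to its
  anticorrelated-pair statistics.
- Centre estimation assumes the centre is constant over the acquisition
  (no drift model).
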