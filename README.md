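# qmcscope

Quantum microscopy by coincidence (QMC), in silico: a physics-faithful
simulator of entangled-biphoton EMCCD frame stacks, the covariance-based
coincidence reconstruction algorithm, and the resolution / contrast-to-noise
metrology that quantifies what coincidence imaging buys over classical
wide-field microscopy — a factor-2 resolution gain at the Heisenberg limit
and near-immunity to stray light.

It is written for people building or evaluating wide-field quantum imaging
systems (SPDC source + EMCCD) and for anyone who wants a controlled testbed
for coincidence-extraction algorithms: every simulated photon has a known
ground-truth rate map, so estimator bias, variance and CNR can be measured
exactly.

## The model

**Coincidence estimation.** Signal and idler photons of an entangled pair
land in the left and right regions of the camera at positions mirrored
through a symmetric centre (momentum anticorrelation in the crystal far
field). With total intensities at a registered pixel pair

    I^L = I_coin + I^L_noise,    I^R = I_coin + I^R_noise,

and detector noise uncorrelated between regions, the temporal covariance
over N frames (population form)

    cov(I^L, I^R) = (1/N) Σ_i (I^L_i − Ī^L)(I^R_i − Ī^R)

reduces to var(I_coin) = mean(I_coin), because the coincidence count is
Poisson (variance = mean). The covariance image therefore *is* the mean
coincidence image, and every left/right-uncorrelated contribution — read
noise, dark counts, stray-light speckle of any magnitude — drops out in
expectation.

**Image formation.** The coincidence image obeys the same incoherent
imaging law as the classical image, but at half the wavelength and with the
squared illumination envelope:

    G²_QMC(ρ) = [ |t(ρ)|² Γ_QMC(λ/2; ρ) ] ⊗ |h(λ/2)|²
    G¹_CI(ρ)  = [ |t(ρ)|² γ_CI(λ; ρ)  ] ⊗ |h(λ)|²

with t the object's amplitude transmission, h the pupil PSF (Airy pattern
of the effective NA) and ⊗ incoherent convolution. Halving the wavelength
halves every lateral PSF scale — the Heisenberg-limit factor 2 for an
N = 2 entangled state.

**Metrology.** Resolution is measured by fitting a knife-edge profile to
ESF(x) = a·erf((x−x0)/w) + b and reporting the FWHM of the Gaussian LSF,
R = 2√(ln 2)·w. Contrast-to-noise ratio is
CNR = |Ī₁ − Ī₂| / √(σ₁² + σ₂²) between object and background masks.

## Worked example

```python
import qmcscope as q

cfg = q.OpticalConfig(na_effective=0.25, pixel_pitch_um=0.1)
fit_c = q.knife_edge_resolution(cfg, "classical")
fit_q = q.knife_edge_resolution(cfg, "qmc")
print(fit_c.R, fit_q.R, fit_c.R / fit_q.R)
```

prints (micrometres):

```
classical resolution R       : 1.214 um  (532 nm)
coincidence resolution R     : 0.603 um  (266 nm equivalent)
classical / coincidence ratio: 2.013
```

the coincidence arm resolves twice as finely with the same pupil. On the
statistical side (`examples/02_simulate_and_reconstruct.py`): 20 000
simulated frames at the 0.49 photons/pixel/frame operating point give

```
true coincidence rate (bar)   : 0.2940 photons/px/frame
reconstructed rate (bar)      : 0.2944 +/- 0.0060
pixels within 3 standard errs : 99.8%
```

i.e. the covariance estimator recovers the ground-truth coincidence rate
map to within its own predicted standard error. The other examples show
stray-light rejection (8× speckle: coincidence CNR ≈ 12.7 vs classical
≈ 0.3), √N CNR growth, and the reproducible YAML→FITS→reconstruction
pipeline, also reachable from the shell:

```sh
qmc all -c config.yaml     # simulate / reconstruct / analyze / all
```

## Layout

- `src/qmcscope/optics_model.py` — PSFs, envelopes, classical/QMC image formation
- `src/qmcscope/biphoton_sim.py` — frame-stack simulator (Poisson pairs, noise, speckle, EM gain)
- `src/qmcscope/coincidence.py` — streaming covariance estimator, centre registration
- `src/qmcscope/analysis.py` — normalization, CNR, ESF/LSF fits, experiment sweeps
- `src/qmcscope/io_cli.py` + `cli.py` — FITS stack I/O, pipeline runner, `qmc` CLI
- `examples/` — one narrative script per capability
- `docs/methods.md` — model assumptions, parameter choices, limitations
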