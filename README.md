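# countdet

Characterization toolkit for electron-counting direct detectors, written
for detector physicists and cryo-EM facility staff who need to quantify
how a counting camera behaves across dose rates: how much signal is lost
to coincidence, how the noise power spectrum reflects that loss, what the
MTF and DQE are at realistic operating points, and what the resolution
cost of pushing the dose rate is.

## The models at its core

**Coincidence loss.** A counting detector cannot distinguish two
electrons arriving too close together; the detected (output) dose rate
*y* saturates as the input rate *x* grows:

    y(x) = (1 − e^(−a·x)) / a

with both rates in electrons per physical pixel per second (eps) and a
single fitted constant *a* (s·px/e⁻). The saturation limit is 1/*a*, the
inversion is closed-form, *x* = −ln(1 − a·y)/a, and the coincidence-loss
fraction is CL(*x*) = 1 − y/x (CL(0) = 0). Input rates for the fit come
from a constant-illumination magnification ladder: the highest
magnification is the zero-loss anchor and input scales with pixel area.

**Noise power spectrum.** Ideal counting gives a white NPS; coincidence
loss makes per-pixel counts sub-Poisson and suppresses low frequencies.
Spectra are rotationally averaged and normalized by their mean between
1.5× and 2.0× physical Nyquist. Because noise *power* scales as the
square of the count-transfer efficiency relative to the per-event white
floor, the loss fraction is estimated as 1 − √(NNPS) over the
0.06–0.08 physical-Nyquist band.

**MTF and DQE.** The MTF is estimated from a slanted straight edge
(a beamstop in practice) via an oversampled edge-spread function;
DQE(0) by noise binning (variance of block-binned flood images); and the
curve composed as DQE(s) = DQE(0) · MTF(s)² / NNPS(s). The ideal
square-pixel detector has DQE = |sinc(s/2)|²: 1 at zero frequency, 0.4
at Nyquist.

**ResLog.** Reconstruction resolution is linear in log₁₀(particles);
slopes measure per-particle information content, intercepts alignment
accuracy. Fits regress a recorded resolution transform (reciprocal Å by
default) on log₁₀ N.

**Simulator.** An event-based counting-sensor simulator provides ground
truth: Poisson arrivals merged within per-pixel counting windows of
length *a* (reproducing the dose-response curve exactly in expectation),
uniform sub-pixel localization with value 16 per event, Poisson false
positives, optional Gaussian scene PSF, and slanted-edge scenes with the
analytic system MTF recorded for recovery tests.

## Worked example

```python
import countdet as cd

model = cd.fit_dose_response([(16, 15), (34, 30), (78, 60)])
print(f"a = {model.a:.5f} s*px/e-   saturation = {cd.saturation_limit(model):.0f} eps")
for x in (15, 30, 66):
    print(f"CL({x:2d} input eps) = {100*cd.coincidence_loss(model, x):.1f}%")
print(f"detected 12.0 eps -> input {cd.invert_detected(model, 12.0):.1f} eps")

plan = cd.plan_exposure(target_dose=60.0, pixel_size=0.599, detected_eps=15.0)
print(f"exposure {plan.exposure_time*1000:.0f} ms, {plan.n_frames} frames, "
      f"{plan.achieved_dose:.1f} e-/A^2")

spec = cd.DetectorSpec(a=0.007, false_positive_rate=0.0)
movie, _ = cd.simulate_flat_movie(spec, cd.Scene.uniform((512, 512), 34.0),
                                  duration=0.21, seed=1, accumulate=True,
                                  ground_truth=False)
y = cd.intensity_to_detected_eps(movie)
print(f"simulated flood at 34 input eps -> {y:.2f} detected eps "
      f"(model predicts {cd.predict_detected(model, 34.0):.2f})")
```

prints

```
a = 0.00708 s*px/e-   saturation = 141 eps
CL(15 input eps) = 5.1%
CL(30 input eps) = 9.9%
CL(66 input eps) = 20.1%
detected 12.0 eps -> input 12.5 eps
exposure 1435 ms, 86 frames, 59.9 e-/A^2
simulated flood at 34 input eps -> 30.24 detected eps (model predicts 30.22)
```

The fitted constant a ≈ 0.0071 s·px/e⁻ means ~5% of electrons are lost
at 15 input eps and ~20% at 66; a detector reading of 12.0 eps
corresponds to 12.5 eps actually arriving. The exposure plan converts a
60 e⁻/Å² dose target at 0.599 Å/px into a frame budget at 60 frames/s,
and the simulated flood reproduces the model's detected rate.

The `countdet` command exposes the same operations from a shell
(`simulate flat|edge|beamoff`, `doserate fit|predict|invert|plan`,
`nps`, `mtf`, `dqe0`, `dqe`, `reslog fit|compare|project`,
`characterize` for the full pipeline from a JSON config).

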