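# Methods

## Dose-response model

Detected rate versus input rate is modelled as y(x) = (1 − e^(−a·x))/a,
with x, y in electrons per physical pixel per second (eps) and a in
s·px/e⁻. The model is the expectation of a counting process in which
each pixel's time axis is partitioned into windows of length a and each
window reports at most one event. `a` is treated purely as the fitted
constant of this curve; no internal clock of a real sensor is implied.

Fitting minimizes the sum of squared residuals in detected-rate space
with bounded 1-D minimization over a ∈ [1e−6, 1] (`scipy`'s bounded
Brent, xatol 1e−13), which is deterministic given the data. A fit that
lands at the lower bound signals "no measurable loss" with a warning.
Coincidence loss CL(x) = 1 − y(x)/x is defined as 0 at x = 0 by
continuity; inversion uses the closed form x = −ln(1 − a·y)/a and
refuses y ≥ 1/a (above saturation).

Input-dose ladders assume exactly zero loss at the highest-magnification
(lowest per-pixel flux) anchor and scale input with pixel area
(input_m = input_anchor · (p_m/p_anchor)², p in Å/px), i.e. constant
specimen-plane flux across the magnification series.

**Units.** eps always means electrons per *physical* pixel per second.
Super-resolution intensities are converted first: mean super-res counts
per second / 16 (per-event value) × 4 (sub-pixels per physical pixel).

## The synthetic counting detector

The simulator realizes the window mechanism literally: per physical
pixel, Poisson arrivals with mean x·a per window; a window with ≥ 1
arrival yields exactly one detected event; surplus arrivals are merged
(the coincidence loss). Detected events land on a uniformly random
sub-pixel (2 per axis) with value 16; false positives are a uniform
Poisson process (default 2.86 × 10⁻⁶ events/px/s, the measured dark
rate of the characterized camera); input rates above 80 eps raise a
saturation error, since the real device produces readout artifacts
rather than data there. Default frame period is 1/60 s (16.6 ms is an
accepted alternative). Windows are assigned to output frames by their
start time; a non-integer number of windows leaves a final shorter
window with proportionally lower mean.

Two sampling paths draw from the same distribution: a frame-resolved
path that samples arrivals window by window, and an accumulated path
(one summed output frame) that draws the per-pixel detected total as a
single Binomial and reconstructs merged arrivals from the truncated
first-arrival representation of an occupied window. The accumulated path
makes practice-scale exposures (~1040 e⁻/px for edge work) cheap. All
randomness comes from one seeded generator in a fixed draw order, so a
seed fully determines movie and ground truth; ground truth satisfies
detected + merged = emitted per pixel, every run.

Two consequences of the window mechanism are worth knowing when
interpreting simulator-based tests:

* **Counts are sub-Poisson.** The per-pixel detected count over n
  windows is Binomial(n, 1 − e^(−a·x)), so the variance-to-mean ratio is
  e^(−a·x) ≈ (1 − CL)². The noise-binning DQE(0) of a simulated flood
  with known incident dose is therefore (1 − CL)/e^(−a·x) ≈ 1/(1 − CL),
  slightly *above* one — an artifact of deterministic
  one-count-per-window merging, not a property of real detectors (which
  also lose localization and deposit information).
* **Partial windows dilute the loss.** If the exposure is not a whole
  number of windows, the trailing short window has less merging, so the
  realized coincidence loss of the movie is slightly below the
  steady-state formula. Statistical tests therefore use durations that
  are integer multiples of a.

What the simulator does *not* emulate: charge sharing and Landau
deposition physics, neighborhood-based event discrimination (merging is
strictly per physical pixel), gain non-uniformity, saturation banding
artifacts, and beam-induced motion. Passing recovery tests demonstrate
that the estimators are unbiased under ideal counting statistics, not
that they are robust to those real-data effects.

## Noise power spectra

`radial_power_spectrum` uses the unnormalized forward 2-D DFT of the
central square crop; raw power |F|² satisfies (and the code asserts)
Parseval's identity, total power = N_pixels · Σ image². The DC term is
excluded; annular means use 512 equal-width, half-open radial bins by
default (bin membership by radial frequency magnitude), with band means
weighted by per-bin sample counts. The frequency axis is in units of
physical Nyquist (1.0 ≡ 0.5 cycles per physical pixel); super-resolution
input extends to 2.0. Normalization divides by the band mean over
1.5–2.0× physical Nyquist — a band that exists only for super-res input;
callers with physical-pixel data must specify their own band.

Coincidence loss from the NNPS uses the 0.06–0.08 physical-Nyquist band
mean (the approximate location of the spectrum's minimum) rather than a
literal minimum, which would be noise-biased. Two figures are exposed:
`nps_suppression` = 1 − band mean, the literal power dip; and
`nps_coincidence_loss` = 1 − √(band mean), the loss estimate. The square
root is required because the NNPS is a *power* (variance) ratio: for
window-limited counting the low-frequency NNPS is the Fano factor
e^(−a·x) ≈ (1 − CL)², so the raw dip is roughly twice the loss and the
amplitude ratio is the loss. With this convention the NPS-based estimate
agrees with the dose-response CL within half a percentage point at
16–78 input eps on full-sensor-area simulations (the residual comes from
sub-pixel placement structure in the normalization band). NPS-based CL
remains a consistency check, not the primary quantification — the
rotationally averaged curves are noisy at exactly the frequencies that
matter.

## Slanted-edge MTF

The edge is located per row by the centroid of the intensity gradient in
a window around the strongest gradient (gradient centroids are robust on
counted images where parametric edge fits are brittle), and a
least-squares line through the per-row locations gives angle, offset and
an rms straightness residual. Slants outside 1–15° are refused (the
sub-pixel phase sampling degenerates); inconsistent per-row locations
(rms > 5 px) signal "no edge"; rms above 1 px signals "edge not
straight".

Super-resolution movies are binned to the physical grid before analysis:
event localization is uniform within a physical pixel, so the super-res
grid is a staircase replication of the physical-pixel signal, and
analysing it as if it carried sub-pixel information would fold a
spurious cos(πf/2) factor into the estimate.

The ESF is binned at 1/8 px pitch (oversample 8) on the edge-normal
coordinate, restricted to within 32 px of the edge — distant bins carry
no signal, but their differentiated noise would enter the spectrum —
with sparsely populated end bins (below half the median occupancy)
trimmed. The LSF is the central finite difference, apodized with a Hann
window centered on the LSF peak (searched within ±8 px of the fitted
edge) spanning the trimmed projection. The MTF is the DFT magnitude,
normalized at zero frequency and compensated for the known
central-difference and bin-aperture responses (sinc(2fΔ)·sinc(fΔ),
Δ = bin pitch; without compensation there is a deterministic −0.02 bias
at Nyquist at oversample 8). On noiseless scenes the estimator is
accurate to 0.003 up to physical Nyquist; on counted edges at ~1040
e⁻/px over a 2048-row ROI, to ~0.015.

Beamstop-geometry effects (distance to sensor, edge roughness) bias real
measurements toward underestimating the MTF; no correction is applied.

## Noise-binning DQE(0)

The flood is converted to detected electrons per physical pixel (summed
over frames, divided by the per-event value). For bin factors
b ∈ {1, 2, 4, …, 64} (capped so blocks stay numerous), the normalized
noise is v(b) = Var[b×b block sums]/(b²·mean). The zero-frequency noise
v∞ is the mean of the largest adjacent pair of bin factors agreeing
within 5% relative; no such pair (e.g. non-uniform illumination, where
v grows without bound) raises a plateau error. With incident dose known,
DQE(0) = (mean/N_in)/v∞; without it, the Poisson-relative figure 1/v∞ is
returned and flagged `poisson_relative` rather than silently assuming
full detection. Variance estimates at large b carry sampling error
~√(2/n_blocks), so DQE(0) on a 2048² flood is reproducible to a few
percent.

The DQE curve is composed pointwise as DQE(s) = DQE(0)·MTF(s)²/NNPS(s),
with NNPS defaulting to unity — appropriate for counting data at low
loss, and avoiding injecting radial-average noise into the curve. A
measured NNPS may be supplied; it is interpolated onto the MTF axis and
must cover it.

## ResLog

Ordinary least squares of transform(resolution) on log₁₀(N). The
transform is mandatory and recorded (`reciprocal` Å⁻¹ by default;
`identity` and `reciprocal_squared` available) because published slopes
are only comparable under a stated transform. Slope comparisons require
matching transforms. Projections n = 10^((t(target) − intercept)/slope)
warn — not refuse — beyond 10× the fitted data range (extrapolating the
intercept to one particle is standard practice, but the uncertainty is
real). A zero slope makes any unreached target unreachable and is an
error.

## Pipeline and I/O

`run_characterization` derives one seed per stage from the config seed
(fixed order via `numpy`'s SeedSequence), so a config reproduces its
report bit for bit; per-stage wall times go to the log only. Stages
without configured inputs are reported as skipped, by name.

MRC support is a deliberately small strict codec: little-endian MRC2014,
modes 0/1/2/6, with unsigned 8-bit as mode 0 plus the IMOD stamp (the
de-facto "8-bit MRC" movie convention); malformed headers produce errors
naming the offending field. Metadata that MRC cannot carry (frame
period, super-res factor, per-event value, gain flag) travels in a JSON
sidecar; reading without a sidecar falls back to explicit defaults with
warnings. Extended headers are read if present but never required.

## Problem sizes in the bundled tests

Statistical tests are sized for laptop-scale runtimes while keeping the
study conditions: dose-response recovery uses five dose points of
~10⁶ pixel-seconds each (recovers a within 5%); NPS/CL agreement uses
the full 4096² sensor area at whole-window exposures; edge recovery uses
a 2048-row ROI at the practical ~1040 e⁻/px accumulated dose; DQE(0)
checks use 2048² floods. Tolerances are 3 Monte-Carlo standard errors
where a closed form exists, and the stated recovery bands (5% on a,
2 points on CL, 0.03 on MTF, 0.05 on DQE(0)) otherwise.

## Known limitations

* The simulator's sub-Poisson output statistics make its absolute
  DQE(0) exceed one slightly (see above); real detectors do not behave
  this way at zero frequency.
* Saturation (> 80 input eps) is refused, not emulated; the real
  artifact regime (banding from readout bandwidth limits) is
  qualitative.
* NPS-based coincidence loss depends on the normalization band being a
  pure event-white floor; detectors with structured high-frequency
  response (charge sharing, centroiding correlations) would bias it.
* Dose calibration is relative to the zero-loss anchor of the
  magnification ladder; no absolute (Faraday-cup) calibration is
  attempted.
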