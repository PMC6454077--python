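# Methods

## The forward model

The simulator stands in for a pump-perfused ex-vivo porcine heart scanned
with dynamic contrast-enhanced CT: a 60 s acquisition starting 5 s before a
15 mL bolus of iodinated contrast is injected at 3 mL/s into the inflow
tubing (1.0–1.2 L/min carrier flow), while a loop of that tubing inside the
field of view provides the arterial input function.

**Arterial input.** Enhancement above baseline follows the normalized
gamma-variate

&nbsp;&nbsp;&nbsp;&nbsp;c_a(t) = A · ((t−t₀)/(αβ))^α · exp(α − (t−t₀)/β),&nbsp;&nbsp; t > t₀,

which peaks at exactly A at t₀ + αβ, making every peak-dependent check
exact. Defaults: baseline 40 HU, arrival delay t₀ = injection + 4 s,
α = 3, β = 1.2 s, A = 250 HU. The shape parameters give a first-pass bolus
with a time-to-peak of 3.6 s and FWHM ≈ 4.9 s — the scale set by the 5 s
injection itself, mildly dispersed over ~200 cm of tubing. A perfusion rig
with a 20 L reservoir has essentially no recirculation, so none is
modelled. The bolus width matters: it is the feature against which frame
spacing competes, and a bolus much broader than the injection would mask
the sampling effect the simulator exists to expose.

**Tissue.** Each segment follows a single-compartment uptake model with
partial extraction,

&nbsp;&nbsp;&nbsp;&nbsp;dC_t/dt = k_in·c_a(t) − (k_in/v_d)·C_t(t),&nbsp;&nbsp;C_t(0) = 0,

with k_in = E·F·ρ/60 (per second, per mL tissue), distribution volume
v_d = dist_volume·ρ (mL/mL) and tissue density ρ. Defaults: E = 0.6
(first-pass extraction of iodinated contrast in myocardium), dist_volume
0.3 mL/g (extracellular contrast space), ρ = 1.05 g/mL. The washout term
is retained so that Patlak back-flux bias is a real, exercisable effect.
The unit chain is deliberately exactly inverse to the estimator's
`60·slope/(peak·ρ)` conversion, so in the ideal limit (E = 1, v_d → ∞,
dense noise-free sampling) the maximum-upslope estimate equals F to
numerical precision.

The linear ODE is integrated with an exact exponential update per step
(piecewise-linear input), implemented as a first-order recursive filter on
the default 0.01 s grid; grids coarser than the internal step are rejected
rather than silently interpolated. Against closed-form boxcar and
exponential-input solutions the integrator errs by far less than the 0.5%
documentation tolerance.

**Stenosis grades.** FFR-labelled grades 0.9, 0.8, 0.7, 0.6, 0.5 and total
occlusion map to pump-flow factors 1.0, 1.0, 0.9, 0.8, 0.7, 0.7 — the rig
lowers global input flow from FFR 0.7 downwards to hold pressure constant.
Inside the circumflex territory (5 lateral segments of the AHA-16 model,
leaving 11 non-ischemic) flow is additionally multiplied by the FFR value,
and zeroed under occlusion. Occlusion only marks the territory; it is not
an analyzed grade.

**Hearts.** Three phantoms (560 g/1.0 L·min⁻¹, 430 g/1.2, 580 g/1.1) span
true global perfusions of 1.79–2.79 mL/g/min at pump flows inside the rig's
operating range; porcine heart weights vary from animal to animal, so the
defaults are chosen to span a plausible range rather than depict specific
hearts.

## Acquisition timing

RR intervals are i.i.d. uniform on [60/115, 60/107] s with a random phase
offset of the first beat. Shuttle mode triggers at 35% of the RR interval
(end-systole; the exact phase is not critical since no cardiac motion is
modelled) on every 4th beat: scans fire every other beat and alternate
between two table positions, so the analyzed slab is revisited every fourth
beat — 2.09–2.24 s apart at 107–115 bpm, inside the nominal "one image per
2–3 s". Non-shuttle mode triggers every beat; continuous mode ignores the
ECG and acquires a regular 16 Hz grid (960 frames per 60 s). Readout is
point interpolation of the dense curve by default; a 250 ms
gantry-rotation averaging window is available as a study knob but off by
default. Z-coverage differences between modes are not modelled — analysis
is per-segment on a shared slab.

## Noise model

CT image noise at 70 kV is modelled as additive white Gaussian noise of
σ = 10 HU per voxel. The analyzed curves, however, are ROI means — a
myocardial segment averages ≈ 80 voxels and the tube ROI ≈ 50 voxels at the
image phantom's default geometry — so the experiment applies
σ/√n to the sampled curves (≈ 1.1 HU on a TAC, ≈ 1.4 HU on the AIF). Noise
applied undiluted to single-voxel curves would swamp any 3-sample slope
fit (slope SD an order of magnitude above the signal) and is not how
segment-level analyses operate. The ROI sizes are configuration keys, so
single-voxel analyses can still be emulated.

## Estimators

**Maximum upslope.** Baseline = mean of samples before 5 s (the
pre-injection lead-in); slope = maximum over sliding least-squares line
fits. ECG-triggered modes use a 3-sample window after a 3-frame moving
average — sparse triggered frames need explicit pre-smoothing, otherwise
the maximum over noisy local slopes is biased upward by an amount that
differs between modes and can invert their comparison. The continuous mode
uses a window spanning 1 s (17 samples at 16 Hz), which provides the
equivalent smoothing by itself. Negative results are floored at zero with
a logged warning. All settings are exposed in `UpslopeConfig` /
the `estimation` config section.

**Patlak.** Ordinary least squares of C_t(T)/c_a(T) on
∫₀^T c_a dt / c_a(T) (both baseline-subtracted, trapezoid integration on
the available samples), K1 = 60·slope/ρ, and the flow correction
F = K1/E with the known simulation E. The default data-driven fit window
runs from detected contrast arrival (first sample above 10% of peak
enhancement) to the sampled AIF peak; on sparse shuttle data the window is
widened in frame-spacing steps until three frames fit. Note the default
window is *not* bias-free: at the default washout rate the
irreversible-uptake assumption already fails appreciably before the AIF
peak, biasing K1 low by 10–23% as E·F grows. Unbiased K1 recovery
(≤ 4% across E = 0.4–1.0 at F = 2) needs a genuinely early window — the
recovery checks use (arrival, arrival + 1.5 s), i.e. the pre-peak third of
the uptake, where accumulated back-flux is still negligible. This is an
inherent property of the Patlak approximation, not of the implementation.

**Statistics.** Summaries report n, median and linearly interpolated
quartiles, plus percent underestimation 100·(1 − median/mean true flow).
Scan modes are compared with a paired Wilcoxon signed-rank test on
per-segment differences matched by (heart, grade, segment, replicate) —
the pairing absorbs the between-heart and repeated-measures structure that
a mixed linear model would otherwise carry, and keeps the statistic fully
reproducible. Zero differences are dropped (signed-rank convention);
all-tied samples report p = 1. Pearson correlation between per-row true
flow and estimated MBF is computed per mode.

## Factorial design and defaults

The default experiment is 3 hearts × 3 modes × 5 analyzed grades × 16
segments × both estimators with one replicate, giving 165 analyzed
(non-ischemic) upslope records per scan mode. One replicate is the
default because the physical experiment had one realization per cell;
variance-sensitive properties (mode ordering, correlation signs) are
assessed over ≥ 100 replicates via the `experiment.replicates` key, as in
the acceptance script. Determinism: every cell derives its own random
stream from (seed, replicate, heart, grade, mode, segment), so runs are
bit-reproducible per seed and rows are pairable across modes.

## What the generator does and does not emulate

It emulates the quantities the analysis consumes: curve shapes with known
ground truth, acquisition timing, ROI-level noise, grade-wise flow
reduction, and the territory structure. It does not emulate cardiac or
table motion, beam hardening, partial volume, reconstruction physics,
pressure/FFR mechanics, heart-to-heart kinetic variability, or the
deterioration of an ex-vivo preparation over a scan session. Passing tests
therefore demonstrate the *sampling-rate mechanism* — sparser temporal
sampling monotonically depresses maximum-upslope MBF relative to truth —
and the internal consistency of the estimators, not agreement with any
particular scanner's absolute values, which also reflect software internals
and physiology outside this model.

## Known limitations

* The maximum-upslope estimator reports ≈ E·F even at infinite sampling
  rate; with the default E = 0.6 the continuous mode plateaus ~30% below
  truth. Only the Patlak-corrected flow approaches F.
* Patlak on shuttle-sampled curves rests on 3–4 frames and a widened
  window; its per-segment values are noisy and back-flux-biased, and are
  reported as-is.
* The gamma-variate AIF is a clean unimodal bolus; fragmented or
  recirculating inputs would interact differently with sparse sampling.
* Segment heterogeneity defaults to none (all non-ischemic segments of a
  heart share one flow); per-segment scale factors exist but are not
  exercised by the default study.
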