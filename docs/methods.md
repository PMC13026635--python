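# Methods

This note documents the models, estimators, defaults and numerical
choices behind the package, and what the synthetic-data harness does and
does not establish about real recordings.

## Recording conventions

Canonical units everywhere: mV, pA, ms, pF, MΩ, nS (so `C·dV/dt = I` and
`R·I` need no conversion factors except MΩ·pA = µV → ×10⁻³ mV). Time is
t = 0 at sweep start; stimulus onsets are carried in the sweep's stimulus
descriptor, never inferred from the trace. Sampling is 50 or 100 kHz by
default.

Voltages carry a liquid-junction-potential flag. The correction is
`V_corrected = V_recorded − 16 mV` — the subtraction direction is the
standard one for a K-gluconate internal solution; only the magnitude is
conventionally reported, so the sign is exposed as a parameter. The flag
makes double application an error, and resting-potential estimation
refuses unflagged sweeps. Generators emit true (corrected) potentials by
default (`ljp_offset = 0`); setting `ljp_offset = 16` produces
recorded-convention data for exercising the correction path.

## Passive properties

*Capacitance.* The averaged −5 mV step transient is fitted with
I(t) = I_ss + A₁e^(−t/τ₁) + A₂e^(−t/τ₂) over the full step window by
bounded least squares (`scipy.optimize.curve_fit`, trf). Initialization
is deterministic two-stage tail peeling (log-linear fit of the late tail
for the slow component, subtraction, repeat for the fast one), with up to
5 perturbed restarts. Bounds keep both taus inside (sample/4, 2·window)
— without them the slow component can degenerate into a constant traded
off against the offset on noisy averages. τ₁ ≤ τ₂ is enforced by
relabeling. The capacitive charge is the closed form
Q = A₁τ₁(1−e^(−5τ_w/τ₁)) + A₂τ₂(1−e^(−5τ_w/τ₂)), τ_w = (A₁τ₁+A₂τ₂)/(A₁+A₂),
and C = |Q|/|ΔV|. Numerical trapezoid integration of the
baseline-subtracted average over the same window is kept as a test
oracle, not used in the estimator.

*R_in, τ_mem, E_rest.* Ohm's law at steady state and a mono-exponential
onset fit of the averaged −5 pA response. Analysis windows are not
conventionally reported, so the defaults are: baseline = final 20% of the
pre-stimulus segment, steady state = final 20% of the step. A fitted tau
below half a sample interval is reported as a degenerate fit.

## Spike features

Events are local maxima above a peak criterion (−20 mV default,
post-correction) preceded within 2 ms by dV/dt above the slope criterion.
Derivatives are central differences on the raw trace — acquisition
hardware already low-passes at 3 kHz, so no further smoothing is applied
by default. The threshold criterion ("rapid rise" operationalized) is
0.03 V/ms sustained for ≥ 2 samples, earliest crossing, linear
interpolation between the bracketing samples; it is configurable because
no numeric criterion is conventional. All level crossings (halfwidth,
threshold) interpolate linearly for sub-sample precision at 50–100 kHz.

The AHP fit runs from the post-spike minimum until the trace returns
within 5% of baseline or 20 ms, whichever is first; the reported decay
time is τ·ln 2. Amplitude is referenced to the resting potential (the
threshold-referenced convention also exists; the reference is an explicit
argument).

On simulator traces driven by nA-scale ramps the passive charging slope
I/C alone reaches ~0.07 V/ms on a 20 pF cell, so simulator analyses use a
0.1 V/ms criterion (`physio.validation.SIM_DVDT_CRITERION`); likewise the
synthetic-cohort pipeline uses 0.02 V/ms with −30 mV peaks because some
published group medians place spike peaks near the −20 mV default.

## Timing

Jitter is the sample SD (n−1); the population convention is not
universal and n−1 is the safer small-sample choice. Train spikes are
assigned to pulses by peak time in the half-open window
[onset, onset+2 ms), ties to the earlier pulse; a second spike in one
window is resolved to the first and logged; a silent pulse is NaN and
excluded from that pulse's statistics. "Reliable output" for the minimum
sustain current means 100% pulse completion across repetitions
(configurable fraction). Per-cell aggregation happens first (median
across repetitions), then group medians.

## Vacuolization

The pipeline follows the published image-processing recipe: 8-bit
min–max conversion (which also makes the score invariant to global
gain), 100 × 100 px ROI, 3-plane maximum projection starting at the
nucleus plane (an explicit per-cell input; the plane is selected visually
in practice), soma segmentation, in-mask histogram thresholding,
binarization, B/W ratio with both counts restricted to the mask.

Two points were genuinely open and are resolved as follows:

- *Segmentation.* Otsu + largest component + **convex hull**. A manual
  soma outline is convex; plain hole-filling keeps interior vacuoles but
  loses dark bays where vacuoles touch the soma edge, which biases the
  black count low.
- *Threshold.* The histogram (256 bins, moving-average width 5, peaks
  with ≥ 10-bin separation and ≥ 5%-of-max prominence) has a dark
  (vacuole) and a bright (cytoplasm) mode. The cytoplasmic peak is the
  *maximum* admissible threshold — cutting exactly at it would classify
  half the cytoplasm noise as black — and the actual cut is the smoothed
  valley between the two modes. Pixels strictly below the cut are black
  (dye-excluded); pixels equal to it are white. A unimodal in-mask
  histogram means no dark population: the strict two-peak API raises (so
  such cells can be flagged and excluded), while the pipeline scores them
  as B/W = 0, which is the correct answer for a homogeneously dye-filled
  soma.

## Statistics

Shapiro–Wilk per group (reported, never gating: the nonparametric tests
run regardless), Kruskal–Wallis with mid-ranks and the standard tie
correction against χ²(k−1) (via `scipy.stats`), and hand-implemented Dunn
z tests on the pooled ranks,
z = (R̄ᵢ−R̄ⱼ)/√[(N(N+1)/12 − ΣT/(12(N−1)))(1/nᵢ+1/nⱼ)], two-sided normal
p, Bonferroni factor k(k−1)/2, capped at 1. Quantiles are linear
interpolation (type 7). α = 0.05 with 0.05/0.01/0.001 star tiers. The
statistical unit is the cell.

## The synthetic harness

Every generator is a pure function of (params, seed) — bitwise
reproducible — and emits its ground truth in closed form, never
recomputed from the rendered samples.

*Parametric spikes.* Piecewise waveform: baseline; slow linear approach
to threshold (10 mV/ms, below any detection criterion); linear rise
threshold→peak over `rise_duration`; linear fall at slope
(peak−threshold)/`fall_duration` down to resting−depth; exponential
recovery with τ_AHP. The geometry makes truth exact: halfwidth =
(rise+fall)/2, dV/dt extrema are the two slopes, AHP halftime = τ·ln 2.

*Conductance model.* A generic single-compartment Na/KLT/KHT/leak point
neuron in the ventral-brainstem style, integrated with fixed-step RK4
(default 5 µs; halving dt changes no sample by more than 10⁻³ mV and
spike peaks by less than one 100 kHz sample). Defaults: C = 20 pF,
gNa = 2000 nS, gKLT = 120 nS, gKHT = 300 nS, gL = 4 nS, E_K = −90 mV,
and a global gating rate scale of 6 that brings the room-temperature
rate functions into the fast regime needed for sub-millisecond spikes
and 500 Hz entrainment. These values were calibrated so the harness
reproduces the qualitative physiology of interest — resting near
−71 mV, nA-scale ramp rheobase, halfwidth a few tenths of a millisecond,
and entrainment that degrades when the fast-repolarizing KHT (Kv3-like)
conductance is reduced. The model is a test harness, not a biophysical
claim about MNTB neurons. Noise is additive Gaussian current, constant
within each stimulus sample.

In the KHT direction experiment, noisy trains are driven at the
*baseline* twin's noise-free minimum sustain current for both twins: at
its own (higher) minimum the KHT-reduced cell is again comfortably
suprathreshold and the precision loss is masked; holding the drive at
what sufficed before the conductance loss exposes it.

*Vacuole stacks.* Bright soma ellipsoid (cytoplasm level 200),
background 10, dark spherical vacuoles (level 40, radius 4–7 px ≈
1.3–2.2 µm, the distended-lysosome scale) placed fully inside the soma,
Gaussian blur σ = 0.5 px (~160 nm, the lateral PSF scale of a confocal
at 320 nm pixels), Gaussian noise σ = 8 intensity levels, rendered
16-bit. Truth is the B/W ratio of the ideal (unblurred, noiseless)
3-plane projection at the soma-centre plane, black = below the midpoint
of the two levels.

*Cohorts.* Four groups (WT, untreated KO, low-/high-dose treated) with
per-group medians set to the published group medians wherever those are
printed (ramp current, threshold, amplitude, halfwidth, dV/dt min,
rheobase, latency, jitter, minimum sustain current, B/W ratio).
Within-group variability is reported nowhere, so scale parameters draw
lognormal with CV 0.12 around the median and voltages normal with
1.5 mV SD — an arbitrary but fixed choice, documented here. The spike
cartoon links features (halfwidth = (rise+fall)/2 with fall set by the
repolarization slope), so the implied dV/dt max is smaller than real
cells'; the printed halfwidth and dV/dt-min medians take priority.
Cohort rendering uses reduced sizes (25 VC/CC repetitions, 30 square
repetitions over 30 ms, 8 train repetitions, 15-plane stacks) — the
estimators are invariant to repetition count, and the per-protocol
generators keep the full acquisition-scale defaults (100 repetitions,
500 ms squares).

## What the synthetic tests do and do not show

Passing recovery tests establish that the estimators are unbiased and
precise *under the generative model*: biexponential transients, additive
Gaussian noise, piecewise-linear spikes, spherical vacuoles, Gaussian
PSF. Real recordings add series-resistance artifacts, drift, synaptic
noise, non-convex somata, anisotropic PSFs and chromatic effects that
the harness deliberately omits (no stochastic gating, no synaptic input
model, no deconvolution). Direction checks on the conductance model show
the analysis chain responds correctly to a KHT manipulation; they say
nothing about which conductance changes in the disease.

## Problem sizes

The test suite and the acceptance script size their simulations for a
single CPU: 10-point passive grids, 50 random spike waveforms, 6 paired
model cells for the direction experiment (ramp ladders and 50 pA train
ladders integrated as single batches), 200 null cohorts for calibration,
and one 4 × 6-cell end-to-end cohort. These sizes are stated in the code
where they are used.
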