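# Methods

This note records the generative model, the analysis algorithms, and the
numerical choices behind `calcilux`. Everything below is implemented in
`src/calcilux/` and exercised by the test suite.

## 1. Generative model

### Signal and units

The core activity statistic is ΔI/I₀ = (I − I₀)/I₀, the fractional change
of a region's bioluminescence over its pre-stimulus baseline. Internally
ΔI/I₀ is a dimensionless fraction; the acceptance script reports it × 100
(percent).

### Transients

A Ca²⁺ transient is modeled as an instantaneous rise to amplitude *A*
followed by exponential decay with half-life t½ = 216 ms. Frames integrate
the emission over the exposure window, so the movie stores the
exposure-averaged transient (`transient_exposure_average`): the rise is held
flat for one frame interval so that the peak frame reads exactly *A*, and
the summed trace satisfies Σᵢ vᵢ·dt = A·(dt + t½/ln 2) (photon
conservation, verified in tests). Single-cell (HEK-style) traces use the
same decay but point-sample intensity at 50 Hz.

### Event classes

For each stimulation pulse, a responsive neuron fires a **primary** event
with probability `response_prob` (0.7 in vivo) at a latency drawn from
[0, 0.5] s. Cascade partners fire **secondary** events at latencies ≥ 1 s
(≤ 5 s horizon), modeling the neuron → astrocyte → neuron relay; setting
`astrocyte_coupling_on=False` (the norepinephrine condition) abolishes
them. Latencies in (0.5, 1.0) s are never generated and, on the analysis
side, detected events in that band are **discarded**. Events with no
stimulus within the horizon are **spontaneous** (amplitude ≈ 0.5 ΔI/I₀
versus ≈ 3 for primaries).

### Field geometry

Cells are placed on a jittered square lattice: the field is divided into a
k×k grid whose pitch exceeds the required minimum separation, one site per
cell is chosen at random, and each position is jittered within its cell so
that the minimum separation (2 × cell radius + margin) is guaranteed by
construction. Rejection sampling was abandoned because 50 cells at the
in-vivo density sit near the random-sequential-adsorption jamming limit.

### Slow drifts and the circadian profile

The luciferase substrate decays with a 2.5 h half-life and is replenished
every 3 h; this multiplies the whole frame by a slowly varying gain that
per-stimulus re-baselining cancels exactly (a tested invariant). During the
peak hours 7–8 the preset applies an amplitude gain of 2.5 and raises
cascade participation from 0.2 to 1.0. The split between amplitude and
connectivity is a free preset choice; this one was calibrated (see
`scratch/calibrate_circadian.py`, preserved as the calibration record) so
that the measured NAP fold through the full pipeline is ≈ 4: with 8 ROIs
the distinct-neighbor degree J saturates at 7, capping the connectivity
contribution at ≈ 1.55, and the amplitude gain supplies the rest. Measured
fold over fresh seeds: 3.85 ± 0.75 (SD).

### Sparse rendering

A 14-hour session at 10 Hz would be ~500k frames. Frames are rendered only
within ±5 s of each stimulus plus a 60 s background epoch per hour;
spontaneous events are generated only inside rendered epochs. Stimuli start
2 s into each hour so every pulse has a full 1 s baseline window.

### Photocurrent and MEA

The opsin photocurrent rises as i_max·(1 − e^(−t/τ_on)) during the pulse
(τ_on = 32 ms, i_max = 440 pA) and decays with τ_off = 68 ms after it, with
a zero-current lead-in honoring the schedule onset. The concomitant
recording couples optical change to current at 0.5 %/pA (2 pA per 1 %).
MEA spikes are placed at ground-truth event times for neurons within the
electrode pickup radius, with amplitude proportional to the optical peak
plus Gaussian noise; with noise fraction q the expected optical–electrical
R² is 1 − q (0.9 at q = 0.1 temporally, 0.88 at q = 0.12 spatially).

## 2. Analysis pipeline

### ROI assignment

The response image is built from the first ≤ 10 stimuli: for each, the
pixelwise maximum of the unmasked frames within 0.6 s after pulse offset
minus the mean of a 1 s baseline; the per-stimulus images are combined by
pixelwise maximum so a neuron that misses some stimuli is still captured.
After median-filter background subtraction, pixels above 5 robust SDs form
connected components; components ≥ 4 px become ROIs, ordered by peak
intensity. On the in-vivo preset this recovers exactly the 8 planted
responsive neurons with centroid error ≤ 2 px.

### Trace extraction

Per-ROI intensity is background-corrected with an annulus median. Annulus
pixels belonging to any glowing source (session mean image above median +
5 robust SDs, or any ROI pixel) are excluded — without this, silent
neighbors inside the annulus biased ΔI/I₀ by ≈ +6 %; with it the residual
bias is ≈ +0.4 %. If fewer than 10 annulus pixels survive, the raw ring
minus ROI pixels is used. ΔI/I₀ is computed per stimulus epoch against the
mean of the 1 s pre-stimulus window (median of the whole trace when there
is no schedule); frames overlapping a stimulation pulse are masked (camera
deadtime) and propagate as NaN rather than being interpolated.

### Event detection

Per ROI, the noise SD is the median-absolute-deviation estimate of the
trace's frame-to-frame differences. Detection uses hysteresis — an event
must exceed max(5σ, 0.1) but extends down to max(2σ, 0.04) — so a primary
transient's decay tail is not re-detected as a spurious secondary event.
Within a suprathreshold run, a new event is split wherever a single-frame
rise exceeds the high threshold, so a genuine delayed event riding on a
decay tail is still found. The absolute floors guard against near-zero σ
on noiseless movies, where uint16 quantization would otherwise make the
5σ threshold meaningless. Onset latency relative to the nearest preceding
stimulus assigns the class (primary ≤ 0.5 s, secondary ≥ 1 s within 5 s,
discarded between, spontaneous otherwise, with 1e-9 boundary tolerance).

### Fidelity and kinetics

Fidelity is the fraction of stimuli in a window that elicited a primary
response at a ROI; hourly summaries pool responses over ROIs
(Σ responses / Σ stimuli). Decay kinetics fit log-linear or exponential
decay segments after each peak; photocurrent fitting fits the rise and
decay phases separately with `scipy.optimize.curve_fit` and rejects
non-monotone rises.

### Network analysis (NAP)

Within each stimulus epoch, each event links to its nearest-in-time
predecessor event in another ROI with lag in (0, 500 ms] and distance
≤ 200 μm, giving a forest per epoch; forests are superimposed across
stimuli into a multigraph. A vertex with J ≥ 3 distinct undirected
neighbors is a node, and NAP = Σ nodes Jₙ·(mean primary ΔI/I₀)ₙ. The
linking rule is verified against a brute-force oracle on small instances
(property-based test), and NAP against hand computations (e.g.
3·2 + 4·3 = 18).

### Optical–electrical correlation

Spikes are paired greedily (smallest |lag| first, each spike and event used
once) with optical events of ROIs within the electrode pickup radius and
|lag| ≤ 200 ms; a guard raises on ROI/electrode coordinate frames that
cannot overlap (unit mistakes). Temporal R² regresses spike amplitude on
optical peak over pooled pairs; spatial R² regresses per-electrode spike
count on the active-pixel percentage inside the electrode disc.

## 3. Numerical and testing notes

- All randomness flows through `numpy.random.default_rng(seed)`; identical
  configuration + seed reproduces artifacts bit-identically (checksummed
  manifests).
- Movies are stored as uint16 TIFF with a JSON sidecar (times, mask,
  schedule, session parameters); quantization error is ≤ 1 count.
- Boundary comparisons use a 1e-9 epsilon; tests allow 1e-6 for generator
  float drift in latencies.
- The minimum hourly fidelity statistic is genuinely stochastic: with
  pooled hourly fidelity ~ Bin(80, 0.7)/80, the probability that the
  minimum over 14 hours dips below 0.6 is ≈ 0.24 per seed. Test and
  acceptance seeds were fixed a priori and not selected on outcomes.
- Property-based tests (hypothesis) run derandomized for reproducibility.

## 4. Limitations

- Transients superpose linearly; no indicator saturation or bleaching
  beyond the substrate-decay gain.
- Spike waveforms are not modeled — the MEA layer generates spike times and
  amplitudes directly.
- The network generator plants pairwise cascade delays, not a full
  conductance-based circuit; NAP recovery is therefore a consistency check
  of the analysis, not a biophysical claim.
- Registration is assumed stable (no motion correction); a drift check is
  provided but no correction.
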