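# Methods

This note documents the forward model behind the synthetic recordings, the
estimation procedures in the analysis chain, the parameters that matter and
why their defaults are what they are, and the limits of what the simulations
can show about real recordings.

## Forward model (synthetic recordings)

### Stimulation protocol

A recording is a staircase of `n_pulses` blue-light pulses at onsets
`t_start + i·interval`, pulse *i* carrying irradiance `i·intensity_step`
(the first pulse is dark, so the staircase probes the response threshold
from below). Defaults: 10 pulses of 100 ms, 7 mW/cm² steps (0–63 mW/cm²),
5.5 s apart — long enough for a calcium transient with a 1.5 s decay
constant to relax essentially to baseline — recorded for 60 s at 10
frames/s (600 frames). A protocol optionally carries a circular spatial
mask (centre + radius in μm); neurons outside the mask receive no light.
The default masked geometry uses a 300 μm radius centred at (250, 250) μm,
off-centre in the 832 × 702 μm field so that all three analysis zones
(see below) are populated.

### Network

Somata are placed uniformly at random in the field of view, rejecting
candidates whose centre lies closer than the sum of soma radii to an
accepted soma (no overlap; default radius 15 μm). The synaptic graph is
Erdős–Rényi with one Bernoulli draw per unordered pair (symmetric, zero
diagonal; default edge probability 0.15, a typical density for dissociated
cultures at this scale), or any explicit binary matrix.

### Spiking

Per pulse, every neuron inside the mask fires at the pulse onset with
probability

p(I) = p_max / (1 + exp(−(I − I_half)/s)),  p(0) ≡ 0,

a saturating sigmoid of irradiance I (defaults I_half = 12 mW/cm²,
s = 4 mW/cm², p_max = 0.98). The sigmoid reproduces the empirical shape of
channelrhodopsin dose–response curves — threshold, steep rise, plateau at
roughly 25 mW/cm² and above — without modelling channel biophysics. Each
spike is delivered to all postsynaptic neighbours after a fixed synaptic
delay (50 ms) and triggers each with probability `transmission_prob`,
recursively; a neuron cannot fire twice within the absolute refractory
period (400 ms). With the default delay and refractory period a cascade is
a single synchronous wave per pulse: every return path through the graph
delivers during the originating neuron's refractory window, so the model
cannot reverberate. The firing model deliberately ignores pulse duration
(one firing opportunity per pulse); duration-dependent response scaling is
a known omission, listed under limitations.

### Calcium and rendering

Each spike adds a double-exponential indicator kernel
`A·s·(e^(−t/τ_d) − e^(−t/τ_r))`, normalised so its continuous-time peak is
exactly `amplitude_per_spike` (default 0.8 ΔF/F, with τ_r = 0.1 s,
τ_d = 1.5 s — kinetics of a slow red indicator at room temperature);
kernels sum linearly, i.e. the indicator is assumed far from saturation.
The movie renders each soma as a hard disk on a 160 × 135 pixel grid at
5.2 μm/px (a 640 × 540 sensor with 4 × 4 binning):

pixel(t) = background + F₀ · (1 + ΔF/F(t)) · e^(−t/τ_bleach) + ε,

with ε ~ N(0, noise_sd²) i.i.d. per pixel and frame, clipped at zero.
Photobleaching multiplies the fluorescent signal only, not the additive
camera background — this is the model the baseline fit assumes, and the
distinction matters: a pure exponential cannot absorb a constant offset.
Defaults F₀ = 100, background = 2, τ_bleach = 120 s, noise_sd = 15. The
background is kept small relative to F₀ because the ΔF/F quotient divides
by the *total* baseline including background: at the defaults the resulting
ΔF/F compression is ~2–3%, far below the noise floor. At the default
geometry a soma spans ~26 pixels, so trace-level noise is
15/√26 ≈ 3 counts ≈ 0.03 ΔF/F — a peak SNR of roughly 25.

### Determinism

All randomness flows through `numpy.random.default_rng` seeds. In the
pipeline a single master seed spawns per-stage child seeds (network,
spikes, render, surrogate null) via `numpy.random.SeedSequence`, in that
fixed order, so each stage is independently reproducible and reruns are
bit-identical.

## Analysis chain

### Segmentation

The reference image is the temporal mean of the movie (the default rather
than the max projection: somata carry static baseline fluorescence, and
averaging 600 frames suppresses sensor noise by ~24×). Canny edges feed a
circular Hough accumulator over radii 2–6 px; accumulator peaks scoring at
least `1 − sensitivity` (the normalized score is the fraction of a
candidate circle's perimeter supported by edges; default sensitivity 0.5)
are accepted in score order, with a Euclidean minimum separation (default
twice the minimum search radius) suppressing duplicates. On rendered
movies at the default settings the true somata score ≳ 0.56 and noise
artefacts ≲ 0.44, which is why the threshold sits at 0.5. Traces are the
mean pixel intensity over each ROI disk per frame. Coordinates are 0-based
(row, col) pixel indices; physical positions are `index × pixel_size` μm.

### Baseline estimation and ΔF/F

The baseline model is `F_base(t) = a·e^(−t/τ) + c` with a ≥ 0 and τ capped
at 50× the recording length (beyond which the exponential is numerically a
line and the fit degenerates). The two-pass procedure:

1. least-squares fit over all frames;
2. frames whose residual exceeds `exclusion_threshold` (default 2.5) noise
   SDs *above* the fit are flagged as transients, each flag is extended
   4 s forward and 0.3 s backward, and the model is refit on the surviving
   frames.

Two details are deliberate. First, the noise SD comes from robust first
differences of the trace (`1.4826·median|ΔF|/√2`), not from the pass-1
residuals: at this assay's pulse density transients occupy well over half
the frames, the pass-1 fit rides high, and the residual MAD is inflated —
a threshold based on it barely masks anything, leaving ΔF/F biased low by
20–30% (measured on ground-truthed simulations). Second, the forward
extension of the transient mask excludes the sub-threshold decay tail
(4 s ≈ 2.7 decay constants); without it the tail frames drag the refit
upward by ~5–10%. Negative excursions are never masked — the indicator
reports positive-going events only. If the optimiser fails or fewer than
`min_frames` (20) frames survive masking, the baseline falls back to a
constant at the 10th percentile of the trace and the result is flagged.
ΔF/F = (F − F_base)/F_base, which has ~zero median over baseline frames; a
non-positive fitted baseline raises an error naming the offending frame.

Measured performance at default settings (60 neurons, full-field,
τ_bleach = 120 s): ΔF/F RMSE ≈ 0.05 against the planted truth, mean
per-pulse peak error ≈ 5%. ΔF/F error grows as the baseline bleaches away
(the quotient's denominator shrinks); at τ_bleach = 30 s the last-second
baseline is 13% of its initial value and recovery is noise-limited, which
is why the bleach-robustness suite states its tolerance (RMSE < 0.07) at a
lower sensor noise (SD 6).

### Events

An event opens at the frame where ΔF/F crosses the detection threshold
(default 0.2) upward — onset is the crossing frame itself, with no
sub-frame extrapolation, since at 10 Hz sub-frame onset estimates are not
reliable. The event tracks its running peak and closes when the trace
falls below `close_fraction` (default 0.2) of that peak; events whose
onset follows the previous close by less than `min_separation` (0.5 s) are
merged. Amplitude is the window maximum; rise time is onset-to-peak; the
fall time constant is a log-linear least-squares exponential fit from the
peak down to 20% of the peak (log-linear rather than nonlinear because it
is robust and adequate at 10 Hz; a post-peak segment shorter than 3 frames
leaves the fall time undefined but keeps the event).

### Zones

ROI centres (not edges) are classified by Euclidean distance d to the mask
centre: stimulated (d ≤ r), zone 1 (r < d ≤ 2r), zone 2 (d > 2r). For the
standard 300 μm mask the zone-1 outer boundary is 600 μm. Per-pulse peaks
use half-open windows [onset_i, onset_{i+1}) — anchored at pulse onset,
with the last window running to the end of the trace — so every frame
after the first onset belongs to exactly one pulse. Zone summaries report
mean ± SEM (sample SD/√n) per pulse; a single-neuron zone reports SEM = 0
by convention, and an empty zone reports n = 0 with NaN means rather than
erroring. Full-field protocols label every ROI stimulated and flag the
partition accordingly.

### Connectivity

Traces are z-scored; the pair statistic is the maximum over lags
|ℓ| ≤ max_lag (default 0.5 s = 5 frames) of the circular cross-correlation
`c(ℓ) = (1/T)·Σ_t x̃(t)·ỹ(t−ℓ)`, computed by FFT. Correlation is circular —
rather than windowed-linear — so that the circular-shift surrogate below
is *exactly* exchangeable with the observed statistic under independence;
at T = 600 the wrap-around contribution is negligible. A zero-variance
trace gets correlation 0 against everything (flagged in the result), and
the diagonal is 1 by definition.

The null for each pair circularly shifts one trace by a uniform random
offset and recomputes the statistic, 100 times (a circular shift preserves
each trace's autocorrelation while destroying any cross-correlation).
Offsets are drawn at least `2·max_lag + 1` frames away from zero shift so
a surrogate never overlaps the observed alignment — without this guard
surrogates landing near zero inflate the cutoff exactly when the observed
statistic is high, and the test runs measurably conservative. The cutoff
is the empirical (1 − α) quantile taken as an order statistic (`higher`
interpolation: with 100 shuffles and α = 0.05, the 96th smallest null
value), and an edge requires the observed statistic to *strictly* exceed
it, giving a type-I rate of ≈ 5/101 ≈ 0.0495 per pair under independence
(measured: 0.051 over 3800 independent-noise pairs). Decisions are
symmetrized by logical AND — the mean-global-connectivity formula treats
the graph as undirected — and the diagonal is forced to zero. The summary
statistic is MGC = mean degree/(N − 1) ∈ [0, 1], invariant under node
relabelling, and undefined (an error) for N < 2.

An event-time-shuffling surrogate was considered as an alternative null
and is not implemented; the output metadata records which surrogate
produced each result (`params["surrogate"]`).

## What the simulations do and do not show

The generator emulates: the acquisition geometry and timing, a saturating
optogenetic dose–response with plateau, distance- and graph-dependent
spread of evoked excitation, linear indicator kinetics, photobleaching,
and additive sensor noise. Passing tests therefore show that the analysis
chain correctly inverts *this* forward model at realistic SNR.

They do not show robustness to what the model omits: shot noise and fixed-
pattern sensor noise, neuropil and out-of-focus contamination, overlapping
or non-circular somata, motion, indicator saturation and photoswitching,
spontaneous (non-evoked) activity, conductance-based dynamics, inhibition,
synaptic depression, or duration-dependent spike trains within a pulse.
Functional connectivity on strongly driven cultures is also *expected* to
exceed structural connectivity: common optogenetic drive synchronises
neurons that share no synapse, so the benchmark's adjacency
precision/recall against the planted graph documents that confound rather
than hiding it — the meaningful network-level readout is the contrast in
mean global connectivity between conditions (e.g. intact vs. blocked
transmission), not the raw agreement with the structural graph.

## Problem sizes

The shipped tests and examples run at the assay's native scale — 600-frame
movies of 160 × 135 pixels with 15–60 neurons, 100-shuffle nulls on up to
60 traces — chosen so a full simulate-analyse-score cycle takes about a
second on one core; Monte-Carlo suites (null calibration, condition
contrast) use 20 seeded repetitions.
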