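# Methods

This note documents the models and procedures implemented in `gridwaves`,
the parameters that matter, the choices made where the design was open,
and what the synthetic benchmarks do and do not establish.

## Generalized phase

The wideband (3–40 Hz) LFP is band-limited with a zero-phase fourth-order
Butterworth filter (applied as second-order sections, forward–backward)
and the analytic signal Χ = V + iH[V] computed per channel via the
single-sided FFT. Phase φ = arg Χ, amplitude A = |Χ|, and instantaneous
frequency f = (1/2π)·dφ/dt from the forward difference of the unwrapped
phase.

On wideband signals a weak fast component riding on a strong slow one
drives φ backwards for a few samples (f < 0) whenever the amplitude ratio
of rider to carrier exceeds f_slow/f_fast. The correction masks all
samples flanking a negative forward difference and re-interpolates the
unwrapped phase across each masked run with a monotone piecewise-cubic
(PCHIP) interpolant anchored on the surrounding valid samples. Because a
bridged run can itself expose a net phase decrease, the mask/interpolate
cycle repeats (up to 5 passes) and a final running-maximum guard enforces
a non-decreasing unwrapped phase, so corrected f ≥ 0 at every sample —
at the cost that pathological segments become locally flat (f = 0) rather
than negative. Runs touching the record edge are extended from the
nearest valid sample. The first and last 100 ms of each record are
flagged low-confidence (filter and Hilbert edge effects) and excluded
from wave evaluation.

## Traveling-wave detection

**Evaluation points.** Rising crossings of −π/2 of the corrected phase on
the trigger channel — the positive LFP upswing. The trigger channel is
the deterministic reference electrode (largest mean evoked amplitude),
the same channel used for trial inclusion and late-wave sorting.

**Source point.** The spatial phase gradient is computed on the electrode
lattice with central differences (one-sided at edges), with neighbour
differences wrapped to (−π, π] to avoid unwrap ambiguity. Under the
analytic-signal convention the phase is most advanced at the wave origin
(φ = ωt − k·r), so the outward propagation field is −∇φ and the source is
the electrode of **maximum divergence of −∇φ**. Gradient components are
smoothed with a 3×3 box before the divergence; without smoothing,
site-level phase noise dominates the second difference and single-frame
localization of a planted radial source at SNR 10 drops from ~100 % to
~26 %. Ties break to the smallest channel index. For trial-level statements
(`trial_source`) the source is instead the candidate electrode whose
distance map maximizes the circular-linear phase-distance correlation
summed over the trial's evaluation frames — the defining property of a
source, fit globally over all channels, and far more noise-robust than
averaging or voting over per-frame divergence argmaxes (100 % vs ~85 %
exact recovery of planted interior sources at SNR 10). Per-frame
detection keeps the divergence source so that acceptance and its
location-shuffle null use the same rule. Sources on the boundary ring of
the array are not cleanly localizable (an edge source is
indistinguishable from an incoming plane wave), so the synthetic
benchmarks plant interior sources.

**Acceptance.** The circular–linear correlation ρ ∈ [0, 1] between the
phase frame and the Euclidean distance from the source uses Mardia's
statistic

    ρ² = (r_dc² + r_ds² − 2 r_dc r_ds r_cs) / (1 − r_cs²)

with r_dc = corr(d, cos φ), r_ds = corr(d, sin φ), r_cs = corr(cos φ,
sin φ), vectorized so the shuffle null is cheap. The null permutes
electrode locations, re-localizes the source on the shuffled geometry at
a randomly drawn evaluation point, and measures ρ; the detection
threshold is the 99th percentile of ≥ 1000 such samples, built once per
dataset. A wave additionally requires ≥ 60 % unmasked channels and a
positive wavenumber.

**Kinematics.** The wavenumber is *not* taken from the slope of phase
against distance-from-source: for a plane wave whose nominal source sits
on the grid edge, Euclidean distance over-counts the propagation distance
and inflates the recovered speed by ~1.45×. Instead the phase frame is
regressed on the two electrode coordinates (after unwrapping along the
mean propagation direction); when the plane fit explains the field
(R² ≥ 0.35) k is the norm of the fitted gradient — exact for plane waves
and robust to phase noise, which enters the regressand only. A poor plane
fit indicates an expanding (radial) wavefront, where |∇φ| = k at every
site; k is then the median per-site gradient magnitude. f is the mean
corrected instantaneous frequency over unmasked channels at the
evaluation sample (grid-average; the source- or trigger-channel readings
are not distinguishable on the synthetic fixtures), v = 2πf/k, and the
amplitude is the LFP value at the next zero-phase crossing on the trigger
channel. Epochs are assigned from touch-relative time: prestimulus, early
(0–50 ms), late (100–300 ms passive; 50–100 ms active — a config
parameter, since the two paradigms compress the late window differently).

**PGD.** Phase-gradient directionality = ‖mean gradient‖ / mean ‖gradient‖
over sites: 1 for perfectly aligned propagation, ~1/√n_sites for
incoherent fields.

**Late-wave sorting.** Single-trial LFP on the reference channel is
normalized to the 500-ms prestimulus mean; a trial is *strong-late* iff
the maximum |amplitude| 80–200 ms post-touch strictly exceeds 3
prestimulus SDs. The late-wave amplitude of an averaged trace is
trough-to-peak: the late trough followed by the maximum 100–300 ms
post-touch. Note the 3×SD rule is scale-free: on white-noise trials it
fires at a fixed ~15–20 % rate regardless of noise amplitude, so
responsive-trial counts are exact only for noise-free or
temporally-correlated baselines.

## Calcium-ensemble pipeline

Order of operations: 2.5-SD event binarization → population-coactivity
gate → 300-ms binning → cosine similarity map → significance mask →
eigendecomposition against a shuffled null → Dice connectivity per
retained eigenstate.

Choices that required judgment:

- **Noise floor** per cell is the robust first-difference estimator
  1.4826·MAD(ΔF)/√2, which stays at the noise floor even when slow
  calcium transients occupy most of the trace (the raw-trace MAD does
  not).
- **Coactivity gate.** Its purpose is removing frames explainable by
  independent *background* activity ("solitary events"). The chance level
  is a binomial null at the median per-cell event rate (99th percentile
  over surrogate draws) — the median is robust to a minority of
  high-rate ensemble cells. A null built from full-raster shuffles would
  instead sit at the overall mean coactivity and, when ensembles are
  frequent, delete exactly the frames of interest.
- **Similarity and eigenvalue nulls** come from spatiotemporally shuffled
  surrogates (per-neuron temporal permutation, then cross-ROI
  relabeling). Cosine maps of nonnegative vectors retain a global
  mean-rate mode that shuffling cannot remove, so the structure-sensitive
  chance level for eigenstates is the *second* eigenvalue of the shuffled
  map; retained components must beat its 99th percentile, truncated once
  they cumulatively capture 90 % of variance.
- **Membership.** Bins are assigned to their dominant retained
  eigenstate; within a state's frames, neuron pairs with Dice > 0.25 form
  connections, and each connected component of the Dice graph is one
  ensemble (a mixed state carrying two groups' reactivations contains two
  disjoint cliques). Neurons active in < 5 % of the state frames are
  excluded from pairing — two near-empty background trains that coincide
  once would otherwise score Dice 0.67. Per-bin reactivation indices are
  emitted both as the count and as the fraction of significant partners
  (fraction is the default); ensemble reactivation is the proportion of
  members active in at least one above-chance-coactivity state frame.

The planted-ensemble generator treats co-activation as the reactivation
probability per 300-ms block (one co-firing frame per reactivation),
matching the time scale the analysis bins at. At a *per-frame* rate of
0.3 the chance Dice between two independent high-rate cells is ≈ 0.3,
above the 0.25 connection threshold, and no pipeline can keep memberships
apart — a useful reminder that the Dice threshold presumes sparse
reactivation.

## Laminar analysis

CSD uses the n-step second spatial difference with the step s = n·Δz in
the denominator, (V₊ₙ + V₋ₙ − 2V)/s², which converges to ∂²V/∂z² for any
n (default n = 2); the top and bottom channels are duplicated n times
(Vaknin padding) so every input channel gets an estimate. Sinks are
negative. Spectrograms use the complex Morlet CWT (PyWavelets); band
power is the summed spectrogram magnitude over the band rows within the
early (0–60 ms) and late (100–200 ms) windows — the figure-level variants
(0–50/100–250 ms) are reachable through the window arguments. The
relative laminar power profile divides each frequency column of the
per-channel Welch PSD matrix by its maximum over channels. The late-sink
bootstrap resamples 20 trials per late-wave class (with replacement),
averages, takes the CSD, and records the most negative superficial-channel
CSD value in the late window; "superficial" defaults to the top third of
the probe and is configurable, since the anatomical span of L2/3 is
dataset-specific.

## Behavior

The whisker angle is measured from the tip label relative to a reference
point on the whisker pad; whisking phase is the analytic-signal phase of
the 1–30 Hz band-filtered angle, with phase 0 at maximal protraction.
Bending is the Menger curvature of the three distal labels. Touches are
entries of the tip label into the ROI polygon (consecutive in-ROI frames
are one episode); the interval filter keeps the first touch and any touch
> 100 ms after the last kept one, and is idempotent. D′ = Z(hit) −
Z(false alarm) with rates of exactly 0 or 1 clamped to 1/(2N).

## Balanced-state spiking network

Conductance-based leaky integrate-and-fire neurons, 80 % excitatory, on a
lattice over a periodic 2×2 mm sheet; forward Euler at dt = 0.1 ms with
delayed spike delivery through a circular event buffer. Each cell makes
320 synapses drawn from a Gaussian offset kernel; every synapse delays by
τᵢⱼ = τ_s + dᵢⱼ/ϑ_c (τ_s = 0.5 ms). After a 50-ms Poisson kick the
network receives no external input.

The default operating point was calibrated once so that the scaled-down
network (19,881 neurons) self-sustains the asynchronous-irregular state
for the full simulated duration:

| parameter | value | note |
|---|---|---|
| τ_m | 10 ms (C = 100 pF, g_L = 10 nS) | faster membranes shorten the per-hop integration lag |
| E_L, V_thresh, V_reset, E_E, E_I | −60, −50, −60, 0, −80 mV | standard cortical values |
| τ_E = τ_I | 5 ms | slower inhibition (10 ms) raises CV ISI to ~1.6 |
| g_E, g_I | 2, 63 nS | many-weak-synapses regime at in-degree 320 |
| σ_E, σ_I | 0.15, 0.08 mm | local inhibition stabilizes slow conduction |
| ϑ_c | 0.05 m/s | see below |
| refractory | 5 ms | |

Diagnostics at these defaults (5-s runs): mean rate ≈ 6 Hz, CV ISI ≈
1.05, mean pairwise spike-count correlation ≈ 0.001.

Two scaled-size effects shaped the calibration. First, the self-sustained
low-rate state lives between extinction and a high-rate attractor; with
few strong synapses (in-degree 80) the 2×2 mm sheet goes extinct within
seconds, while in-degree 320 with proportionally weaker synapses holds
the state on every seed tested. Second, the per-hop latency of activity
propagation is dominated by synaptic/membrane integration (~3 ms), so the
emergent wave speed saturates near 0.03–0.04 m/s regardless of ϑ_c; only
when the conduction delay dominates (ϑ_c ≈ 0.05 m/s over σ_E = 0.15 mm
hops, stabilized by shorter-range inhibition) does the detected wave
speed track the conduction speed (measured median ≈ 0.65·ϑ_c). At full
biological scale (450k neurons, 4×4 mm) the same saturation argument
permits faster ϑ_c; the 0.05 m/s default is this package's scaled-down
operating point, not a physiological claim.

The simulated LFP sums |g_E(E_E − V)| + |g_I(E_I − V)| over non-overlapping
pools of 20×20 neurons at 1 kHz (10×10 pools are configurable but at this
density their phase noise roughly doubles the estimated wavenumber). The
pooled signal feeds the standard `WaveDetector` unchanged.

Feedback is a 20-ms Poisson volley onto a 0.4-mm patch with a fraction
p_target_inhibitory (default 0.8) of the drive routed to the patch's
inhibitory cells. When no onset is given, a baseline run locates the
first prominent patch-rate peak (a wave passing over the patch) and the
paired run centres the volley on it; the two runs share all other
randomness, and spikes are bit-identical before the window. Inhibitory-
biased feedback lowers the fraction of patch neurons spiking during the
wave pass (10/10 seed pairs at defaults), and in the 20 ms after
cessation both E and I patch rates dip below the pre-onset baseline —
the inhibitory-stabilization signature. The dip is transient; windows
longer than ~30 ms average it away against the rebound.

## Synthetic data: what passing tests show

Generators use additive white Gaussian noise, independent across
channels/cells, and idealized waveforms (pure phase-propagating
sinusoids, half-sine evoked bumps, exponential calcium kernels, sinusoidal
whisking). Passing the benchmarks therefore establishes algorithmic
correctness — parameter recovery, null calibration, exactness of closed-
form statistics — under the stated noise model. It does not establish
robustness to 1/f background, movement artifacts, electrode impedance
heterogeneity, neuropil contamination, or overlapping/partial ensemble
membership; those need real recordings. Default geometry (8×8 grid,
0.2-mm pitch, 1 kHz) is a plausible surface-grid layout, not a measured
device. Problem sizes in the test suite (1.5–5 s records, 200-cell
rasters, 20-seed sweeps, 50-surrogate nulls in tests vs the 1000-shuffle
default) were chosen to keep the full suite a desk-scale run on one CPU.
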