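# Methods

This note documents the models, estimators and design choices behind
`pnisig`, in the order data flows through the package.

## Synthetic data generator

The generator exists so that every estimator in the package can be tested
against known ground truth. It emulates the statistical structure of
multichannel recordings from a cuff-style array on a small nerve, not their
biophysics: no cable or axon models, no realistic birdsong audio.

**Baseline noise.** Band-limited Gaussian noise: white Gaussian samples are
shaped by a zero-phase 4-pole Butterworth band-pass and rescaled per channel
to the preset RMS exactly. Two named presets bracket the effect of
electroplating the electrode sites: `pre-plating` (10 µV RMS, which puts
peak-to-peak noise above 60 µV in a 1 Hz–7.5 kHz bandwidth over tens of
seconds) and `post-plating` (1 µV RMS, peak-to-peak below 10 µV). Gaussian
noise has no 1/f excess, mains hum, or movement artifact; detector
calibration results on this noise therefore say nothing about robustness to
structured interference.

**Acute stimulation sessions.** Stimuli are spaced `isi_s` apart (default
1 s, i.e. 1 Hz delivery of biphasic 200 µs/phase pulses, signed currents
with positive = cathodic-first). Each stimulation event contributes:

* a biphasic square artifact (±`artifact_amp`, default 200 µV, one phase
  duration each) with an exponential tail (τ = 0.08 ms) — only its removal
  is tested downstream, so the exact shape is immaterial;
* an evoked compound-action-potential waveform modeled as a Gaussian
  derivative (biphasic, antisymmetric, normalized to peak +1/trough −1);
  channel kernels differ in width (σ from 0.18 to 0.32 ms) and polarity to
  emulate channel-unique response components. Waveform amplitude is
  `block_factor` × 4PL(|I|) with the ground-truth recruitment sigmoid
  (defaults Vmin 0, Vmax 100 µV, I50 35 µA, slope 5 µA, hence 95%
  saturation at 35 + 5·ln 19 ≈ 49.7 µA, and peak-to-peak plateau
  ≈ 200 µV); at exactly 0 µA the amplitude is gated to zero (no pulse, no
  response). `block_factor` emulates pharmacological conduction block
  (1 = saline control, ≈0.02 = lidocaine);
* onset latency = conduction distance / velocity, with distance 20 mm and
  per-trial velocity uniform on 4–24 m/s (the conduction-velocity range of
  4–6 µm myelinated fibers), so latencies span 0.83–5 ms. Latencies in the
  slowest decile fall partly outside the 0.75–4 ms response window; this
  attenuates measured Vpp uniformly across currents and so does not bias
  the recovered saturation current.

A single integer seed expands into independent per-trial substreams through
`numpy.random.SeedSequence`, making sessions bit-reproducible.

**Chronic singing sessions.** Each channel has a true per-millisecond
activity envelope, `w·shared + (1−w)·unique(channel)` with shared weight
`w` (default 0.8); envelopes are smooth non-negative curves (Gaussian-
filtered noise, 15 ms scale, mean 1). The multi-unit signal is an
inhomogeneous Poisson spike train whose rate follows the channel envelope
(default 200 events/s, 1 ms biphasic spike kernel, per-spike amplitudes
uniform in 0.6–1.4 × 60 µV). The spike pattern is drawn **once per (seed,
channel)** in template time; each rendition warps that fixed pattern with
its own random monotone time map and adds fresh noise. Consequences:

* with zero warp jitter and zero noise, renditions are sample-identical
  (full stereotypy limit);
* consecutive days generated from one seed are statistically stationary
  (the day index only advances the warp/noise substreams), which is the
  null condition needed for day-over-day calibration experiments;
* rendition-to-rendition spiking variability of real multi-unit data is
  *not* emulated — variability here comes from tempo warps and recording
  noise only.

Warps are piecewise-linear monotone maps with knots every 50 ms and segment
slopes uniform in [1−jitter, 1+jitter] (default jitter 0.1, i.e. ±10% local
tempo), chosen to be smooth, invertible and recoverable by DTW. The song
itself is represented by a per-ms amplitude-envelope template warped with
the same map per rendition; optional audio is that envelope modulating
white noise.

## Preprocessing

Common-mode subtraction removes the per-sample across-channel mean (shared
pickup and movement artifact); it is idempotent and annihilates any signal
common to all channels. Band-pass filtering is forward-backward
(zero-phase) IIR — Bessel 1 Hz–10 kHz order 4 for the acquisition-style
chain, Butterworth 0.3–6 kHz order 2 for analysis — with odd-reflection
padding of at least three time constants of the low cutoff to suppress edge
transients. Activity envelopes are the squared signal averaged in a 20 ms
boxcar advanced 1 ms; bins whose boxcar would extend past the trace are
dropped (no partial windows, so edge bins never bias correlations).
Baseline-noise metrics (RMS, Vpp) are computed after band-passing with a
settling margin (3 low-cutoff time constants, capped at 10% of the trace)
trimmed from each end; the power spectrum is a Welch estimate (1 s
segments, 50% overlap, Hann).

## Evoked-response analysis

Trials are −5 … +25 ms snippets aligned on the stimulation-artifact onset,
re-detected as the first sample within ±1 ms of the commanded time at which
any channel exceeds 8× its pre-stimulus SD (falling back to the commanded
time when no artifact is present). The artifact span (−0.1 to 0.75 ms) is
blanked by linear interpolation; samples outside it are untouched, so the
response window (0.75–4 ms) is bit-identical before and after blanking.
Response amplitude is per-channel max − min inside the window, averaged
across channels (or per selected channel).

**Detection.** The statistic is SNR = RMS(response window) / RMS(full
pre-stimulus window) on the trial-averaged trace. The pre-stimulus window
ends 1 ms before onset: zero-phase filtering smears the artifact
symmetrically in time, and the 1 ms guard keeps the noise estimate clear of
that backward smear. The null distribution is a bootstrap over the
pre-stimulus interval: in each of `n_boot` resamples, the "signal" segment
is the average of response-window-length blocks drawn at random offsets
from the pre-stimulus interval of m = n/2 trials sampled without
replacement, rescaled by √(m/n) so its variance matches an n-trial average;
the "noise" segment is the pre-stimulus interval of all trials (whose
average is draw-invariant). A response is detected when the observed SNR
exceeds the upper bound of the central 90% null interval (one-sided:
a response can only raise SNR; the sidedness is recorded in the result
metadata).

The m-out-of-n subsample is a deliberate calibration choice. Drawing trial
indices *with replacement* forces repeated trials to contribute heavily
overlapping blocks (the usable pre-stimulus interval is only ~4 ms against
a 3.25 ms block), which inflates the null spread and makes the detector
strongly conservative (~97% coverage at a nominal 90%); a pure permutation
(each trial exactly once) leaves only block offsets varying and slightly
narrows the null (~87–88%). The variance-matched subsample restores
across-trial resampling variance without overlap inflation; in a
1500-session calibration study on null recordings it gave 89.3% ± 0.8
coverage and a 5.3% one-sided false-positive rate at the 90% level. The
residual ≈1% undercoverage is accepted and visible in the reported
numbers. Both alternative schemes remain selectable
(`trial_resampling="permute" | "replace"`).

**Recruitment.** Trials are binned on |current| into half-open 5 µA bins;
per-bin mean Vpp is fitted with the 4-parameter logistic by bounded
least-squares (Vmin ≥ 0, I50 inside the observed current range, slope > 0)
from five I50 starting points at evenly spaced quantiles of the bin
centers, keeping the best converged solution; tolerances are 1e-15 so
noiseless 4PL data are recovered to ≤1e-6 relative error. Flat data or
failure of every start raises a fit error rather than returning a
degenerate curve. The saturation ("plateau") current is where the fitted
curve reaches Vmin + 0.95 (Vmax − Vmin).

**Condition comparisons** (e.g., saline / lidocaine / washout) use a
repeated-measures one-way ANOVA (statsmodels `AnovaRM`) on per-subject
means, followed by control-referenced Dunnett post-hoc tests
(`scipy.stats.dunnett`) at α = 0.05. All-identical inputs return F = 0,
p = 1 explicitly (the RM-ANOVA ratio is 0/0 there).

## Song alignment

The alignment feature is the smoothed (5 ms) log amplitude envelope of the
audio at 1 ms resolution; the simulator supplies this feature directly. A
template is the element-wise mean of the first 25 renditions after linear
resampling to their median length (the day-1 block convention). DTW
minimizes summed squared differences of per-sequence z-scored features
(z-scoring buys amplitude invariance across days) over paths with steps
{(1,0), (0,1), (1,1)} inside a Sakoe-Chiba corridor of half-width
`band` × max(m, n) (default 0.2) around the length-scaled diagonal; an
infeasible corridor raises an error rather than silently widening.
Backtracking breaks cost ties deterministically: diagonal first, then the
rendition-advancing step. The implementation is verified against exhaustive
path enumeration for all length pairs up to 6. Applying a warp assigns each
template bin the mean of the rendition bins mapped to it, with no temporal
(premotor) offset.

## Chronic stability metrics

Envelope similarity is plain Pearson correlation (undefined, and raised as
an error, for zero-variance envelopes). The within/across partition takes
all rendition pairs — same-channel pairs as "within", different-channel
pairs as "across" (simultaneous pairs are not excluded) — and compares
per-subject means with a two-tailed paired t-test. The running stability
series correlates the mean envelope of the first 25 renditions with a
25-rendition sliding window (advance 1); the day-1 self-consistency point
uses two consecutive 25-rendition blocks. Day-referenced daily metrics
exclude the reference block from the reference day's own average, so the
reference day is not favored by construction. Event rates count upward
envelope threshold crossings (rise from below to at-or-above), with the
threshold unique to each motif at mean + 5 SD of its own envelope, divided
by the motif's unwarped duration; no debounce is applied, and the rate is
invariant to positive affine rescaling of the envelope. Day 1 vs last day
is a per-metric two-tailed paired t-test across channels.

A structural caveat found during calibration: when rendition tempo warps
are shared by all channels (song tempo is global), per-channel daily
metrics cluster at the day level and the cross-channel paired t-test
becomes anticonservative — with ground-truth alignment and no implementation
error at all, rejection rates reached ~25% at a nominal 5%. The type-I
calibration experiment therefore runs with zero warp jitter, where
channel-independent recording noise is the only variability and rejections
measure ≈4–5%. On real data the same clustering argument applies whenever
day-level nuisances (arousal, posture, temperature) move all channels
together; the paired test's p-values should then be read as descriptive.

## Electromechanics

Pure closed forms at the device design point: bending strain ε = d_N/BR;
neutral plane of the 45/30/30 µm elastomer stack at half the total
thickness under the uniform-modulus assumption (metal films treated as
zero-thickness markers — composite-beam weighting is out of scope), giving
film offsets of 7.5 µm (L1) and 22.5 µm (L2); first-order Poisson
thickness t = t₀(1 − ν ε) with ν = 0.5 (incompressible elastomer,
uniaxial strain assumed); disc area π(d/2)²; current density I/area
(1 µA/µm² = 1000 mA/mm²) and charge per phase I·t; impedance fold change;
Ohmic voltage V = I·Z against a 10 V stimulator compliance limit.

## Problem sizes and runtimes

The Monte-Carlo experiments use deliberately scaled problem sizes chosen to
give stable statistics at interactive runtimes on one CPU: detector
calibration uses 500 null sessions of 16 trials with 2000 bootstrap
resamples; recruitment recovery uses the full acute preset (21 currents ×
40 trials) over 20 seeds with 50 ms inter-stimulus spacing (trials are
independent, so spacing does not affect any measured quantity, only the
length of the generated trace); chronic experiments use 4–6 channels,
300 ms motifs, 8–40 renditions/day at 8 kHz sampling with a matching
1 Hz–3 kHz noise band. Acute defaults (24.4 kHz sampling, 1 Hz stimulation)
remain those of the acquisition convention.

## Known limitations

* The generator's noise is Gaussian and stationary; artifact shapes are
  schematic; multi-unit spiking is frozen per channel within a seed (see
  above). Passing tests demonstrate estimator correctness under these
  conditions, not robustness to real-world interference.
* The DTW feature and step set stand in for a previously described
  alignment method whose exact feature set is not re-derivable here; both
  are configuration-exposed.
* The bootstrap detector retains ≈1% undercoverage at the 90% level with
  16-trial sessions and a 5 ms pre-stimulus window; longer pre-stimulus
  context would remove the constraint.
* `within_across_summary` with a single subject returns means without a
  paired test (the test needs ≥2 subjects).
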