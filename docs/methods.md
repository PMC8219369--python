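# Methods

`szloop` re-creates, on fully synthetic data, the computational chain of a
closed-loop optogenetics experiment in chronically epileptic mice: online
electrographic seizure detection from hippocampal LFP, randomized
stimulation of half of the detected seizures, quantification of
stimulation-locked oscillatory entrainment, and the endpoint statistics on
seizure durations.  This note documents the models, the defaults and why
they were chosen, the numerical decisions, and what the synthetic study
conditions do and do not establish about real recordings.

## Synthetic LFP model

### Background activity

Background LFP is the sum of two components, scaled so the total standard
deviation is `amplitude_sd` (default 50 µV):

* **broadband noise** with power spectral density ∝ 1/f^`noise_exponent`
  (default exponent 1), produced by spectral shaping of white Gaussian
  noise;
* **a theta oscillation** at `theta_freq` (default 7 Hz) carrying
  `theta_power` (default 0.3) of the total variance.  The oscillation's
  phase performs a Brownian walk with diffusion `theta_phase_diffusion`
  (default 0.3 rad²/s).  The diffusion term matters: a phase-coherent
  sinusoid would have an identical phase at every stimulation epoch (the
  inter-epoch spacing times the theta frequency is an integer number of
  cycles), which fabricates trial-to-trial phase clustering and inflates
  baseline PLV from ≈0.08 to ≈0.5.  With diffusion, theta decorrelates over
  a few seconds, as a biological rhythm does.

Every generator is a pure function of its parameters and one integer seed;
the master seed is split per component (noise, theta, event times,
durations, epoch phases) with `numpy.random.SeedSequence.spawn`.

### Stimulation and the phase-locked response

The LED channel is binary 0/1: trains of `round(pulse_width·fs)`-sample
square pulses at 10 Hz for 30 s, 120 epochs, 90 s between epochs, with one
full inter-epoch gap before the first train so every epoch has an
immediately preceding baseline window of equal length.

Septal-drive entrainment is modelled at the population level.  During each
stimulation epoch a sinusoid at the pulse rate is added to the LFP whose
phase lag to the LED fundamental is drawn once per epoch from a von Mises
law with concentration κ (`locking_strength`), and whose amplitude is

    A(κ) = locked_amplitude_sd × amplitude_sd × R(κ),   R(κ) = I₁(κ)/I₀(κ).

R(κ) is the mean resultant of the von Mises law — the coherent amplitude
that survives averaging over a population of oscillators each locking with
concentration κ.  Scaling by R(κ) makes *both* entrainment readouts grow
with κ: phase clustering across trials (PLV) and narrow-band 10 Hz power
(the entrainment ratio).  A fixed-amplitude tone would leave the power
ratio flat in κ, since a periodogram is blind to the epoch phase.  At κ = 0
the amplitude is zero and the LFP is independent of the LED by
construction; `locked_amplitude_sd` defaults to 4 (strong, clearly visible
entrainment at full locking).

### Electrographic seizures

Seizure onsets follow a Poisson process at `event_rate` (default 12/h, at
the frequent end of chronic intrahippocampal-kainate models, chosen so that
a few simulated hours yield statistically useful event counts).  Durations
are log-normal with median 25 s and log-SD 0.45 — heavy-tailed, median well
above the 3 s a detector needs for three full intervals.  A seizure is a
train of alternating-sign raised-cosine (40 ms Hann) deflections at
`spike_rate` 8 Hz with peak amplitude `spike_amplitude` × background SD
(default 5), with a 1.5 s linear amplitude ramp at onset and offset.
Discrete large deflections — rather than filtered noise — are what drive
all four detector features the way real discharges do.  Overlapping drawn
events are merged; a warning is raised if events cover more than half the
trace.

These defaults exercise the detector; they are not fitted to any animal's
seizure morphology (none is published at this quantitative level).

## Seizure detection

The LFP is analysed in non-overlapping 1-s intervals aligned to the start
of the recording.  Per interval:

1. **coastline** Σ|v[k+1] − v[k]| (µV);
2. **intermittency** — the fraction of the coastline contributed by the
   `ceil(0.10·n_steps)` largest steps (the ceiling guarantees at least one);
3. **spikiness** — max over 19.6-ms bins (floor(0.0196·fs) samples,
   remainder dropped; 10 samples at 512 Hz) of the bin voltage range,
   divided by the median bin range; defined as 1 when the median is 0;
4. **coherence** — the interval is mean-referenced; local extrema are
   paired in temporal order into disjoint (peak, trough) pairs, ranked by
   peak-to-trough amplitude; each pair's span runs to the midpoints toward
   its neighbouring extrema (so an isolated cycle owns the full area around
   its peak and trough, and a pure sine of n cycles scores min(1, 10/n));
   the summed |v − mean| over the top-10 spans is divided by the total,
   capped at 1.

Coastline is amplitude-equivariant; the other three are amplitude-invariant
— checked by property tests and against naive-loop oracles.

Raw features are mapped through per-feature logistics
1/(1 + exp(−(x − centre)/scale)).  The calibration is data-driven: centre =
midpoint of the baseline and seizure medians, scale = half the pooled
interquartile range, fitted on a training recording with known seizure
intervals.  An interval is classified as seizure when some library entry
lies within 0.1 of it on **every** feature (per-metric Chebyshev rule,
boundary inclusive).  Three consecutive positive intervals raise a seizure
timestamp; the event onset is the first of the three.  Offline, the offset
extends to the last positive interval before a run of more than
`gap_tolerance_intervals` (default 2) negatives — an automated surrogate
for expert offline duration review.

**Library curation.**  The library is built from all 1-s intervals lying
fully inside training-truth seizures, then curated: entries with fewer than
3 of 4 sigmoid features above 0.5 are dropped (typically the first/last
ramp second of an event, ~3% of entries).  Without curation a handful of
baseline-like templates make the nearest-entry rule match ordinary
background (tens of false events per hour); with it the false-timestamp
rate on seizure-free background is ≈0/h while recall and duration fidelity
are unaffected.  `curate=False` restores the uncurated contract.

## Closed-loop controller

Classification of each 1-s block uses only that block's samples, so the
decision stream is causal; truncating the input never changes earlier
decisions.  After a timestamp, further timestamps are locked out for one
refractory period (default: the 30-s train length), so each seizure is
randomized exactly once: one Bernoulli(0.5) variate is consumed per
emitted timestamp, in detection order, from a seeded stream, and a
positive draw emits a 30-s train.  The lockout matters beyond
train-overlap hygiene: a long discharge that re-satisfies the
three-interval rule after a brief classification gap would otherwise draw
extra variates, making stimulation probability increase with seizure
duration — and since the interval following a seizure equals the
inter-onset gap minus its duration, that bias masquerades as a
post-stimulation change in seizure *rate*.  With the lockout, the
interseizure-interval endpoint is null under duration-only effects, as it
should be.

The stimulation effect used for end-to-end power checks truncates each
stimulated seizure to `multiplier` × its remaining duration after train
onset (`multiplier` 0.6 for opsin cohorts, 1.0 = exact null).  Observed
durations are then read from the modified ground truth, standing in for
blinded offline review.

## Entrainment quantification

Instantaneous phase is the angle of the analytic signal (Hilbert
transform) of the mean-removed trace, computed over the *whole* continuous
recording and then sliced into epochs — keeping Hilbert edge artefacts
outside the 30-s windows.  Per timepoint τ,

    PLV(τ) = | n⁻¹ Σ_trials exp(i(φ_LED(trial, τ) − φ_LFP(trial, τ))) |,

averaged over τ within condition; the baseline mean is subtracted from the
stimulation mean.  With n independent trials the null expectation of PLV is
√π/2·n^(−1/2) ≈ 0.081 at n = 120, which baseline subtraction removes.

Spectra are one-sided rectangular-window periodograms (mean removed, no
further detrending), satisfying Parseval.  The entrainment ratio is the
cumulative PSD in [9, 11] Hz over [3, 13] Hz, endpoints inclusive, bins
assigned by centre frequency; efficiency is the median over epochs of the
paired stimulation-minus-baseline ratio.  For a flat spectrum the ratio is
the bandwidth fraction ≈ 0.2; a pure 10 Hz (5 Hz) tone gives ≈ 1 (≈ 0).

## Endpoint statistics

All tests are two-sided.  Per animal, light-on vs light-off duration
distributions are compared with a two-sample Kolmogorov–Smirnov test, and
the normalized change is (median_on − median_off)/median_off.  Across
animals: paired Wilcoxon signed-rank on per-animal medians — exact
distribution for ≤ 25 pairs (small-n fidelity matters at n = 7), normal
approximation with continuity correction above; all-zero differences
degenerate to (W, p) = (0, 1).  Normalized changes of opsin vs control
cohorts use a two-sample t-test, Welch form by default (safer at 4 vs 7
animals; the pooled form is available by flag).  The interval following
each seizure (offset to next onset, trailing interval dropped) is assigned
to that seizure's condition and per-animal medians are compared by paired
Wilcoxon.  Median Racine severities (validated to lie in 1..6) are compared
with a paired t-test.

Type-I calibration (rejection rate in [0.02, 0.09] at α = 0.05 over 1000
null replicates for each endpoint test) is verified on event-level null
cohorts drawn from the same seizure model — Poisson onsets, log-normal
durations, Bernoulli flags, multiplier 1.0 — which is distributionally
identical to the full signal pipeline's event table under the null and
cheap enough to replicate a thousand times.

## Problem sizes and numerical choices

* Test-suite simulations use 2–6 h recordings at 512 Hz, a 2-h training
  recording for the library, 3 replicate sessions per κ for the
  dose-response sweep, and 4–6 h per animal for the 7 + 4 cohort — sizes at
  which every contract is measured with comfortable margins on a single
  CPU.
* EDF export quantizes to 16 bits over each channel's observed range;
  round-trips agree within one quantization step.  Constant channels are
  written with a widened physical range to avoid zero gain.
* Degenerate inputs: flat intervals return intermittency 0, spikiness 1,
  coherence 0; constant signals have no defined phase (error); zero
  wide-band power defines the entrainment ratio as 0 with a warning.
* Ties in the coherence pair ranking are resolved by stable sort order;
  for continuous-valued data exact ties have probability zero.

## Limitations

The generator reproduces the statistical structure the analyses assume —
spectral shape, rhythmic discharges, heavy-tailed durations, per-epoch
phase locking — not hippocampal biophysics.  Passing tests demonstrate
that the implementations recover known ground truth under these
conditions; they do not certify detector performance on real mouse LFP,
where artefacts, state-dependent background, and seizure-morphology
diversity are all richer.  The severity endpoint consumes simulated Racine
scores and only checks statistical plumbing.  Wireless-arm single-channel
operation is assumed throughout; no multi-channel fusion is attempted.
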