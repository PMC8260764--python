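# Methods

This note documents the models, conventions and numerical choices behind
`ceaphys`, in the order data flows through the pipeline.

## Experiment timelines

A protocol is an ordered list of sessions, each an ordered list of
stimulus events (`cs`, `pip`, `us`, `light`) with onsets and durations in
seconds, intervals half-open `[onset, onset + duration)`. The standard
paradigm is: habituation (4 CS, context B), fear conditioning (5 CS+US,
context A, US onset at CS offset), two extinction sessions (12 CS each,
context B), retrieval (4 CS, B) and renewal (4 CS, A). Discriminative
(two-CS), 16-CS and optogenetic two-CS templates are also provided.

The CS is a 30-s train of 50-ms pips at 0.9 Hz. Whether the first pip
coincides exactly with CS onset is not observable from the session
documentation we model; we adopt the convention that pip *k* starts at
`k / rate` from CS onset and is included iff it ends by CS offset. This
yields 27 pips per CS and 108 per 4-CS block, consistent with the
protocol's printed totals, and pip counts are invariant to the
inter-trial intervals, which are drawn uniformly from 20–180 s under a
caller-supplied seed. In optogenetic extinction sessions every pip of
the 5th–16th presentation of each CS carries a light event from −50 ms
to +300 ms around pip onset.

## Synthetic data

The generator emulates the statistical structure the analyses assume; it
is not a biophysical model.

* **Spike trains** are inhomogeneous Poisson processes, simulated by
  thinning a homogeneous process at the maximum rate (exact for
  piecewise-constant intensities). Each phenotype has a baseline rate
  (default 10 Hz — recorded baselines are not published, so this is a
  free parameter chosen as a plausible CEA tonic rate) and a per-state
  gain applied inside `[pip + latency, pip + latency + 0.25 s]`.
  Default gains: CElon ×3 post-conditioning and ×1.3 post-extinction;
  CEloff ×0.2 / ×0.7; CEm ×3 / ×1.4; an `s1_persistent`
  (extinction-resistant) state keeps the post-conditioning gain. These
  are qualitative defaults reproducing the sign and reversal of the
  recorded classes, not measured values. An absolute refractory period
  (default 2 ms, by deletion) makes trains pass the autocorrelogram
  criterion; it introduces ~4% count underdispersion at 10 Hz, which
  the baseline-normalized z absorbs because numerator and denominator
  shrink together.
* **Waveforms** are a fixed template plus i.i.d. Gaussian sample noise.
* **Movement traces** are binary at a configurable sample rate; the
  scheduled immobility intervals are exactly the zero runs, so scorer
  round-trips are exact by construction.
* **Phototagged units** are Poisson at baseline except
  `[pulse onset + latency, pulse offset]`, where the inhibited rate
  applies.
* **Morphologies** are node/parent plans rendered to SWC trees, with
  optional positional jitter (off by default, hence deterministic).

What the generator does **not** emulate: bursting and serial ISI
structure, slow drift and nonstationarity, waveform amplitude
modulation, overlapping spikes during light, video-based freezing noise,
or tissue-shrinkage artefacts in reconstructions. Passing tests
therefore validate the analysis arithmetic and its calibration under
the assumed model, not robustness to these real-data features.

## PSTHs and the z transform

Trials are individual pips (the pip-locked rasters motivate this; a
per-CS alternative would be a one-line change where the block's trial
indices are built). Counts use 50-ms half-open bins over ±500 ms around
pip onset; the baseline is the ten bins in [−0.5, 0) s, pooled over the
block's trials, with the sample (n−1) standard deviation.

Two z scales are exposed:

* `scale="sd"` — the raw transform: values standardized by the pooled
  single-trial baseline SD. With one trial per block this reproduces the
  textbook example (baseline {1,2,3,2}, response 4 → z = 2.449), and
  applied to single-trial counts (`trial_zscores`) it is the natural
  null-calibration view (baseline-bin z ≈ N(0,1)).
* `scale="sem"` — the calibrated transform used for significance
  classification: the block-averaged bin counts are standardized by the
  exact standard error of `mean_b − μ_base`,
  `σ_base · sqrt(1/n + 1/(n·n_base_bins))`, so the statistic is
  standard normal under a stationary unit for any trial count. Without
  this, a 108-trial block mean has a sampling SD ~10× smaller than the
  single-trial SD and a fixed threshold has no calibrated meaning.

A zero baseline SD yields an invalid (NaN) result and the unit is
flagged unclassifiable rather than silently scored 0.

## Classification

A unit is responsive when |z| ≥ 1.96 (`scale="sem"`) in at least one of
the five bins in 0–250 ms post-pip of the reference epoch — the first
4-CS block of extinction day 1, when conditioned responding is
expressed. No multiple-bin correction is applied, following common
practice in this literature; the family-wise null call rate is
therefore ≈ 1 − 0.95⁵ ≈ 0.22 (measured 0.217 ± 0.003 by simulation),
which bounds the achievable specificity of the non-responsive label.
Ties between equal-magnitude extremes break toward the earlier bin; the
threshold and a peak-only criterion are configurable. Responsive CEl
units are CElon/CEloff by sign; responsive CEm-region units are CEm.
Reported proportions round half-up to integer percentages.

## Spike-sorting QC

J3 uses squared Euclidean scatter (J2/J1, between over within); DB is
the standard Davies–Bouldin index with mean distances. Point-mass
within-scatter or coincident centroids return an `inf` marker. Because
the commercial sorter's exact J3 normalization is unpublished, absolute
J3 values are comparable only within this implementation; the
artificial-cluster null (random hyperplane bisections of a centred
cloud, orientation uniform on the sphere, 1000 splits by default)
provides the reference distribution. The refractory check reports the
fraction of ISIs under 1 ms plus a ±50-ms, 1-ms-bin autocorrelogram.
Duplicate detection operationalizes "a peak where the reference fires"
as any cross-correlogram bin within ±1 ms of zero lag exceeding the
10–50-ms flank mean by 5 flank SDs; when flagged, the unit with fewer
spikes is dropped. Exclusion order in the pipeline: duplicates →
refractory → undefined baseline, first applicable reason recorded.

## Phototagging

Light responsiveness is a paired sign-flip permutation test (default
1000 shuffles, α = 0.01) of in-pulse spike counts against
duration-matched immediately-pre-pulse baselines, which controls slow
drift; the underlying statistical test in the original workflow is not
published, so the permutation test is this package's choice. Onset
latency uses CUSUM change-point analysis of the pulse-averaged 1-ms
rate series over [−0.1, +0.3] s: the cumulative sum of deviations from
the series mean peaks at the last pre-change bin, so the change time is
the right edge of the argmax-|CUSUM| bin; significance compares the
CUSUM range against permutations of the series (default 1000, α =
0.05). A single change point suffices for onset latency. The <10-ms
time-locking criterion applies to excitatory tagging; for Arch
inhibition the latency is reported without a hard cut, matching the
reported latency distributions. Inhibition magnitude is the percent
rate change in light versus the pre-pulse baseline; when a significant
change point exists, the in-light window starts at the estimated onset
so a slow latency does not dilute the measured modulation (a 15→1.5 Hz
unit with 20-ms latency then measures −90%, not −85%).

## Behaviour

Freezing is any maximal immobility run ≥ 2 s; a qualifying bout
contributes its entire duration (including the first 2 s — the
detection-threshold convention is ambiguous in beam-break descriptions,
and this choice is recorded here). Epoch percentages are overlaps of
qualifying bouts with the epoch. The 50% spontaneous-recovery cut-off
retains subjects with strictly `< 50%` CS freezing at retrieval.
Repeated-measures ANOVA (one or two within factors) is computed by
pingouin behind this module's interface; Greenhouse–Geisser correction
is off by default (uncorrected df are the convention here) and
available behind a flag. Bonferroni post-hocs are two-sided paired t
tests versus a reference condition with `p_adj = min(1, k·p)`.

The pipeline's synthetic behaviour targets group means of ~26% CS
freezing at habituation, ~62% at early extinction and ~34% by late
extinction (no-CS ~20%), with 8%-SD subject offsets and 6%-SD epoch
noise.

## Morphometry

Sholl intersections are counted against concentric spheres at 10-µm
steps, with Euclidean (not path) distance from the soma root node, per
the classical definition; a piecewise-linear segment straddling a
sphere counts once, and a tangential segment dipping inside with both
endpoints outside counts twice. Dendrite count is the number of soma
children; terminal branches are the unbranched paths ending at tips.
SWC is the interchange format, written with full float precision so
round trips are bit-exact.

## Problem sizes and determinism

Default analyses run on: 60-unit synthetic populations (20/10/10/20 per
class) over habituation plus two extinction sessions; 10,000-unit null
calibrations; 200-pair duplicate nulls; 50-seed phototag recovery; and
1000-replicate ANOVA null uniformity — sizes chosen so the full suite
completes in well under a minute per stage on one core. Every stochastic
component takes an explicit seed (numpy `default_rng` /
`SeedSequence`); identical configurations reproduce all outputs bit for
bit.

## Known limitations

* Absolute J3 values are implementation-specific (see above).
* The classifier's non-responsive specificity is capped near 78% by the
  uncorrected multi-bin significance rule; applications needing higher
  specificity should raise the threshold or enable the peak-only
  criterion, at the cost of sensitivity.
* The freezing-level modifier of the classification rule used in the
  original workflow ("according to the freezing levels") is not
  operationalizable from the available description and is not guessed.
* Real recordings' nonstationarities are outside the generator's scope;
  see the synthetic-data section.
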