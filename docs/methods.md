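# Methods

This note documents the models, statistical procedures, numerical
conventions and design choices behind `ctxcode`, and what the synthetic
data do and do not establish.

## The experimental design being modeled

A context–probe experiment presents sequences of 1-s natural sounds. The
response to a probe sound is compared across the possible preceding
contexts: silence (sequence onset), each other sound, and the probe itself.
For N sounds this defines N(N+1) ordered (context, probe) events and
N·C(N+1, 2) *contextual instances* (one probe with an unordered pair of
distinct contexts) — 40 for N=4, 550 for N=10. Full event coverage with
minimal presentations takes N sequences of N+1 sounds whose initial sounds
are all distinct.

`stimdesign.design_sequences` solves this exact-cover problem
constructively. The ordered pairs form the complete digraph with self-loops
over the sounds; identifying sounds with residues mod N, all sequences
share one increment pattern that is a permutation of the residues, and
sequence i starts at residue i. The pair (a, b) is then covered exactly
once: at the unique step whose increment equals b − a (mod N), in the
sequence whose walk reaches a at that step. A seeded permutation of
increments and a seeded relabeling of sounds randomize the design;
`validate_sequences` re-checks the contract on every returned design. We
chose this construction over search-based exact-cover solvers because it is
O(N²), cannot fail, and is trivially seedable; any solver meeting the
coverage contract is interchangeable.

### Sound metrics

Stand-in spectrograms are 18-channel, log-spaced (≈1/3 octave per channel),
100 Hz, with narrowband / band-noise / naturalistic profile families.
Three descriptive metrics summarize a spectrogram:

- **Bandwidth** — the octave span between the 15th and 85th percentiles of
  total spectral power (the band holding the central 70%). Each channel is
  treated as a uniform bin in log2 frequency (edges midway between
  centers, end bins extended symmetrically) and percentiles are linearly
  interpolated within bins; a flat spectrum spanning 6 octaves edge-to-edge
  therefore yields exactly 0.7 × 6 = 4.2 octaves. The binning/interpolation
  convention is ours; alternatives differ by O(channel width).
- **Temporal stationarity** — the temporal standard deviation of each
  in-band channel, averaged over channels (scales linearly with amplitude).
- **Spectral correlation** — the mean pairwise Pearson r over time among
  in-band channels. Channels whose centers fall outside the 70% band are
  excluded from both.

## Synthetic recordings (`synthgen`)

The generator emulates the structure of an awake-recording dataset: I
neurons (default 20), R repeats of each sequence (default 20, the typical
repetition count for this design), spike counts at 20 Hz (50-ms analysis
bins) and 100 Hz (encoding-model bins; the 20-Hz counts are exact sums of
the 100-Hz counts, so segmenting and re-averaging are consistent by
construction).

Rates are baseline (per-neuron, ~5–15 spikes/s) plus per-sound tuned
envelopes (onset transient + modulated sustained component). Context
effects are injected per (neuron, context, probe) triple: a profile on the
20-Hz probe-window grid with a configurable shape (exponential decay by
default — effects are typically strongest at probe onset — plus
late-onset, two-peak, and flat options), amplitude drawn in Z-score·s and
duration in ms, converted to firing rate through the neuron's predicted
single-trial rate SD. A triple is modulated with probability
q = 1 − √(1 − s), so the fraction of instances whose two contexts differ
is ≈ s, the configured `effect_sparsity`. Default amplitude/duration
ranges (0.05–0.8 Z·s, 50–1000 ms) bracket the magnitudes reported for
auditory cortex (means ≈ 0.24 Z·s and ≈ 250 ms).

Noise is Poisson by default (Gaussian and noise-free options exist; the
Z-scored analysis is distribution-agnostic). Negative post-modulation
rates are clipped at zero and counted — with default settings ~1% of
samples; recovery tests use settings where clipping is negligible.
Optional ingredients:

- **Coupling** — a lagged influence matrix W: at each 10-ms step neuron i
  receives Σⱼ W[i, j] · (mean rate of j over the preceding 150–300 ms),
  generated sequentially within each trial. Negative diagonal terms give
  self-adaptation, off-diagonal terms network coupling; this is the ground
  truth probed by the encoding models.
- **Pupil** — a slow per-trial arousal trace (sinusoidal drift over
  presentation order + smoothed noise, optional within-trial component);
  neurons with nonzero pupil gain have rates scaled by
  1 + gain·(pupil z-score), a monotone modulation.
- **Cell types** — peak-to-trough delays from a two-mode mixture (0.25 and
  0.70 ms, so classification thresholds near 0.37/0.47 ms fall in the
  valley), with a narrow-spiking fraction of 0.2 and optotag flags on a
  subset of narrow cells.

**Ground truth convention.** The injected effects are re-expressed in the
analysis' own units using the *empirical* per-neuron normalization of the
generated recording (mean/SD of single-trial 20-Hz rates over the whole
recording). Under this convention the noise-free limit gives exact
equality between injected and recovered amplitude/duration, which is the
correctness anchor for the whole chain; with noise, the same quantities
are recovered statistically. Durations are multiples of 50 ms by
construction.

**What the generator does not emulate:** refractory or bursting spike-train
structure, slow nonstationarity of excitability, correlated trial-to-trial
noise beyond the explicit coupling, realistic receptive fields (tuning is
an abstract per-sound gain), and sound-evoked pupil dynamics tied to
acoustics. Tests passing on synthetic data therefore establish the
*statistical machinery* (calibration, recovery, invariants), not claims
about biological recordings.

## Context-effect quantification (`ctxfx`)

Single-trial rates are Z-scored per neuron over the entire recording
(spontaneous + evoked); zero-variance neurons are excluded with a warning.
An optional reliability filter keeps neurons whose half-split PSTHs
correlate above 0.1 at 20 Hz.

For each instance the two context conditions contribute R trials each of
the 20-bin probe window. Per bin, a two-sample Student's t (pooled
variance; Welch available — the choice is a convention, both are provided)
at α = 0.05 marks candidate bins; contiguous same-sign significant bins
form clusters scored by the summed t. The null is the distribution of the
per-shuffle **maximum** |cluster score| over random reassignments of the
pooled 2R trials to conditions (two-sided via the absolute value); cluster
p-values use the add-one estimator (1 + #{null ≥ obs})/(n_shuffles + 1),
so p ∈ (0, 1] always. Bins with zero within-condition variance get t = 0
when the means agree and ±∞ when they differ (the noise-free limit), which
propagates correctly through ranking against the finite null.

Metrics: amplitude = Σ_sig |ΔZ| × 0.05 s; duration = (last significant bin
index + 1) × 50 ms (half-open bins, 0-based, so a duration is always a
multiple of 50 ms and a bin-edge value like 450 ms is representable).
Bonferroni across each neuron's instances (α = 0.05/n_instances); for
site-level unions the threshold additionally divides by the neuron count.
Note the interaction with permutation resolution: the smallest achievable
p is 1/(n_shuffles + 1), so site-level significance at N=4 with I neurons
requires n_shuffles > 800·I; the canonical setting of 11,000 shuffles
resolves sites up to ~13 neurons at N=4 (and single-neuron correction at
N=10). Bonferroni is applied to the permutation p as computed.

The amplitude–duration association test permutes the time bins of each
profile (with their significance), which randomizes the last-bin duration
while leaving the integral amplitude untouched; the observed Pearson
r(A, D) is compared to the null distribution of r over 1000 shuffles.
Parametric (e.g. exponential) fits to effect time courses are deliberately
out of scope: profiles are routinely non-monotonic.

## Population coding (`popcode`)

Coverage is the percentage of tested instances with significant effects.
The site union takes, per instance, the largest significant amplitude
across neurons (with the neuron-count Bonferroni factor); the best neuron
is the coverage argmax (ties broken by summed amplitude, then lowest id).
`site_coverage_summary` computes mean/best/union from one shared
correction setting, under which union ≥ best ≥ mean holds by construction.
PC1 analysis fits PCA (neuron means removed) on trial-averaged responses
concatenated over sequences, keeps components to 90% variance, projects
single trials, fixes PC1's sign by positive correlation with mean
population activity, and analyzes the PC1 trace exactly like a neuron.

### Dense-code transform

Let r_{i,c,p,j}(t) be the Z-scored response of neuron i to probe p in
context c on trial j. With r̄ the context/trial average and
m_{i,c,p}(t) = ⟨r − r̄⟩_j the context modulation, the transform replaces
each population vector m⃗(c, p, t) by its diagonal image with components
sign(m̄)·‖m⃗‖₂/√I (norm-preserving; the ‖m⃗‖₂/I reading is available via
`magnitude="mean"`). The offset l = m − target is subtracted from single
trials, preserving trial-to-trial variability. The across-context variance
of trial-averaged responses is then restored by scaling the rotated
context component by ⟨v⟩_i/ṽ (the printed form; a √-ratio variant that
restores variance exactly under pure scaling is available via
`variance="sqrt"`).

Because the diagonal targets need not sum to zero across contexts — the
original modulations do, by definition — the raw rotation can shift a
neuron's context-averaged probe response. A final per-(neuron, probe, time)
offset (constant in context and trial, hence invisible to every
modulation-based quantity and to within-probe decoding geometry) restores
all mean probe responses exactly. With this step the three contract
invariants hold to machine precision simultaneously: context modulations
identical across neurons, per-(c, p, t) modulation norm preserved, and
mean probe responses preserved. No choice of diagonal targets could
satisfy the zero-context-sum and per-context-norm constraints at once, so
the explicit re-centering is the only exact resolution.

### Decoding

Per 50-ms bin, single-trial population vectors are standardized and
classified with a linear SVM (C = 1, seeded), stratified 4-fold CV,
accuracy averaged over folds; chance is 1/#classes (1/(N+1) for context,
1/N for probe). On sparse-effect simulations, the dense transform lowers
context accuracy while probe accuracy is statistically unchanged — the
operational signature that the sparse arrangement, not the magnitude, of
context effects supports readout.

## Category statistics, cell types, pupil, jackknife (`stats`)

**Category regression.** Effect metrics are divided by their grand mean so
OLS coefficients read as percent change versus the base category
(different / non-vocalization). Each instance contributes one row per
context, carrying that context's similarity (silence / same / different)
and identity labels with the instance's metric value; silence has no
identity and is assigned the base level so the similarity × identity
interaction stays estimable. Instances pairing silence with a vocalization
context can be excluded (their interaction confounds the marginal
effects). Because both rows of an instance share one metric value, the
design attenuates marginal estimates relative to a per-context generative
model; recovery tests therefore assert sign, ordering and significance of
injected effects rather than point equality. Significance is by t-tests on
the OLS coefficients (statsmodels).

**Group comparisons.** Kruskal–Wallis (scipy) with hand-implemented Dunn
post hoc z-tests on pooled ranks (tie-corrected, Bonferroni over pairs) —
no maintained Dunn implementation exists in the dependency set.

**Spike width.** Gaussian KDE (Silverman bandwidth) over peak-to-trough
delays must be multimodal; the valley between the two dominant modes ±
0.05 ms (a 0.1-ms safety band) separates narrow from broad spiking, the
band itself is unclassified, and unimodal distributions are refused rather
than guessed. Fixed thresholds (e.g. 0.37/0.47 ms) can be supplied.

**Pupil.** Trials of each instance are split at the median pupil over the
context+probe interval (rank-balanced fallback when the median is
degenerate; constant traces are an error). MI = (large − small)/(|large| +
|small|) is computed for context-averaged mean Z rates (mean Z ≥ 0.1) and
for |ΔZ| context effects of significant instances (mean |ΔZ| ≥ 0.3, signs
flipped positive before pooling), overall and in four 250-ms intervals.

**Jackknife.** Delete-one, or grouped delete-d when n exceeds the fold
count (seeded partition into 100 or 200 groups); reported SE uses the
standard (g − 1)/g factor, with a normal-quantile CI.

## Encoding models (`encmodel`)

All four variants share the architecture: prediction =
ReLU(STRF ⊛ spectrogram + w_self · h_self + Σ w_pop,j · h_j + b), with
18 spectral channels × 30 10-ms lags (0–300 ms) and history features h
averaging activity over lags 15–29 (150–300 ms before the predicted bin —
lags under 150 ms are excluded so history terms cannot proxy short-latency
stimulus drive; the STRF is extended to 300 ms for the same reason).
Targets are trial-averaged 100-Hz responses normalized to each neuron's
peak. Variants scramble the self and/or population inputs by independent
circular shifts of 10–60 s (shifts are taken modulo the recording length
with a floor of one history window; shifting rather than shuffling
preserves short-term structure so the scrambled channel is realistic but
uninformative). Parameter counts are identical across variants by
construction.

Fitting: squared error on the rectified output (the architecture specifies
the output nonlinearity and optimizer; MSE on the peak-normalized rate is
our loss choice), minimized by seeded full-batch ADAM (lr 1e-3, up to a
few hundred epochs, early stopping on a 10% in-fold slice) from a ridge
least-squares warm start — the warm start cuts fitting time by an order of
magnitude and is exact in the fully linear regime. Cross-validation holds
out one stimulus sequence per fold; performance is Pearson's R over the
concatenated held-out predictions. Model comparisons use two-sided paired
Wilcoxon signed-rank tests on absolute prediction R, Bonferroni over the
six pairs.

Context-effect prediction uses a model fitted on a separate estimation
stimulus set, predicting the context–probe recording with the *actual*
recorded histories as inputs (teacher forcing — the models describe, not
simulate, the network). Predicted and actual probe-response differences
between contexts are compared on 0–1 (min–max) normalized responses,
integrated over four 250-ms intervals (100-Hz bins 0–24, 25–49, 50–74,
75–99), restricted to instances significant in the data; per interval,
Pearson r with a 200-fold jackknife SD. The 0–1 normalization is per
neuron over the concatenated responses. Coupling summaries average the
fitted population weights by source class (outgoing) and target class
(incoming).

## Pipeline and formats

`pipeline.run_pipeline` executes design → simulate → quantify → category
stats → coverage → dense-code decoding (encoding models optional) from one
seeded `RunConfig`, writing tidy CSVs (floats rounded to 6 significant
digits so reruns are byte-identical), an HDF5 recording
(/counts, /fine_counts, /pupil, /tables/*, sequences as a JSON attribute),
and a manifest with SHA-256 checksums. Failures persist a partial manifest
naming the failed stage. Time conventions are global: half-open [start,
end) bins in seconds from sequence onset, 0-based indices, 1-s probe
windows.

## Problem sizes and tolerances

Defaults in the test suite and `scripts/acceptance.py` are desk-scale
choices: sites of 4–30 neurons, N = 4 sounds, 10–20 repeats, 200–7000
permutations (7000 where site-level Bonferroni must be resolvable at 6–8
neurons; the canonical analysis setting remains 11,000), 500–1000 null
instances for calibration, 150–400 ADAM epochs. Exact invariants
(exact-cover, noise-free recovery, dense-transform identities) are
asserted at 1e-6 or machine precision; stochastic recoveries at the
documented thresholds (amplitude correlation ≥ 0.8, duration MAE ≤ 2 bins
at per-bin |ΔZ| ≥ 1 with 20 trials; null false-positive rate 0.05 ± 0.02).

## Known limitations

- The generator's context effects are additive rate offsets specified in
  Z units; real effects may interact with tuning nonlinearly.
- The categorical regression inherits the row-duplication attenuation
  discussed above; coefficients are comparative, not generative, effect
  sizes.
- Encoding-model dissociations on coupled simulations are clean for the
  population channel; a self-history channel is intrinsically somewhat
  informative for any temporally smooth signal, so "Self ≈ STRF under
  coupling-only" holds only approximately and is not asserted.
- The permutation-resolution/Bonferroni interaction bounds detectable
  site sizes at a given shuffle count (see above); raising shuffles is the
  only remedy consistent with the correction.
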