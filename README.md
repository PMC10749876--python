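# ctxcode

Population analysis of long-lasting sensory-context effects in auditory
cortex. When a 1-s natural *probe* sound follows different 1-s *context*
sounds, many cortical neurons respond differently to the identical probe for
hundreds of milliseconds — far beyond the integration window of a classical
spectro-temporal receptive field. `ctxcode` implements the full analysis
chain for such context–probe experiments, together with a synthetic-data
generator with known ground truth so every stage is testable without access
to recordings.

The package is for computational/systems neuroscientists analyzing
trial-based population spike data (binned counts, neurons × trials × time),
and for methodologists who want calibrated reference implementations of the
component statistics.

## What it computes

**Stimulus design.** For N sounds, every ordered (context, probe) event —
context ∈ {silence, the N sounds}, probe ∈ {the N sounds} — is covered
exactly once by N sequences of N+1 sounds (an exact-cover problem, solved
constructively by a seeded difference family). A *contextual instance* is a
probe with an unordered pair of distinct contexts: N·C(N+1, 2) instances
(40 for N=4, 550 for N=10).

**Context-effect quantification.** Responses are Z-scored per neuron over
the whole recording and compared across the two contexts of each instance
at 50-ms resolution. Significance uses a cluster-mass permutation test:
contiguous same-sign bins with per-bin two-sample *t* at p < 0.05 form
clusters scored by ΣT; each cluster's p-value is the tail probability of
|ΣT| against the per-shuffle **maximum** cluster score over random
reassignments of trials to contexts, with Bonferroni correction across the
instances tested per neuron. Significant effects are summarized by

- amplitude  A = ∫ |ΔZ(t)| dt over significant bins  (Z-score·s), and
- duration  D = end time of the last significant bin  (ms).

**Population coding.** Contextual *coverage* (percentage of instances with
significant effects) per neuron, for the site union (max significant
amplitude per instance across neurons, with a neuron-count Bonferroni
factor), the best neuron, and the first principal component of population
activity treated as a pseudo-neuron. The *dense-code* control rotates each
population context-modulation vector m⃗(c, p, t) onto the equal-activity
diagonal — each component becomes sign(m̄)·‖m⃗‖₂/√I, preserving the vector
norm — then restores across-context variance and mean probe responses.
Per-bin linear SVMs (standardized features, stratified 4-fold CV) decode
context or probe labels from single-trial population vectors.

**Encoding models.** Four GLMs with identical parameter counts: an 18 × 30
STRF (10-ms lags, 0–300 ms), a scalar self-history weight and one weight
per neighbour neuron (activity averaged 150–300 ms before the predicted
bin), and a bias, through a ReLU. Variants scramble (circularly time-shift
by tens of seconds) the self and/or population inputs: STRF scrambles both,
Self keeps only its own history, Pop only the neighbours', Full keeps both.
Fitting is seeded ADAM on the squared error of the rectified output with a
ridge warm start, one cross-validation fold per stimulus sequence.

**Statistics.** Categorical OLS of normalized effect size on context
similarity (silence/same/different) × identity (vocalization or not);
Kruskal–Wallis with Dunn post hoc tests; spike-width cell typing from the
KDE valley of the peak-to-trough-delay distribution; pupil median-split
modulation index MI = (large − small)/(|large| + |small|); delete-d
jackknife uncertainty.

## Worked example

```python
import numpy as np
from ctxcode.synthgen import SimConfig, simulate_population
from ctxcode.ctxfx import quantify_recording

cfg = SimConfig(n_neurons=6, seed=5, effect_sparsity=0.25,
                baseline_rate=10.0, effect_shape="flat",
                effect_sign="positive",
                effect_amplitude_range=(0.8, 2.0),
                effect_duration_range=(100, 800))
rec, gt = simulate_population(cfg)
effects = quantify_recording(rec, n_shuffles=2000, seed=3)

m = effects.merge(gt.effect_map,
                  on=["neuron", "probe", "context_a", "context_b"],
                  suffixes=("", "_true"))
det = m[m.has_effect & m.significant]
print(np.corrcoef(det.amplitude_zs, det.amplitude_zs_true)[0, 1])
```

Running `python examples/02_quantify_context_effects.py` (the same
computation with a printed table) gives

```
instances tested: 240   significant: 43   truly injected: 43
amplitude recovery r = 0.965  (integral |dZ|, Z-score*s)
duration MAE = 3 ms (last significant 50-ms bin)
```

i.e. of 240 contextual instances (6 neurons × 40), the cluster-mass test
flags the injected ones; estimated amplitudes track the generative truth at
r ≈ 0.97 and durations are recovered to a small fraction of one 50-ms bin
on average. The other scripts in `examples/` walk through
sequence design, population coverage (union ≥ best neuron ≥ mean neuron),
the dense-code decoding control (context accuracy collapses, probe
accuracy holds), the encoding-model dissociation, and a full pipeline run.

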