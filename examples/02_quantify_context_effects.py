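"""Simulate a recording and quantify context effects per instance.

A small population is simulated with known injected context effects
(amplitude in Z-score*s, duration in ms).  The cluster-mass permutation
test then recovers them from the noisy spike counts; the printed table
compares estimates with the generative ground truth.
"""

import warnings

import numpy as np

from ctxcode.ctxfx import quantify_recording
from ctxcode.synthgen import SimConfig, simulate_population

warnings.filterwarnings("ignore")

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
sig = m[m.significant]
print(f"instances tested: {len(m)}   significant: {len(sig)}"
      f"   truly injected: {int(m.has_effect.sum())}")

det = m[m.has_effect & m.significant]
r = np.corrcoef(det.amplitude_zs, det.amplitude_zs_true)[0, 1]
mae = np.abs(det.duration_ms - det.duration_ms_true).mean()
print(f"amplitude recovery r = {r:.3f}  (integral |dZ|, Z-score*s)")
print(f"duration MAE = {mae:.0f} ms (last significant 50-ms bin)")
print()
print(det[["neuron", "probe", "context_a", "context_b", "amplitude_zs",
           "amplitude_zs_true", "duration_ms", "duration_ms_true"]]
      .head(8).to_string(index=False))
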