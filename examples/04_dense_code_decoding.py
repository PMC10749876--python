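"""Why the sparse arrangement matters: the dense-code control.

The dense transform rotates each population context-modulation vector onto
the equal-activity diagonal — same overall magnitude, but identical across
neurons — while preserving every neuron's mean probe response and
trial-to-trial variability.  Per-bin linear SVM decoding then shows that
context information collapses under the dense code while probe information
is untouched.
"""

import warnings

import numpy as np

from ctxcode.ctxfx import zscore_normalize
from ctxcode.popcode import decode_timecourse, densify
from ctxcode.synthgen import SimConfig, segment_instances, simulate_population

warnings.filterwarnings("ignore")

cfg = SimConfig(n_neurons=15, seed=9, n_sounds=4, effect_sparsity=0.1,
                baseline_rate=10.0)
rec, _ = simulate_population(cfg)
z, _ = zscore_normalize(rec)
grid = segment_instances(rec, data=z).grid()

dt = densify(grid)
target = dt.m - dt.l
norm_err = np.abs(np.linalg.norm(target, axis=0)
                  - np.linalg.norm(dt.m, axis=0)).max()
print(f"modulation L2 norm preserved: max error {norm_err:.2e}")
print(f"mean probe response preserved: max error "
      f"{np.abs(dt.r_hat.mean(axis=(1, 3)) - dt.r_bar).max():.2e}")

bins = np.arange(8)  # first 400 ms of the probe window
for label in ("context", "probe"):
    a0 = decode_timecourse(grid, label, seed=1, bins=bins)
    a1 = decode_timecourse(dt.r_hat, label, seed=1, bins=bins)
    print(f"{label:7s} decoding: original {a0.accuracy.mean():.3f}  "
          f"dense {a1.accuracy.mean():.3f}  (chance {a0.chance:.3f})")
print("context accuracy drops under the dense code; probe accuracy holds.")
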