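"""One reproducible end-to-end run.

Executes design -> simulate -> quantify -> stats -> coverage -> dense-code
decoding with a single seeded configuration, writing tidy CSVs, a checksum
manifest, and a markdown report with figures.
"""

import warnings

from ctxcode.pipeline import RunConfig, report, run_pipeline

warnings.filterwarnings("ignore")

cfg = RunConfig(seed=1, n_neurons=8, effect_sparsity=0.15,
                n_shuffles=11000)
out = run_pipeline(cfg, "scratch/example_run")
print(f"run directory: {out}")
print((out / "manifest.json").read_text()[:400], "...")
print()
print(report(out).read_text())
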