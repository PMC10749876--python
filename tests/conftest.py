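import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")

warnings.filterwarnings("ignore", message=".*rate samples clipped.*")


@pytest.fixture(scope="session")
def strong_site():
    """10-neuron site with strong flat positive injected effects plus its
    quantified effects table (shared across recovery-style tests)."""
    from ctxcode.ctxfx import quantify_recording
    from ctxcode.synthgen import SimConfig, simulate_population

    cfg = SimConfig(n_neurons=10, seed=5, effect_sparsity=0.25,
                    baseline_rate=10.0, effect_shape="flat",
                    effect_sign="positive",
                    effect_amplitude_range=(0.8, 2.5),
                    effect_duration_range=(100, 800))
    rec, gt = simulate_population(cfg)
    effects = quantify_recording(rec, n_shuffles=1200, seed=3)
    return rec, gt, effects


@pytest.fixture(scope="session")
def sparse_grid():
    """15-neuron site at study-condition sparse effects: Z-scored event grid
    (neurons, contexts, probes, trials, time) for dense-code and decoding."""
    from ctxcode.ctxfx import zscore_normalize
    from ctxcode.synthgen import SimConfig, simulate_population, segment_instances

    cfg = SimConfig(n_neurons=15, seed=9, n_sounds=4, effect_sparsity=0.1,
                    baseline_rate=10.0)
    rec, gt = simulate_population(cfg)
    z, _ = zscore_normalize(rec)
    grid = segment_instances(rec, data=z).grid()
    return rec, gt, grid


@pytest.fixture(scope="session")
def coupled_fits():
    """Encoding-model fits for a small coupled network (8 neurons)."""
    from ctxcode.encmodel import fit_variants, prepare_encoding_inputs
    from ctxcode.synthgen import SimConfig, simulate_population

    I = 8
    rng = np.random.default_rng(4)
    W = np.zeros((I, I))
    for i in range(I):
        picks = rng.choice([j for j in range(I) if j != i], 3, replace=False)
        W[i, picks] = rng.uniform(0.3, 0.6, 3)
    cfg = SimConfig(n_neurons=I, n_reps=10, seed=4, effect_sparsity=0.0,
                    baseline_rate=8.0, coupling=W)
    rec, gt = simulate_population(cfg)
    from ctxcode.encmodel import prepare_encoding_inputs
    specs, resp = prepare_encoding_inputs(rec, seed=4)
    fits = [fit_variants(specs, resp, i, scramble_seed=10 + i, epochs=120)
            for i in range(I)]
    return rec, gt, specs, resp, fits
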