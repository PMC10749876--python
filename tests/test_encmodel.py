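import numpy as np
import pandas as pd
import pytest
from scipy.stats import wilcoxon

from ctxcode.encmodel import (VARIANTS, build_design, compare_models,
                              fit_model, predict_context_effects,
                              prepare_encoding_inputs, summarize_coupling)
from ctxcode.stimdesign import synthesize_sound_spectrogram


def toy_inputs(n_neurons=3, n_seq=3, seed=0):
    rng = np.random.default_rng(seed)
    specs = []
    for s in range(n_seq):
        parts = [synthesize_sound_spectrogram(k + 1, seed=seed + 11 * s + k).values
                 for k in range(4)]
        specs.append(np.concatenate(parts, axis=1))
    specs = np.stack(specs)
    resp = np.abs(rng.standard_normal((n_neurons, n_seq, specs.shape[-1])))
    resp /= resp.max(axis=(1, 2), keepdims=True)
    return specs, resp


class TestBuildDesign:
    def test_parameter_count_parity(self):
        specs, resp = toy_inputs()
        shapes = {v: build_design(specs, resp, 0, v, scramble_seed=1).X.shape
                  for v in VARIANTS}
        assert len(set(shapes.values())) == 1
        n_feat = 18 * 30 + 1 + (resp.shape[0] - 1)
        assert shapes["Full"][1] == n_feat

    def test_full_differs_from_pop_only_in_self_channel(self):
        specs, resp = toy_inputs()
        full = build_design(specs, resp, 0, "Full", scramble_seed=2)
        pop = build_design(specs, resp, 0, "Pop", scramble_seed=2)
        sl = full.slices
        assert np.array_equal(full.X[:, sl["strf"]], pop.X[:, sl["strf"]])
        assert np.array_equal(full.X[:, sl["pop"]], pop.X[:, sl["pop"]])
        assert not np.array_equal(full.X[:, sl["self"]], pop.X[:, sl["self"]])

    def test_zero_population_yields_zero_pop_columns(self):
        specs, resp = toy_inputs()
        resp[1:] = 0.0
        d = build_design(specs, resp, 0, "Pop", scramble_seed=0)
        assert np.all(d.X[:, d.slices["pop"]] == 0.0)

    def test_history_window_excludes_short_lags(self):
        # an impulse in the self signal must only influence predictors
        # 150-300 ms later
        specs, resp = toy_inputs()
        resp[0] = 0.0
        resp[0, 0, 100] = 1.0
        d = build_design(specs, resp, 0, "Full", scramble_seed=0)
        col = d.X[:500, d.slices["self"]].ravel()  # sequence 0 rows
        nz = np.nonzero(col)[0]
        assert nz.min() == 115 and nz.max() == 129

    def test_unknown_variant(self):
        specs, resp = toy_inputs()
        with pytest.raises(ValueError):
            build_design(specs, resp, 0, "Both")


class TestFitModel:
    def test_white_noise_target_near_zero_r(self):
        specs, resp = toy_inputs(seed=3)
        d = build_design(specs, resp, 0, "STRF", scramble_seed=1)
        fit = fit_model(d, epochs=60, seed=0)
        assert abs(fit.prediction_r) < 3.0 / np.sqrt(d.y.size) + 0.05

    def test_fold_count_equals_sequences(self):
        specs, resp = toy_inputs(seed=4)
        d = build_design(specs, resp, 0, "STRF", scramble_seed=1)
        fit = fit_model(d, epochs=30, seed=0)
        assert len(fit.fold_weights) == specs.shape[0]
        assert fit.predictions.shape == d.y.shape


class TestScramblingEffects:
    def test_scrambled_pop_weights_shrink(self, coupled_fits):
        _, _, _, _, fits = coupled_fits
        ratios = []
        for f in fits:
            w_full = np.abs(f["Full"].w_pop).mean()
            w_scr = np.abs(f["Self"].w_pop).mean()  # pop scrambled
            if w_full > 0:
                ratios.append(w_scr / w_full)
        assert np.mean(ratios) < 0.5

    def test_coupled_population_improves_prediction(self, coupled_fits):
        _, _, _, _, fits = coupled_fits
        r_full = np.array([f["Full"].prediction_r for f in fits])
        r_strf = np.array([f["STRF"].prediction_r for f in fits])
        assert wilcoxon(r_full, r_strf, alternative="greater").pvalue < 0.05


class TestCompareModels:
    def test_identical_fits_p_one(self, coupled_fits):
        _, _, _, _, fits = coupled_fits
        same = [{v: f["Full"] for v in VARIANTS} for f in fits]
        comp = compare_models(same)
        assert (comp.p_bonf == 1.0).all()

    def test_pairs_and_bonferroni(self, coupled_fits):
        _, _, _, _, fits = coupled_fits
        comp = compare_models(fits)
        assert len(comp) == 6
        assert comp.p_bonf.max() <= 1.0


class TestContextPrediction:
    def test_interval_boundaries_and_strf_memory(self, coupled_fits):
        rec, _, specs, resp, fits = coupled_fits
        fit = fits[0]["Full"]
        # zero history weights: predicted context differences must vanish
        # once the 300-ms stimulus memory has elapsed (intervals iii, iv)
        import copy
        f0 = copy.deepcopy(fit)
        sl = f0.spec.slices
        f0.weights[sl["self"]] = 0.0
        f0.weights[sl["pop"]] = 0.0
        eff = pd.DataFrame([
            dict(neuron=0, probe=p, context_a=a, context_b=b,
                 amplitude_zs=1.0, duration_ms=500.0, min_cluster_p=1e-4,
                 significant=True)
            for (p, a, b) in [(1, 0, 2), (2, 1, 3), (3, 0, 1), (4, 2, 3)]
        ])
        out = predict_context_effects(f0, specs, resp, 0, eff, rec)
        t = out["table"]
        assert len(t) > 0
        assert np.allclose(t.pred_iv3, 0.0, atol=1e-12)
        assert np.allclose(t.pred_iv4, 0.0, atol=1e-12)

    def test_self_consistent_model_high_interval_r(self, coupled_fits):
        rec, _, specs, resp, fits = coupled_fits
        from ctxcode.ctxfx import quantify_recording
        eff = quantify_recording(rec, n_shuffles=800, seed=6,
                                 neurons=np.array([0]))
        if eff.significant.sum() < 3:
            pytest.skip("too few significant instances in fixture")
        out = predict_context_effects(fits[0]["Full"], specs, resp, 0,
                                      eff, rec)
        rs = [v for v in out["interval_r"].values() if np.isfinite(v)]
        assert rs and np.mean(rs) > 0.5


class TestSummarizeCoupling:
    def test_zero_weights_zero_means(self, coupled_fits):
        _, _, _, _, fits = coupled_fits
        import copy
        z = {}
        for i, f in enumerate(fits[:3]):
            fz = copy.deepcopy(f["Full"])
            fz.weights[fz.spec.slices["pop"]] = 0.0
            z[i] = fz
        classes = pd.Series({i: "broad" for i in range(8)})
        tab = summarize_coupling(z, classes)
        assert tab.incoming_mean.abs().max() == 0.0
        assert tab.outgoing_mean.abs().max() == 0.0

    def test_positive_coupling_recovered(self, coupled_fits):
        rec, gt, _, _, fits = coupled_fits
        full = {i: fits[i]["Full"] for i in range(len(fits))}
        classes = pd.Series(rec.neuron_table.true_class.to_numpy(),
                            index=rec.neuron_table.neuron.to_numpy())
        tab = summarize_coupling(full, classes)
        # generative coupling is positive: recovered means should be > 0
        assert (tab.outgoing_mean > 0).all()

    def test_single_neuron_empty(self):
        specs, resp = toy_inputs(n_neurons=1)
        d = build_design(specs, resp, 0, "Full", scramble_seed=0)
        fit = fit_model(d, epochs=20, seed=0)
        tab = summarize_coupling({0: fit}, pd.Series({0: "broad"}))
        assert tab.n_outgoing.sum() == 0
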