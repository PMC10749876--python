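import numpy as np
import pytest

from ctxcode.ctxfx import (EffectProfile, amplitude_duration_association,
                           cluster_mass_test, correct_instances,
                           effect_metrics, reliability_filter,
                           zscore_normalize)
from ctxcode.synthgen import SimConfig, simulate_population


def make_profile(delta, sig_mask):
    delta = np.asarray(delta, float)
    mask = np.asarray(sig_mask, bool)
    return EffectProfile(delta=delta, tscore=np.zeros_like(delta),
                         sig_mask=mask, clusters=[])


class TestZscore:
    def test_global_moments(self):
        rec, _ = simulate_population(SimConfig(n_neurons=3, n_reps=5,
                                               n_sounds=3, seed=0))
        z, kept = zscore_normalize(rec)
        for i in np.where(kept)[0]:
            assert abs(z[i].mean()) < 1e-9
            assert abs(z[i].std() - 1.0) < 1e-9

    def test_constant_neuron_excluded(self):
        rec, _ = simulate_population(SimConfig(n_neurons=2, n_reps=5,
                                               n_sounds=2, seed=0))
        rec.counts[0] = 3.0
        with pytest.warns(UserWarning, match="zero-variance"):
            z, kept = zscore_normalize(rec)
        assert not kept[0] and kept[1]

    def test_affine_invariance(self):
        rec, _ = simulate_population(SimConfig(n_neurons=2, n_reps=5,
                                               n_sounds=2, seed=1))
        rec.counts[1] = 2.5 * rec.counts[0] + 7.0
        z, _ = zscore_normalize(rec)
        assert np.allclose(z[0], z[1])


class TestReliabilityFilter:
    def test_noise_free_neuron_kept(self):
        rec, _ = simulate_population(SimConfig(n_neurons=3, n_reps=6,
                                               n_sounds=2, seed=2,
                                               noise_model="none"))
        kept = reliability_filter(rec, threshold=0.1, seed=0)
        assert set(kept) == {0, 1, 2}  # identical halves, r = 1

    def test_vacuous_threshold_keeps_all(self):
        rec, _ = simulate_population(SimConfig(n_neurons=3, n_reps=4,
                                               n_sounds=2, seed=3))
        assert len(reliability_filter(rec, threshold=-1.0, seed=0)) == 3

    def test_pure_noise_neuron_dropped(self):
        # untuned flat-rate neurons: PSTH halves share no signal
        rec, _ = simulate_population(SimConfig(n_neurons=6, n_reps=20,
                                               n_sounds=4, probe_gain=0.0,
                                               seed=4))
        kept = reliability_filter(rec, threshold=0.1, seed=0)
        assert len(kept) <= 2  # r ~ N(0, 1/sqrt(100)); most fall below 0.1


class TestClusterMassTest:
    def test_identical_conditions_no_clusters(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal((10, 20))
        prof = cluster_mass_test(a, a.copy(), n_shuffles=200, seed=1)
        assert not prof.sig_mask.any() and prof.clusters == []

    def test_injected_block_detected(self):
        # dZ = 2 over bins 0-5, sigma = 0.3: per-bin power ~ 1
        rng = np.random.default_rng(5)
        a = 0.3 * rng.standard_normal((20, 20))
        b = 0.3 * rng.standard_normal((20, 20))
        a[:, :6] += 2.0
        prof = cluster_mass_test(a, b, n_shuffles=500, seed=2)
        assert prof.sig_mask[:6].all()
        assert prof.min_cluster_p < 0.01

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(7)
        a = rng.standard_normal((15, 20))
        b = rng.standard_normal((15, 20))
        a[:, 4:9] += 1.2
        p1 = cluster_mass_test(a, b, n_shuffles=2000, seed=3)
        p2 = cluster_mass_test(b, a, n_shuffles=2000, seed=3)
        assert np.allclose(p1.delta, -p2.delta)
        assert np.allclose(np.abs(p1.tscore), np.abs(p2.tscore))
        s1 = sorted(abs(c[2]) for c in p1.clusters)
        s2 = sorted(abs(c[2]) for c in p2.clusters)
        assert np.allclose(s1, s2)
        assert abs(p1.min_cluster_p - p2.min_cluster_p) < 0.02

    def test_zero_variance_equal_means_nonsignificant(self):
        a = np.ones((5, 10))
        prof = cluster_mass_test(a, np.ones((5, 10)), n_shuffles=100, seed=0)
        assert not prof.sig_mask.any()

    def test_input_validation(self):
        with pytest.raises(ValueError):
            cluster_mass_test(np.ones((1, 5)), np.ones((5, 5)))
        with pytest.raises(ValueError):
            cluster_mass_test(np.ones((5, 4)), np.ones((5, 5)))

    def test_welch_variant_similar_on_equal_variance(self):
        rng = np.random.default_rng(8)
        a = rng.standard_normal((20, 20)) + np.r_[np.full(8, 1.0),
                                                  np.zeros(12)]
        b = rng.standard_normal((20, 20))
        p_pooled = cluster_mass_test(a, b, n_shuffles=500, seed=1)
        p_welch = cluster_mass_test(a, b, n_shuffles=500, seed=1, welch=True)
        assert np.allclose(p_pooled.tscore, p_welch.tscore, atol=1e-6)


class TestEffectMetrics:
    def test_full_window(self):
        m = effect_metrics(make_profile(np.ones(20), np.ones(20, bool)))
        assert m.amplitude == pytest.approx(1.0)
        assert m.duration == pytest.approx(1000.0)
        assert m.significant

    def test_partial_block_arithmetic(self):
        mask = np.zeros(20, bool)
        mask[3:12] = True  # bins 3..11
        m = effect_metrics(make_profile(np.full(20, 0.8), mask))
        assert m.amplitude == pytest.approx(0.8 * 9 * 0.05)  # 0.36 Z.s
        assert m.duration == pytest.approx(600.0)

    def test_empty_mask(self):
        m = effect_metrics(make_profile(np.ones(20), np.zeros(20, bool)))
        assert (m.amplitude, m.duration, m.significant) == (0.0, 0.0, False)


class TestCorrectInstances:
    def test_thresholds(self):
        p = np.full(40, 0.5)
        p[0] = 0.001
        sig = correct_instances(p)
        assert sig[0] and not sig[1:].any()  # 0.001 < 0.05/40
        p550 = np.full(550, 0.5)
        p550[0] = 2e-4
        assert not correct_instances(p550).any()  # threshold 9.09e-5

    def test_single_instance_reduces_to_alpha(self):
        assert correct_instances(np.array([0.04]))[0]
        assert not correct_instances(np.array([0.06]))[0]

    def test_neuron_factor(self):
        p = np.full(40, 1e-4)
        assert correct_instances(p).all()
        assert not correct_instances(p, n_extra_comparisons=100).any()


class TestAmplitudeDurationAssociation:
    def _profiles(self, rng, n=40, coupled=True):
        out = []
        for _ in range(n):
            dur = rng.integers(2, 18)
            amp_scale = dur / 10 if coupled else 1.0
            delta = np.zeros(20)
            delta[:dur] = amp_scale * rng.uniform(0.5, 1.0, dur)
            mask = delta != 0
            out.append(make_profile(delta, mask))
        return out

    def test_coupled_durations_significant(self):
        rng = np.random.default_rng(0)
        res = amplitude_duration_association(self._profiles(rng), seed=1)
        assert res["r"] > 0.6
        assert res["p"] < 0.05

    def test_amplitude_invariant_under_shuffle(self):
        # the null randomizes duration only; amplitudes are untouched
        rng = np.random.default_rng(1)
        profs = self._profiles(rng, n=10)
        amps = [effect_metrics(p).amplitude for p in profs]
        perm = [make_profile(p.delta[::-1], p.sig_mask[::-1]) for p in profs]
        assert np.allclose([effect_metrics(p).amplitude for p in perm], amps)

    def test_single_bin_degenerate(self):
        profs = []
        for _ in range(5):
            d = np.zeros(20)
            d[0] = 1.0
            profs.append(make_profile(d, d != 0))
        res = amplitude_duration_association(profs, seed=0)
        assert res["degenerate"]

    def test_too_few_profiles(self):
        with pytest.raises(ValueError):
            amplitude_duration_association([make_profile(np.ones(20),
                                                         np.ones(20, bool))])


def test_permutation_pvalues_use_add_one_estimator():
    rng = np.random.default_rng(2)
    a = rng.standard_normal((10, 20))
    b = rng.standard_normal((10, 20)) + 3.0
    prof = cluster_mass_test(a, b, n_shuffles=99, seed=0)
    assert prof.clusters
    for c in prof.clusters:
        assert 0 < c[3] <= 1
        assert c[3] >= 1.0 / 100.0
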