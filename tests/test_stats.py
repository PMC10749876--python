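import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from ctxcode.stats import (assign_categories, build_category_table,
                           category_regression, classify_spike_width,
                           group_compare, jackknife_ci, modulation_index,
                           pupil_split_mi)
from ctxcode.stimdesign import SoundLibrary

LIB = SoundLibrary(4, {3: True, 4: True})


class TestCategories:
    def test_silence(self):
        d = assign_categories(2, 0, LIB)
        assert d["similarity"] == "silence" and d["is_silence"]

    def test_same_vocal(self):
        d = assign_categories(3, 3, LIB)
        assert d["similarity"] == "same" and d["identity"] == "vocalization"

    def test_different_nonvocal_base(self):
        d = assign_categories(1, 2, LIB)
        assert d["similarity"] == "different"
        assert d["identity"] == "non-vocalization"

    def test_unknown_id(self):
        with pytest.raises(KeyError):
            assign_categories(1, 9, LIB)

    def test_row_duplication_bookkeeping(self):
        eff = pd.DataFrame([
            dict(neuron=0, probe=1, context_a=0, context_b=2,
                 amplitude_zs=1.0, duration_ms=100.0),
            dict(neuron=0, probe=2, context_a=1, context_b=3,
                 amplitude_zs=1.0, duration_ms=100.0),
        ])
        tab = build_category_table(eff, LIB)
        assert len(tab) == 4  # two rows per instance, one per context

    def test_silence_vocal_exclusion(self):
        eff = pd.DataFrame([
            dict(neuron=0, probe=1, context_a=0, context_b=3,
                 amplitude_zs=1.0, duration_ms=100.0),
        ])
        assert len(build_category_table(eff, LIB,
                                        exclude_silence_vocal=True)) == 0


class TestCategoryRegression:
    def _make(self, silence_boost, vocal_boost, n=1500, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for _ in range(n):
            p = int(rng.integers(1, 5))
            ca, cb = map(int, rng.choice(5, 2, replace=False))
            labs = [assign_categories(p, c, LIB) for c in (ca, cb)]
            amp = 1.0
            if any(d["is_silence"] for d in labs):
                amp *= 1 + silence_boost
            if any(d["identity"] == "vocalization" for d in labs):
                amp *= 1 + vocal_boost
            rows.append(dict(neuron=0, probe=p, context_a=ca, context_b=cb,
                             amplitude_zs=amp + rng.normal(0, 0.05),
                             duration_ms=200.0))
        return build_category_table(pd.DataFrame(rows), LIB)

    def test_null_coefficients_near_zero(self):
        reg = category_regression(self._make(0.0, 0.0, seed=1))
        effects = reg[reg.term != "Intercept"]
        assert (effects.pvalue.dropna() > 0.01).all()

    def test_injected_boosts_recovered_in_sign_and_order(self):
        reg = category_regression(self._make(0.15, 0.08, seed=2))
        coefs = dict(zip(reg.term, reg.coef_pct))
        pvals = dict(zip(reg.term, reg.pvalue))
        sil = [t for t in coefs if "silence" in t and ":" not in t][0]
        voc = [t for t in coefs if "vocalization" in t and ":" not in t][0]
        assert coefs[sil] > coefs[voc] > 0
        assert pvals[sil] < 0.001 and pvals[voc] < 0.001

    def test_degenerate_single_category(self):
        tab = self._make(0.0, 0.0, n=50, seed=3)
        tab = tab[tab.similarity == "different"]
        with pytest.raises(ValueError):
            category_regression(tab)


class TestGroupCompare:
    def test_identical_groups(self):
        v = np.tile(np.arange(10.0), 2)
        g = np.repeat(["a", "b"], 10)
        res = group_compare(v, g)
        assert res["p"] == pytest.approx(1.0)

    def test_shifted_groups_detected(self):
        rng = np.random.default_rng(0)
        v = np.concatenate([rng.normal(0, 1, 200), rng.normal(2, 1, 200)])
        g = np.repeat(["a", "b"], 200)
        res = group_compare(v, g)
        assert res["p"] < 1e-3
        assert (res["dunn"].p_bonf < 1e-3).all()

    def test_two_groups_match_ranksum(self):
        rng = np.random.default_rng(1)
        v = np.concatenate([rng.normal(0, 1, 50), rng.normal(0.5, 1, 50)])
        g = np.repeat(["a", "b"], 50)
        res = group_compare(v, g)
        u_p = sps.mannwhitneyu(v[:50], v[50:]).pvalue
        assert res["p"] == pytest.approx(u_p, rel=0.05)

    def test_validation(self):
        with pytest.raises(ValueError):
            group_compare([1, 2, 3], ["a", "a", "a"])
        with pytest.raises(ValueError):
            group_compare([1, 2, 3], ["a", "a", "b"])


class TestSpikeWidth:
    def test_bimodal_mixture_classified(self):
        rng = np.random.default_rng(0)
        ptd = np.concatenate([rng.normal(0.25, 0.04, 150),
                              rng.normal(0.70, 0.08, 350)])
        truth = np.array(["narrow"] * 150 + ["broad"] * 350)
        res = classify_spike_width(ptd)
        assert 0.35 < res.valley < 0.55
        got = res.table.cell_class.to_numpy()
        ok = got != "unclassified"
        assert (got[ok] == truth[ok]).mean() >= 0.95

    def test_unimodal_refused(self):
        with pytest.raises(ValueError):
            classify_spike_width(np.full(50, 0.4))
        rng = np.random.default_rng(1)
        with pytest.raises(ValueError):
            classify_spike_width(rng.normal(0.5, 0.05, 300))

    def test_manual_banding_rule(self):
        ptd = np.array([0.30, 0.36, 0.40, 0.48, 0.80])
        res = classify_spike_width(ptd, thresholds=(0.37, 0.47))
        assert list(res.table.cell_class) == \
            ["narrow", "narrow", "unclassified", "broad", "broad"]


class TestModulationIndex:
    def test_formula_values(self):
        assert modulation_index(2, 1) == pytest.approx(1 / 3)
        assert modulation_index(3, 3) == 0.0
        assert modulation_index(0, 0) == 0.0

    @given(st.floats(-50, 50), st.floats(-50, 50))
    def test_antisymmetry(self, a, b):
        assert modulation_index(a, b) == pytest.approx(
            -modulation_index(b, a), abs=1e-12)

    @given(st.floats(-50, 50), st.floats(-50, 50),
           st.floats(0.01, 100))
    def test_scale_invariance(self, a, b, c):
        assert modulation_index(c * a, c * b) == pytest.approx(
            modulation_index(a, b), abs=1e-9)

    def test_bounded(self):
        rng = np.random.default_rng(0)
        for a, b in rng.standard_normal((100, 2)):
            assert -1.0 <= modulation_index(a, b) <= 1.0


class TestPupilSplitMI:
    def test_gain_free_centered_on_zero(self, strong_site):
        rec, _, eff = strong_site
        out = pupil_split_mi(rec, eff)
        assert abs(out["rate_mi"].mi.mean()) < 0.1

    def test_constant_pupil_flagged(self, strong_site):
        import copy
        rec, _, eff = strong_site
        r = copy.deepcopy(rec)
        r.pupil = np.ones_like(rec.pupil)
        with pytest.raises(ValueError):
            pupil_split_mi(r, eff)


class TestJackknife:
    def test_constant_values_zero_width(self):
        res = jackknife_ci(np.full(50, 2.5), np.mean)
        assert res["std"] == 0.0
        assert res["ci"][0] == res["ci"][1] == 2.5

    def test_mean_matches_closed_form_se(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 400)
        res = jackknife_ci(x, np.mean, n_folds=200)
        se = x.std(ddof=1) / np.sqrt(400)
        assert res["std"] == pytest.approx(se, rel=0.10)

    def test_median_on_skewed_data_smoke(self):
        rng = np.random.default_rng(1)
        res = jackknife_ci(rng.lognormal(0, 1, 150), np.median, n_folds=100)
        assert np.isfinite(res["std"])

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            jackknife_ci([1.0, 2.0], np.mean)
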