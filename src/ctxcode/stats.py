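"""Category-level inference and auxiliary statistics.

Covers the categorical regression of context-effect magnitude on context
similarity (silence / same / different) and identity (vocalization or not),
nonparametric group comparisons (Kruskal-Wallis with Dunn post hoc tests),
classification of putative cell type from spike peak-to-trough delay,
pupil-indexed arousal analyses (median split and modulation index), and
jackknife uncertainty estimates.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats as sps
from scipy.stats import gaussian_kde

from .stimdesign import SILENCE_ID, SoundLibrary

__all__ = [
    "assign_categories",
    "build_category_table",
    "category_regression",
    "group_compare",
    "CellTypeResult",
    "classify_spike_width",
    "modulation_index",
    "pupil_split_mi",
    "jackknife_ci",
]


def assign_categories(probe: int, context: int, library: SoundLibrary) -> dict:
    """Similarity and identity labels for one context of an instance.

    Similarity is ``silence`` for the silent context, ``same`` when the
    context sound equals the probe, else ``different``.  Identity is
    ``vocalization``/``non-vocalization``; the silent context carries no
    identity and is mapped to the base level for regression.
    """
    if context == SILENCE_ID:
        return {"similarity": "silence", "identity": "non-vocalization",
                "is_silence": True}
    if not 1 <= context <= library.n_sounds:
        raise KeyError(f"unknown sound id {context}")
    return {
        "similarity": "same" if context == probe else "different",
        "identity": ("vocalization" if library.vocal(context)
                     else "non-vocalization"),
        "is_silence": False,
    }


def build_category_table(effects: pd.DataFrame, library: SoundLibrary,
                         exclude_silence_vocal: bool = False) -> pd.DataFrame:
    """One labeled row per context of each instance.

    Each two-context instance contributes two rows carrying the same metric
    values, one per context label.  With ``exclude_silence_vocal=True``,
    instances pairing a silence context with a vocalization context are
    dropped (their interaction confounds the marginal effects).
    """
    rows = []
    for rec in effects.itertuples():
        labs = [assign_categories(rec.probe, c, library)
                for c in (rec.context_a, rec.context_b)]
        if exclude_silence_vocal:
            has_sil = any(d["is_silence"] for d in labs)
            has_voc = any(d["identity"] == "vocalization" for d in labs)
            if has_sil and has_voc:
                continue
        for c, d in zip((rec.context_a, rec.context_b), labs):
            rows.append({
                "neuron": rec.neuron, "probe": rec.probe, "context": c,
                "similarity": d["similarity"], "identity": d["identity"],
                "amplitude_zs": rec.amplitude_zs,
                "duration_ms": rec.duration_ms,
                "probe_is_vocalization": library.vocal(rec.probe),
            })
    return pd.DataFrame(rows)


def category_regression(table: pd.DataFrame, metric: str = "amplitude_zs",
                        include_probe_identity: bool = False) -> pd.DataFrame:
    """OLS of normalized effect size on context similarity x identity.

    The metric is divided by its grand mean so coefficients read as percent
    change relative to the base category (different / non-vocalization).
    Returns a table of coefficients (percent), t statistics and p-values.
    """
    df = table.copy()
    grand = df[metric].mean()
    if grand == 0:
        raise ValueError("grand mean of metric is zero")
    df["y"] = df[metric] / grand
    formula = ("y ~ C(similarity, Treatment('different'))"
               " * C(identity, Treatment('non-vocalization'))")
    if include_probe_identity:
        formula += " + probe_is_vocalization"
    present = df.similarity.nunique() >= 2
    if not present:
        raise ValueError("need >= 2 categories present")
    fit = smf.ols(formula, data=df).fit()
    out = pd.DataFrame({
        "coef_pct": 100.0 * fit.params,
        "tvalue": fit.tvalues,
        "pvalue": fit.pvalues,
    })
    out.index.name = "term"
    return out.reset_index()


def _dunn_posthoc(values: np.ndarray, groups: np.ndarray) -> pd.DataFrame:
    """Dunn's pairwise z tests on pooled ranks with tie correction and
    Bonferroni adjustment over all group pairs."""
    vals = np.asarray(values, dtype=float)
    grp = np.asarray(groups)
    labels = pd.unique(grp)
    n = vals.size
    ranks = sps.rankdata(vals)
    _, counts = np.unique(vals, return_counts=True)
    ties = ((counts ** 3 - counts).sum()) / (12.0 * (n - 1))
    var_base = n * (n + 1) / 12.0 - ties
    rows = []
    n_pairs = len(labels) * (len(labels) - 1) // 2
    for a, b in itertools.combinations(labels, 2):
        ma, mb = grp == a, grp == b
        ra, rb = ranks[ma].mean(), ranks[mb].mean()
        se = np.sqrt(var_base * (1.0 / ma.sum() + 1.0 / mb.sum()))
        z = (ra - rb) / se
        p = min(2.0 * sps.norm.sf(abs(z)) * n_pairs, 1.0)
        rows.append({"group_a": a, "group_b": b, "z": z, "p_bonf": p})
    return pd.DataFrame(rows)


def group_compare(values, groups) -> dict:
    """Kruskal-Wallis test plus Dunn post hoc table (Bonferroni-corrected)."""
    vals = np.asarray(values, dtype=float)
    grp = np.asarray(groups)
    labels = pd.unique(grp)
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    samples = [vals[grp == g] for g in labels]
    if any(s.size < 2 for s in samples):
        raise ValueError("every group needs >= 2 values")
    h, p = sps.kruskal(*samples)
    return {"H": float(h), "p": float(p),
            "dunn": _dunn_posthoc(vals, grp)}


# ---------------------------------------------------------------------------
# spike-width cell typing


@dataclass
class CellTypeResult:
    table: pd.DataFrame  # per neuron: ptd_ms, cell_class
    threshold_low: float
    threshold_high: float
    valley: float


def classify_spike_width(ptd_ms, safety: float = 0.1,
                         thresholds: tuple[float, float] | None = None
                         ) -> CellTypeResult:
    """Classify neurons as narrow or broad spiking from peak-to-trough delay.

    A kernel density estimate (Silverman bandwidth) of the PTD distribution
    must be bimodal; the valley between the two dominant modes, widened by
    ``safety``/2 on each side, separates narrow (< low) from broad (> high),
    with in-band values left unclassified.  Fixed thresholds (e.g. the
    0.37/0.47 ms banding) can be supplied to bypass the density fit.
    """
    ptd = np.asarray(ptd_ms, dtype=float)
    if thresholds is None:
        if np.ptp(ptd) == 0:
            raise ValueError("degenerate PTD distribution: unimodal")
        kde = gaussian_kde(ptd)
        grid = np.linspace(ptd.min(), ptd.max(), 512)
        dens = kde(grid)
        interior = (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])
        peaks = np.where(interior)[0] + 1
        if peaks.size < 2:
            raise ValueError("PTD density is unimodal; classification refused")
        top2 = peaks[np.argsort(dens[peaks])[-2:]]
        lo_pk, hi_pk = sorted(top2)
        valley = grid[lo_pk + np.argmin(dens[lo_pk:hi_pk + 1])]
        low, high = valley - safety / 2, valley + safety / 2
    else:
        low, high = thresholds
        valley = 0.5 * (low + high)
    if not low < high:
        raise ValueError("threshold_low must be < threshold_high")
    cls = np.where(ptd < low, "narrow", np.where(ptd > high, "broad",
                                                 "unclassified"))
    table = pd.DataFrame({"ptd_ms": ptd, "cell_class": cls})
    return CellTypeResult(table=table, threshold_low=float(low),
                          threshold_high=float(high), valley=float(valley))


# ---------------------------------------------------------------------------
# pupil state


def modulation_index(large: float, small: float) -> float:
    """(large - small) / (|large| + |small|); 0 when both are 0."""
    denom = abs(large) + abs(small)
    if denom == 0:
        return 0.0
    return (large - small) / denom


def pupil_split_mi(rec, effects: pd.DataFrame,
                   rate_floor: float = 0.1, effect_floor: float = 0.3,
                   interval_ms: float = 250.0) -> dict:
    """Pupil median-split modulation indices for rates and context effects.

    Trials of each contextual instance are split by the median pupil size
    over the context+probe interval.  MI = (large - small)/(|large| +
    |small|) is computed for the context-averaged mean Z firing rate per
    (neuron, probe) (requiring mean Z >= ``rate_floor``) and for the |dZ|
    context-effect of significant instances (requiring mean |dZ| >=
    ``effect_floor``), overall and in non-overlapping 250-ms intervals.
    Effect signs are flipped positive before pooling.
    """
    from .ctxfx import zscore_normalize
    from .synthgen import segment_instances

    if np.ptp(rec.pupil) < 1e-12:
        raise ValueError("constant pupil trace: median split undefined")
    z, _ = zscore_normalize(rec)
    seg = segment_instances(rec, data=z)
    ev = seg.events
    bins_per_sound = seg.tensor.shape[-1]
    n_iv = int(round(bins_per_sound * rec.bin_dt * 1e3 / interval_ms))
    iv_edges = np.linspace(0, bins_per_sound, n_iv + 1).astype(int)
    bin_dt = rec.bin_dt

    # per-event trial pupil: median over context+probe window
    def event_pupil(row):
        k = row.position
        lo = max(k - 1, 0) * bins_per_sound
        hi = (k + 1) * bins_per_sound
        tr = rec.trial_table.trial[rec.trial_table.sequence == row.sequence]
        return np.median(rec.pupil[tr.to_numpy(), lo:hi], axis=1)

    rate_rows, eff_rows = [], []
    for e, row in ev.iterrows():
        pup = event_pupil(row)
        big = pup > np.median(pup)
        if big.sum() in (0, big.size):  # fall back to balanced rank split
            order = np.argsort(pup)
            big = np.zeros(pup.size, bool)
            big[order[pup.size // 2:]] = True
        resp = seg.tensor[:, e]  # (I, reps, bins)
        mean_z = resp.mean(axis=(1, 2))
        for i in np.where(mean_z >= rate_floor)[0]:
            rate_rows.append({
                "neuron": i, "probe": row.probe, "context": row.context,
                "mi": modulation_index(resp[i, big].mean(),
                                       resp[i, ~big].mean()),
            })
        ev_split = (row.context, row.probe, big)
        eff_rows.append(ev_split)
    ev_split_map = {(c, p): big for c, p, big in eff_rows}

    eff_mi = []
    for r in effects[effects.significant].itertuples():
        bigA = ev_split_map.get((r.context_a, r.probe))
        bigB = ev_split_map.get((r.context_b, r.probe))
        if bigA is None or bigB is None:
            continue
        rA = seg.get(r.context_a, r.probe)[r.neuron]
        rB = seg.get(r.context_b, r.probe)[r.neuron]
        d_lg = rA[bigA].mean(axis=0) - rB[bigB].mean(axis=0)
        d_sm = rA[~bigA].mean(axis=0) - rB[~bigB].mean(axis=0)
        d_all = rA.mean(axis=0) - rB.mean(axis=0)
        if np.abs(d_all).mean() < effect_floor:
            continue
        sign = np.sign(d_all.sum()) or 1.0
        entry = {"neuron": r.neuron, "probe": r.probe,
                 "context_a": r.context_a, "context_b": r.context_b,
                 "mi_overall": modulation_index((sign * d_lg).mean(),
                                                (sign * d_sm).mean())}
        for k in range(n_iv):
            sl = slice(iv_edges[k], iv_edges[k + 1])
            entry[f"mi_iv{k + 1}"] = modulation_index(
                (sign * d_lg[sl]).mean(), (sign * d_sm[sl]).mean())
        eff_mi.append(entry)
    return {
        "rate_mi": pd.DataFrame(rate_rows),
        "effect_mi": pd.DataFrame(eff_mi),
        "interval_ms": interval_ms,
        "bin_dt": bin_dt,
    }


# ---------------------------------------------------------------------------
# jackknife


def jackknife_ci(values, statistic=np.mean, n_folds: int = 100,
                 ci: float = 0.95, seed: int = 0) -> dict:
    """Delete-one (or grouped delete-d) jackknife estimate, std and CI.

    With more values than folds, values are partitioned into ``n_folds``
    seeded groups and each group is deleted in turn; otherwise the
    classical delete-one jackknife is used.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need >= 3 values")
    g = min(n_folds, n)
    rng = np.random.default_rng(seed)
    assignment = rng.permutation(np.arange(n) % g)
    theta_full = float(statistic(x))
    theta_del = np.empty(g)
    for k in range(g):
        theta_del[k] = statistic(x[assignment != k])
    theta_bar = theta_del.mean()
    se = np.sqrt((g - 1) / g * ((theta_del - theta_bar) ** 2).sum())
    zq = sps.norm.ppf(0.5 + ci / 2)
    return {
        "estimate": theta_full,
        "bias_corrected": g * theta_full - (g - 1) * theta_bar,
        "std": float(se),
        "ci": (theta_full - zq * se, theta_full + zq * se),
        "n_folds": g,
    }
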