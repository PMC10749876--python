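"""Quantification of context effects on probe responses.

For each *contextual instance* — a probe sound preceded by a pair of
distinct contexts — the difference between the two probe PSTHs (in Z units,
50-ms bins) is tested with a cluster-mass permutation test: contiguous bins
with significant same-sign per-bin T scores form clusters whose summed T is
compared against the null distribution of the per-shuffle maximum cluster
score obtained by permuting trial-to-context assignment.  Significant
effects are summarized by an integral amplitude (integral of |dZ| over
significant bins, Z-score*s) and a duration (end time of the last
significant bin, ms).  Bonferroni correction is applied across the
instances tested per neuron (and, for site-level unions, across neurons).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .synthgen import PopulationRecording, SegmentedResponses, segment_instances

__all__ = [
    "EffectProfile",
    "EffectMetrics",
    "zscore_normalize",
    "reliability_filter",
    "cluster_mass_test",
    "effect_metrics",
    "correct_instances",
    "amplitude_duration_association",
    "quantify_recording",
]


@dataclass
class EffectProfile:
    """Per-bin difference trace and its cluster-level significance."""

    delta: np.ndarray  # dZ per bin (context A minus context B PSTH)
    tscore: np.ndarray
    sig_mask: np.ndarray  # bins belonging to significant clusters
    clusters: list[tuple[int, int, float, float]]  # (start, end, score, p)

    @property
    def min_cluster_p(self) -> float:
        return min((c[3] for c in self.clusters), default=1.0)


@dataclass(frozen=True)
class EffectMetrics:
    amplitude: float  # Z-score * s
    duration: float  # ms
    significant: bool


def zscore_normalize(rec: PopulationRecording) -> tuple[np.ndarray, np.ndarray]:
    """Z-score single-trial spike rates per neuron over the whole recording.

    Normalization uses the mean and std of the single-trial rate across all
    bins, spontaneous and evoked alike.  Returns ``(z, kept)`` where ``z``
    is (neurons, trials, time) with zero-variance neurons zeroed out and
    ``kept`` is the boolean mask of neurons with positive variance.
    """
    rates = rec.rates()
    flat = rates.reshape(rates.shape[0], -1)
    mu = flat.mean(axis=1)
    sd = flat.std(axis=1, ddof=0)
    kept = sd > 0
    if not kept.all():
        warnings.warn(f"excluding {int((~kept).sum())} zero-variance neuron(s)")
    sd_safe = np.where(kept, sd, 1.0)
    z = (rates - mu[:, None, None]) / sd_safe[:, None, None]
    z[~kept] = 0.0
    return z, kept


def reliability_filter(rec: PopulationRecording, threshold: float = 0.1,
                       seed: int = 0) -> np.ndarray:
    """Neurons whose PSTHs from random halves of the repeats correlate > threshold.

    Each sequence's trials are split in half at random; the two half-PSTHs
    (concatenated over sequences, 20 Hz) are correlated per neuron.
    """
    rng = np.random.default_rng(seed)
    seq_ids = rec.trial_table.sequence.to_numpy()
    h1, h2 = [], []
    for si in np.unique(seq_ids):
        tr = np.where(seq_ids == si)[0]
        if tr.size < 2:
            raise ValueError("need >= 2 trials per stimulus for the split")
        perm = rng.permutation(tr)
        half = tr.size // 2
        h1.append(rec.counts[:, perm[:half]].mean(axis=1))
        h2.append(rec.counts[:, perm[half:]].mean(axis=1))
    a = np.concatenate(h1, axis=1)
    b = np.concatenate(h2, axis=1)
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    denom = np.sqrt((a * a).sum(axis=1) * (b * b).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (a * b).sum(axis=1) / denom, 0.0)
    return np.where(r > threshold)[0]


# ---------------------------------------------------------------------------
# cluster-mass permutation test


def _tscores(a: np.ndarray, b: np.ndarray, welch: bool) -> tuple[np.ndarray, np.ndarray]:
    """Two-sample t and df per column.  Zero pooled variance yields t=0 for
    equal means and +/-inf otherwise (noise-free injected effects)."""
    na, nb = a.shape[-2], b.shape[-2]
    ma, mb = a.mean(axis=-2), b.mean(axis=-2)
    va, vb = a.var(axis=-2, ddof=1), b.var(axis=-2, ddof=1)
    diff = ma - mb
    if welch:
        se2 = va / na + vb / nb
        with np.errstate(divide="ignore", invalid="ignore"):
            df = se2 ** 2 / (va ** 2 / (na ** 2 * (na - 1))
                             + vb ** 2 / (nb ** 2 * (nb - 1)))
        df = np.where(np.isfinite(df), df, na + nb - 2)
    else:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se2 = sp2 * (1.0 / na + 1.0 / nb)
        df = np.full_like(diff, na + nb - 2, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
        t = np.where(se2 > 0, t,
                     np.where(diff == 0, 0.0, np.sign(diff) * np.inf))
    return t, df


def _max_cluster_scores(t: np.ndarray, sig: np.ndarray) -> np.ndarray:
    """Max |sum of t over a contiguous same-sign significant run| per row.

    Vectorized over rows by scanning the (few) time bins once.
    """
    n_rows, n_bins = t.shape
    best = np.zeros(n_rows)
    cur = np.zeros(n_rows)
    cur_sign = np.zeros(n_rows)
    for j in range(n_bins):
        tj = t[:, j]
        sj = sig[:, j]
        sgn = np.sign(tj)
        cont = sj & (sgn == cur_sign) & (cur_sign != 0)
        cur = np.where(cont, cur + tj, np.where(sj, tj, 0.0))
        cur_sign = np.where(sj, sgn, 0.0)
        best = np.maximum(best, np.abs(cur))
    return best


def _observed_clusters(t: np.ndarray, sig: np.ndarray) -> list[tuple[int, int, float]]:
    """(start, end inclusive, score) of contiguous same-sign significant runs."""
    out = []
    for is_sig, grp in itertools.groupby(
            enumerate(zip(sig, np.sign(t))), key=lambda e: (e[1][0], e[1][1])):
        if not is_sig[0]:
            continue
        idx = [e[0] for e in grp]
        out.append((idx[0], idx[-1], float(t[idx[0]:idx[-1] + 1].sum())))
    return out


def cluster_mass_test(rA: np.ndarray, rB: np.ndarray, n_shuffles: int = 11000,
                      bin_alpha: float = 0.05, cluster_alpha: float = 0.05,
                      welch: bool = False, seed: int = 0,
                      rng: np.random.Generator | None = None) -> EffectProfile:
    """Cluster-mass permutation test between two sets of probe trials.

    ``rA``/``rB`` are (trials, bins) Z-scored responses.  Per-bin two-sample
    Student's t (pooled variance by default, Welch with ``welch=True``) at
    ``bin_alpha`` defines candidate clusters of contiguous same-sign bins;
    each observed cluster's p-value is the add-one tail probability of its
    |summed T| under the null of per-shuffle *maximum* |cluster score| over
    ``n_shuffles`` random reassignments of trials to contexts.
    """
    rA = np.asarray(rA, dtype=float)
    rB = np.asarray(rB, dtype=float)
    if rA.ndim != 2 or rB.ndim != 2 or rA.shape[1] != rB.shape[1]:
        raise ValueError("rA and rB must be (trials, bins) with equal bin counts")
    if rA.shape[0] < 2 or rB.shape[0] < 2:
        raise ValueError("need >= 2 trials per condition")
    nA, nB = rA.shape[0], rB.shape[0]
    n_bins = rA.shape[1]

    t_obs, df = _tscores(rA, rB, welch)
    finite = np.isfinite(t_obs)
    p_bin = np.ones(n_bins)
    p_bin[finite] = 2.0 * sps.t.sf(np.abs(t_obs[finite]), df[finite])
    p_bin[~finite] = 0.0  # zero variance, nonzero difference
    sig_bins = p_bin < bin_alpha
    delta = rA.mean(axis=0) - rB.mean(axis=0)

    clusters_obs = _observed_clusters(t_obs, sig_bins)
    if not clusters_obs:
        return EffectProfile(delta=delta, tscore=t_obs,
                             sig_mask=np.zeros(n_bins, bool), clusters=[])

    if rng is None:
        rng = np.random.default_rng(seed)
    pooled = np.concatenate([rA, rB], axis=0)
    n_tot = nA + nB
    null_max = np.empty(n_shuffles)
    chunk = max(1, int(2e6 // (n_tot * n_bins)))
    done = 0
    while done < n_shuffles:
        m = min(chunk, n_shuffles - done)
        idx = np.argsort(rng.random((m, n_tot)), axis=1)
        shuf = pooled[idx]  # (m, n_tot, bins)
        t_s, df_s = _tscores(shuf[:, :nA], shuf[:, nA:], welch)
        p_s = np.ones_like(t_s)
        fin = np.isfinite(t_s)
        p_s[fin] = 2.0 * sps.t.sf(np.abs(t_s[fin]), df_s[fin])
        p_s[~fin] = 0.0
        t_s = np.where(fin, t_s, np.sign(t_s) * 1e12)  # rankable stand-in for inf
        null_max[done:done + m] = _max_cluster_scores(t_s, p_s < bin_alpha)
        done += m

    out_clusters = []
    sig_mask = np.zeros(n_bins, bool)
    for start, end, score in clusters_obs:
        obs = abs(score) if np.isfinite(score) else 1e12
        p = (1.0 + np.count_nonzero(null_max >= obs)) / (n_shuffles + 1.0)
        out_clusters.append((start, end, score, float(p)))
        if p < cluster_alpha:
            sig_mask[start:end + 1] = True
    return EffectProfile(delta=delta, tscore=t_obs, sig_mask=sig_mask,
                         clusters=out_clusters)


def effect_metrics(profile: EffectProfile, bin_dt: float = 0.05) -> EffectMetrics:
    """Integral amplitude over significant bins and last-significant-bin duration.

    Amplitude is sum(|dZ|) * bin_dt over bins in significant clusters
    (Z-score*s); duration is the end time of the last significant bin
    ((index + 1) * bin width, ms).  Both are 0 with no significant bins.
    """
    mask = profile.sig_mask
    if not mask.any():
        return EffectMetrics(0.0, 0.0, False)
    amp = float(np.abs(profile.delta[mask]).sum() * bin_dt)
    last = int(np.max(np.nonzero(mask)[0]))
    return EffectMetrics(amp, (last + 1) * bin_dt * 1e3, True)


def correct_instances(p_values: np.ndarray, family_alpha: float = 0.05,
                      n_extra_comparisons: int = 1) -> np.ndarray:
    """Bonferroni significance across a neuron's contextual instances.

    The per-instance threshold is ``family_alpha / (n_instances *
    n_extra_comparisons)``; pass the number of neurons in a site as
    ``n_extra_comparisons`` for the site-union analysis.
    """
    p = np.asarray(p_values, dtype=float)
    if n_extra_comparisons < 1:
        raise ValueError("n_extra_comparisons must be >= 1")
    thresh = family_alpha / (p.size * n_extra_comparisons)
    return p < thresh


def amplitude_duration_association(profiles: list[EffectProfile],
                                   bin_dt: float = 0.05,
                                   n_shuffles: int = 1000,
                                   seed: int = 0) -> dict:
    """Test whether the amplitude-duration correlation exceeds its built-in
    baseline by shuffling bin order within each profile.

    Shuffling the time bins (with their significance) randomizes the
    last-bin duration while leaving the integral amplitude unchanged; the
    observed Pearson r(amplitude, duration) over significant profiles is
    compared to the null distribution of r under ``n_shuffles`` shuffles.
    """
    sig = [p for p in profiles if p.sig_mask.any()]
    if len(sig) < 3:
        raise ValueError("need >= 3 significant profiles")
    amps = np.array([effect_metrics(p, bin_dt).amplitude for p in sig])
    durs = np.array([effect_metrics(p, bin_dt).duration for p in sig])
    if np.ptp(durs) == 0 or np.ptp(amps) == 0:
        return {"r": np.nan, "p": np.nan, "null": np.array([]),
                "degenerate": True}
    r_obs = float(np.corrcoef(amps, durs)[0, 1])
    rng = np.random.default_rng(seed)
    n_bins = sig[0].delta.size
    null = np.empty(n_shuffles)
    masks = np.stack([p.sig_mask for p in sig])
    for s in range(n_shuffles):
        last = np.empty(len(sig))
        for k in range(len(sig)):
            perm = rng.permutation(n_bins)
            m = masks[k][perm]
            last[k] = (np.max(np.nonzero(m)[0]) + 1) * bin_dt * 1e3
        if np.ptp(last) == 0:
            null[s] = 0.0
        else:
            null[s] = np.corrcoef(amps, last)[0, 1]
    p = (1.0 + np.count_nonzero(null >= r_obs)) / (n_shuffles + 1.0)
    return {"r": r_obs, "p": float(p), "null": null, "degenerate": False}


def quantify_recording(rec: PopulationRecording, n_shuffles: int = 11000,
                       bin_alpha: float = 0.05, family_alpha: float = 0.05,
                       welch: bool = False, seed: int = 0,
                       neurons: np.ndarray | None = None,
                       segmented: SegmentedResponses | None = None,
                       keep_profiles: bool = False) -> pd.DataFrame | tuple:
    """Run the cluster-mass test for every neuron and contextual instance.

    Returns a tidy table with one row per (neuron, probe, context_a,
    context_b): ``amplitude_zs``, ``duration_ms``, ``min_cluster_p`` and
    ``significant`` (Bonferroni over the instances of each neuron).  With
    ``keep_profiles=True`` also returns the profiles keyed by row index.
    """
    z, kept = zscore_normalize(rec)
    seg = segmented if segmented is not None else segment_instances(rec, data=z)
    n = rec.sequences.n_sounds
    idx = np.arange(rec.n_neurons) if neurons is None else np.asarray(neurons)
    instances = [(p, ca, cb)
                 for p in range(1, n + 1)
                 for ca in range(0, n + 1)
                 for cb in range(ca + 1, n + 1)]
    rng = np.random.default_rng(seed)
    rows = []
    profiles = {}
    for i in idx:
        if not kept[i]:
            continue
        for (p, ca, cb) in instances:
            rA = seg.get(ca, p)[i]
            rB = seg.get(cb, p)[i]
            prof = cluster_mass_test(rA, rB, n_shuffles=n_shuffles,
                                     bin_alpha=bin_alpha, rng=rng, welch=welch)
            met = effect_metrics(prof, rec.bin_dt)
            rows.append((i, p, ca, cb, met.amplitude, met.duration,
                         prof.min_cluster_p))
            if keep_profiles:
                profiles[(i, p, ca, cb)] = prof
    df = pd.DataFrame(rows, columns=["neuron", "probe", "context_a",
                                     "context_b", "amplitude_zs",
                                     "duration_ms", "min_cluster_p"])
    sig = np.zeros(len(df), dtype=bool)
    for i in df.neuron.unique():
        m = df.neuron == i
        sig[m.to_numpy()] = correct_instances(df.loc[m, "min_cluster_p"].to_numpy(),
                                              family_alpha=family_alpha)
    df["significant"] = sig
    if keep_profiles:
        return df, profiles
    return df
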