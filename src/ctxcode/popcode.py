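"""Population-level analyses of context coding.

Coverage of the context space is the percentage of contextual instances in
which an entity shows a significant context effect.  Site-level aggregates
(union across neurons, best neuron, first principal component of population
activity) bound the context information available downstream.  The
dense-code transform rotates each per-(context, probe, time) population
modulation vector onto the equal-activity diagonal, preserving its L2 norm
and every neuron's mean probe response, to ask whether the observed sparse,
neuron-specific arrangement of context effects is what supports linear
decodability.  Per-bin linear SVM decoding quantifies context and probe
information over the probe window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .ctxfx import correct_instances, quantify_recording, zscore_normalize
from .synthgen import PopulationRecording, segment_instances

__all__ = [
    "neuron_coverage",
    "site_union",
    "site_coverage_summary",
    "best_neuron",
    "pc1_trace",
    "pc1_coverage",
    "DenseTransform",
    "densify",
    "DecodingTimecourse",
    "decode_timecourse",
]


def neuron_coverage(effects: pd.DataFrame, n_instances: int) -> pd.DataFrame:
    """Percent of instances with significant context effects, per neuron."""
    g = effects.groupby("neuron")
    out = pd.DataFrame({
        "n_significant": g.significant.sum().astype(int),
        "total_amplitude": g.apply(
            lambda d: d.loc[d.significant, "amplitude_zs"].sum(),
            include_groups=False),
    })
    out["coverage_pct"] = 100.0 * out.n_significant / n_instances
    return out.reset_index()


def site_union(effects: pd.DataFrame, n_neurons: int | None = None,
               family_alpha: float = 0.05) -> pd.DataFrame:
    """Union of context effects across the neurons of a site.

    Significance is re-corrected with the neuron count as an extra
    Bonferroni factor; per instance, the union records the largest
    significant amplitude across neurons (0 if none).
    """
    if effects.empty:
        raise ValueError("empty site")
    if n_neurons is None:
        n_neurons = effects.neuron.nunique()
    df = effects.copy()
    sig = np.zeros(len(df), dtype=bool)
    for i in df.neuron.unique():
        m = (df.neuron == i).to_numpy()
        sig[m] = correct_instances(df.loc[m, "min_cluster_p"].to_numpy(),
                                   family_alpha=family_alpha,
                                   n_extra_comparisons=n_neurons)
    df["significant"] = sig
    df["amp_sig"] = np.where(sig, df.amplitude_zs, 0.0)
    union = (df.groupby(["probe", "context_a", "context_b"], as_index=False)
             .agg(amplitude_zs=("amp_sig", "max"),
                  n_significant_neurons=("significant", "sum")))
    union["significant"] = union.n_significant_neurons > 0
    return union


def site_coverage_summary(effects: pd.DataFrame, n_instances: int,
                          site_corrected: bool = True,
                          family_alpha: float = 0.05) -> pd.DataFrame:
    """Mean single-neuron, best-neuron and union coverage of one site.

    With ``site_corrected=True`` all three entities are computed from the
    same table, Bonferroni-corrected for both instance and neuron counts,
    which guarantees the union >= best >= mean ordering by construction
    (the union covers an instance whenever any constituent does).
    """
    n_neurons = effects.neuron.nunique()
    if site_corrected:
        df = effects.copy()
        sig = np.zeros(len(df), dtype=bool)
        for i in df.neuron.unique():
            m = (df.neuron == i).to_numpy()
            sig[m] = correct_instances(df.loc[m, "min_cluster_p"].to_numpy(),
                                       family_alpha=family_alpha,
                                       n_extra_comparisons=n_neurons)
        df["significant"] = sig
    else:
        df = effects
    cov = neuron_coverage(df, n_instances)
    union = site_union(df, n_neurons=n_neurons,
                       family_alpha=family_alpha) if site_corrected else \
        site_union(effects, n_neurons=n_neurons, family_alpha=family_alpha)
    return pd.DataFrame({
        "entity": ["mean_neuron", "best_neuron", "union"],
        "coverage_pct": [
            float(cov.coverage_pct.mean()),
            float(cov.coverage_pct.max()),
            100.0 * float(union.significant.sum()) / n_instances,
        ],
    })


def best_neuron(effects: pd.DataFrame) -> int:
    """Neuron with the greatest contextual coverage.

    Ties on significant-instance count are broken by larger summed
    significant amplitude, then by lowest neuron id.
    """
    cov = neuron_coverage(effects, n_instances=1)
    cov = cov.sort_values(["n_significant", "total_amplitude", "neuron"],
                          ascending=[False, False, True])
    return int(cov.neuron.iloc[0])


def pc1_trace(rec: PopulationRecording, var_threshold: float = 0.90
              ) -> tuple[np.ndarray, PCA]:
    """Single-trial projection onto the first PC of trial-averaged activity.

    The PCA basis is fitted on trial-averaged Z-scored responses to the
    sequences (time x neuron samples, concatenated over sequences), keeping
    the PCs that explain ``var_threshold`` of the variance; single trials
    are then projected and the first PC returned as a (trials, time)
    pseudo-neuron.  PC1 sign is fixed by positive correlation with the mean
    population activity.
    """
    if rec.n_neurons < 2:
        raise ValueError("need >= 2 neurons for PCA")
    z, _ = zscore_normalize(rec)
    seq_ids = rec.trial_table.sequence.to_numpy()
    means = []
    for si in np.unique(seq_ids):
        means.append(z[:, seq_ids == si].mean(axis=1))  # (I, T)
    train = np.concatenate(means, axis=1).T  # (n_seq * T, I)
    pca = PCA()
    pca.fit(train)
    n_keep = int(np.searchsorted(np.cumsum(pca.explained_variance_ratio_),
                                 var_threshold) + 1)
    pca = PCA(n_components=n_keep).fit(train)
    I, n_trials, T = z.shape
    flat = z.reshape(I, -1).T  # (n_trials * T, I)
    proj = pca.transform(flat)[:, 0].reshape(n_trials, T)
    popmean = z.mean(axis=0).ravel()
    if np.corrcoef(proj.ravel(), popmean)[0, 1] < 0:
        proj = -proj
    return proj, pca


def pc1_coverage(rec: PopulationRecording, n_shuffles: int = 1000,
                 seed: int = 0, family_alpha: float = 0.05) -> pd.DataFrame:
    """Context-effect table for the PC1 pseudo-neuron.

    The projected single-trial PC1 trace is analyzed exactly like a neuron:
    segmented by (context, probe) event, cluster-mass tested per instance,
    Bonferroni-corrected across instances.
    """
    from .ctxfx import cluster_mass_test, effect_metrics

    proj, _ = pc1_trace(rec)
    seg = segment_instances(rec, data=proj[None])
    n = rec.sequences.n_sounds
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(1, n + 1):
        for ca in range(0, n + 1):
            for cb in range(ca + 1, n + 1):
                prof = cluster_mass_test(seg.get(ca, p)[0], seg.get(cb, p)[0],
                                         n_shuffles=n_shuffles, rng=rng)
                met = effect_metrics(prof, rec.bin_dt)
                rows.append((p, ca, cb, met.amplitude, met.duration,
                             prof.min_cluster_p))
    df = pd.DataFrame(rows, columns=["probe", "context_a", "context_b",
                                     "amplitude_zs", "duration_ms",
                                     "min_cluster_p"])
    df["significant"] = correct_instances(df.min_cluster_p.to_numpy(),
                                          family_alpha=family_alpha)
    return df


# ---------------------------------------------------------------------------
# dense-code transform


@dataclass
class DenseTransform:
    """Stages of the dense-code transformation.

    All arrays are (neurons, contexts, probes, trials, time) except where
    noted.  ``r_tilde`` is the rotated response (population context
    modulation equalized across neurons, L2 norm per (context, probe, time)
    preserved under the default magnitude convention); ``r_hat`` adds the
    across-context variance correction of the trial-averaged responses.
    """

    r: np.ndarray
    r_bar: np.ndarray  # (I, P, T) context/trial-averaged probe response
    m: np.ndarray  # (I, C, P, T) context modulation
    l: np.ndarray  # (I, C, P, T) rotation offsets
    r_tilde: np.ndarray
    v: np.ndarray  # (I, P, T) across-context variance, original
    v_tilde: np.ndarray  # (I, P, T) same, rotated
    r_hat: np.ndarray
    magnitude: str
    variance: str

    def modulation(self, which: str = "rotated") -> np.ndarray:
        """Recompute m from a stage of the transform."""
        x = {"original": self.r, "rotated": self.r_tilde,
             "corrected": self.r_hat}[which]
        bar = x.mean(axis=(1, 3), keepdims=True)
        return (x.mean(axis=3) - bar[:, :, :, 0])


def densify(r: np.ndarray, magnitude: str = "norm",
            variance: str = "ratio", recenter: bool = True) -> DenseTransform:
    """Equalize context effects across neurons while preserving probe coding.

    ``r`` is (neurons, contexts, probes, trials, time).  Each population
    context-modulation vector m(c, p, t) is rotated onto the equal-activity
    diagonal: with ``magnitude='norm'`` (default) each component becomes
    sign(mean m) * ||m||_2 / sqrt(I), preserving the vector's L2 norm;
    ``magnitude='mean'`` uses ||m||_2 / I as printed in some renderings.
    The rotation is applied to single trials, and the across-context
    variance of trial-averaged responses is then restored by scaling the
    rotated context component by <v>_i / v~ (``variance='ratio'``) or its
    square root (``variance='sqrt'``).

    Because the diagonal targets need not average to zero across contexts,
    the raw rotation can shift a neuron's context-averaged probe response;
    with ``recenter=True`` (default) a final per-(neuron, probe, time)
    offset restores every mean probe response exactly.  The offset is
    constant across contexts and trials, so it leaves the across-context
    modulation structure (equality across neurons, cluster profiles,
    decoding geometry) untouched.

    With a single neuron or a single context the transform is the identity.
    """
    r = np.asarray(r, dtype=float)
    if r.ndim != 5:
        raise ValueError("r must be (neurons, contexts, probes, trials, time)")
    I, C, P, J, T = r.shape
    r_bar = r.mean(axis=(1, 3))  # (I, P, T)
    m = r.mean(axis=3) - r_bar[:, None]  # (I, C, P, T)
    if I == 1 or C == 1:
        v = ((r.mean(axis=3) ** 2).mean(axis=1) - r.mean(axis=(1, 3)) ** 2)
        return DenseTransform(r=r, r_bar=r_bar, m=m, l=np.zeros_like(m),
                              r_tilde=r.copy(), v=v, v_tilde=v.copy(),
                              r_hat=r.copy(), magnitude=magnitude,
                              variance=variance)
    norm = np.linalg.norm(m, axis=0)  # (C, P, T)
    if magnitude == "norm":
        target = np.sign(m.mean(axis=0)) * norm / np.sqrt(I)
        target = np.where(target == 0, norm / np.sqrt(I), target)
    elif magnitude == "mean":
        target = np.broadcast_to(norm / I, m.shape[1:]).copy()
    else:
        raise ValueError(f"unknown magnitude convention {magnitude!r}")
    l = m - target[None]
    r_tilde = r - l[:, :, :, None, :]

    def across_context_var(x):
        tm = x.mean(axis=3)  # (I, C, P, T)
        return (tm ** 2).mean(axis=1) - x.mean(axis=(1, 3)) ** 2

    v = across_context_var(r)
    v_tilde = across_context_var(r_tilde)
    rt_c = r_tilde.mean(axis=(2, 3))  # (I, C, T) rotated context component
    ratio = np.where(v_tilde > 0, v.mean(axis=0, keepdims=True) / v_tilde, 1.0)
    if variance == "sqrt":
        ratio = np.sqrt(ratio)
    elif variance != "ratio":
        raise ValueError(f"unknown variance convention {variance!r}")
    # r_hat = r_tilde - r_tilde_ic + r_tilde_ic * ratio_ip
    corr = rt_c[:, :, None, None, :] * (ratio[:, None, :, None, :] - 1.0)
    r_hat = r_tilde + corr
    if recenter:
        offset = r_hat.mean(axis=(1, 3)) - r_bar  # (I, P, T)
        r_hat = r_hat - offset[:, None, :, None, :]
    return DenseTransform(r=r, r_bar=r_bar, m=m, l=l, r_tilde=r_tilde,
                          v=v, v_tilde=v_tilde, r_hat=r_hat,
                          magnitude=magnitude, variance=variance)


# ---------------------------------------------------------------------------
# decoding


@dataclass
class DecodingTimecourse:
    accuracy: np.ndarray  # per analyzed bin
    bins: np.ndarray
    chance: float
    label_kind: str


def decode_timecourse(r: np.ndarray, label_kind: str = "context",
                      n_folds: int = 4, seed: int = 0,
                      bins: np.ndarray | None = None,
                      C: float = 1.0) -> DecodingTimecourse:
    """Per-bin linear SVM decoding of context or probe labels.

    ``r`` is (neurons, contexts, probes, trials, time).  At each time bin
    the single-trial population vectors are standardized and classified
    with a linear max-margin classifier under stratified ``n_folds``-fold
    cross-validation; accuracy is averaged over folds.  Chance is the
    reciprocal of the number of classes.
    """
    r = np.asarray(r, dtype=float)
    I, Cc, P, J, T = r.shape
    if label_kind == "context":
        labels = np.broadcast_to(np.arange(Cc)[:, None, None], (Cc, P, J))
    elif label_kind == "probe":
        labels = np.broadcast_to(np.arange(P)[None, :, None], (Cc, P, J))
    else:
        raise ValueError("label_kind must be 'context' or 'probe'")
    y = labels.reshape(-1)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need >= 2 label classes")
    if counts.min() < 2 * n_folds:
        raise ValueError(f"need >= {2 * n_folds} trials per class")
    X_all = r.reshape(I, Cc * P * J, T)
    if bins is None:
        bins = np.arange(T)
    bins = np.asarray(bins)
    acc = np.empty(bins.size)
    for k, t in enumerate(bins):
        X = X_all[:, :, t].T  # (trials, neurons)
        cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        scores = []
        for train, test in cv.split(X, y):
            clf = make_pipeline(
                StandardScaler(),
                LinearSVC(C=C, max_iter=5000, random_state=seed))
            clf.fit(X[train], y[train])
            scores.append(clf.score(X[test], y[test]))
        acc[k] = float(np.mean(scores))
    return DecodingTimecourse(accuracy=acc, bins=bins,
                              chance=1.0 / classes.size, label_kind=label_kind)
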