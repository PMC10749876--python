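"""Generalized linear encoding models with population-history terms.

Four models share one architecture: a spectro-temporal receptive field
(STRF; 18 spectral channels x 30 10-ms lags, 0-300 ms), a scalar weight on
the neuron's own mean activity 150-300 ms in the past, one weight per
simultaneously recorded neighbour over the same window, and a bias, passed
through a rectified linear unit.  The variants differ only in which history
inputs are temporally scrambled (circular shifts by random tens of
seconds): *STRF* scrambles self and population, *Self* scrambles the
population, *Pop* scrambles the self input, *Full* scrambles nothing.
Scrambling removes predictive value while keeping the parameter count
identical, so performance differences reflect the predictors, not
estimation noise.

Fitting minimizes the mean squared error of the rectified output with ADAM
(seeded, ridge-initialized), holding out one stimulus sequence per fold;
performance is Pearson's R over the concatenated held-out predictions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import jackknife_ci

__all__ = [
    "DesignSpec",
    "prepare_encoding_inputs",
    "build_design",
    "ModelFit",
    "fit_model",
    "fit_variants",
    "compare_models",
    "predict_context_effects",
    "summarize_coupling",
]

VARIANTS = ("STRF", "Self", "Pop", "Full")


@dataclass
class DesignSpec:
    """Design tensor for one target neuron and variant."""

    X: np.ndarray  # (n_samples, n_features)
    y: np.ndarray  # (n_samples,)
    fold_ids: np.ndarray  # sequence index per sample
    n_channels: int
    n_lags: int
    pop_sources: np.ndarray  # neuron ids of the population columns
    variant: str

    @property
    def slices(self) -> dict:
        k = self.n_channels * self.n_lags
        return {"strf": slice(0, k), "self": slice(k, k + 1),
                "pop": slice(k + 1, self.X.shape[1])}


def _window_mean(x: np.ndarray, lo: int, hi: int) -> np.ndarray:
    """mean of x[..., t-hi .. t-lo] along the last axis, zero-padded."""
    n = hi - lo + 1
    kern_len = hi + 1
    pad = np.concatenate([np.zeros(x.shape[:-1] + (kern_len,)), x], axis=-1)
    cs = np.cumsum(pad, axis=-1)
    T = x.shape[-1]
    t = np.arange(T) + kern_len
    return (cs[..., t - lo] - cs[..., t - hi - 1]) / n


def _lagged(stim: np.ndarray, n_lags: int) -> np.ndarray:
    """(T, channels * n_lags) lagged copies of a (channels, T) spectrogram."""
    C, T = stim.shape
    out = np.zeros((T, C, n_lags))
    for lag in range(n_lags):
        out[lag:, :, lag] = stim[:, :T - lag].T
    return out.reshape(T, C * n_lags)


def _scramble(resp_flat: np.ndarray, rng: np.random.Generator,
              fine_dt: float, shift_range_s=(10.0, 60.0)) -> np.ndarray:
    """Independent circular time-shifts per source row, in random tens of
    seconds; shifts collapse modulo the recording length (with a warning and
    a minimum effective shift of one history window)."""
    out = np.empty_like(resp_flat)
    T = resp_flat.shape[-1]
    min_shift = int(round(0.3 / fine_dt))
    for j in range(resp_flat.shape[0]):
        shift = int(round(rng.uniform(*shift_range_s) / fine_dt))
        if shift >= T:
            warnings.warn("scramble shift exceeds recording length; "
                          "taken modulo length")
            shift = shift % T
        if shift < min_shift:
            shift = min_shift
        out[j] = np.roll(resp_flat[j], shift)
    return out


def build_design(spectrograms: np.ndarray, responses: np.ndarray,
                 target: int, variant: str = "Full",
                 n_lags: int = 30, history_bins: tuple[int, int] = (15, 29),
                 fine_dt: float = 0.01, scramble_seed: int = 0) -> DesignSpec:
    """Predictors for one neuron: STRF lags + windowed self/pop history.

    ``spectrograms`` is (n_seq, channels, T) at 100 Hz; ``responses`` is
    (neurons, n_seq, T) trial-averaged activity, normalized to each
    neuron's peak.  History features average activity over lags
    ``history_bins`` (inclusive, in 10-ms steps; default 15-29, i.e. the
    window 150-300 ms before the predicted bin).  The variant determines
    which history sources are scrambled.
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}")
    stim = np.asarray(spectrograms, dtype=float)
    resp = np.asarray(responses, dtype=float)
    I, n_seq, T = resp.shape
    rng = np.random.default_rng(scramble_seed)

    flat = resp.reshape(I, n_seq * T)
    scrambled = _scramble(flat, rng, fine_dt)
    scramble_self = variant in ("STRF", "Pop")
    scramble_pop = variant in ("STRF", "Self")
    self_src = (scrambled if scramble_self else flat)[target].reshape(n_seq, T)
    pop_ids = np.array([j for j in range(I) if j != target], dtype=int)
    pop_src = (scrambled if scramble_pop else flat)[pop_ids].reshape(
        len(pop_ids), n_seq, T)

    lo, hi = history_bins
    self_h = _window_mean(self_src, lo, hi)  # (n_seq, T)
    pop_h = _window_mean(pop_src, lo, hi)  # (n_pop, n_seq, T)

    X_rows, y_rows, folds = [], [], []
    for s in range(n_seq):
        lagged = _lagged(stim[s], n_lags)
        cols = [lagged, self_h[s][:, None], pop_h[:, s, :].T]
        X_rows.append(np.concatenate(cols, axis=1))
        y_rows.append(resp[target, s])
        folds.append(np.full(T, s))
    return DesignSpec(
        X=np.concatenate(X_rows, axis=0), y=np.concatenate(y_rows),
        fold_ids=np.concatenate(folds), n_channels=stim.shape[1],
        n_lags=n_lags, pop_sources=pop_ids, variant=variant)


def prepare_encoding_inputs(rec, seed: int = 0,
                            family: str = "naturalistic"
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Stimulus spectrograms and trial-averaged responses for model fitting.

    Returns ``(spectrograms, responses)``: per-sequence 18-channel
    100-Hz spectrograms of the sound sequences (silence floor prepended
    for position-0 context is not needed: sequences start with a sound)
    and per-neuron trial-averaged 100-Hz responses normalized to each
    neuron's peak.
    """
    from .stimdesign import synthesize_sound_spectrogram

    seqs = rec.sequences.sequences
    specs = []
    for seq in seqs:
        parts = [synthesize_sound_spectrogram(s, seed=seed, family=family).values
                 for s in seq]
        specs.append(np.concatenate(parts, axis=1))
    spectrograms = np.stack(specs)  # (n_seq, 18, T_fine)
    seq_ids = rec.trial_table.sequence.to_numpy()
    means = []
    for si in range(len(seqs)):
        means.append(rec.fine_counts[:, seq_ids == si].mean(axis=1))
    resp = np.stack(means, axis=1)  # (I, n_seq, T_fine)
    peak = np.abs(resp).max(axis=(1, 2), keepdims=True)
    peak = np.where(peak > 0, peak, 1.0)
    return spectrograms, resp / peak


# ---------------------------------------------------------------------------


@dataclass
class ModelFit:
    weights: np.ndarray  # full-data fit, (n_features,)
    bias: float
    fold_weights: list = field(default_factory=list)
    predictions: np.ndarray | None = None  # held-out, concatenated
    prediction_r: float = np.nan
    converged: bool = True
    variant: str = "Full"
    spec: DesignSpec | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.maximum(self.X_linear(X), 0.0)

    def X_linear(self, X: np.ndarray) -> np.ndarray:
        return X @ self.weights + self.bias

    @property
    def strf(self) -> np.ndarray:
        sl = self.spec.slices["strf"]
        return self.weights[sl].reshape(self.spec.n_channels,
                                        self.spec.n_lags)

    @property
    def w_self(self) -> float:
        return float(self.weights[self.spec.slices["self"]][0])

    @property
    def w_pop(self) -> np.ndarray:
        return self.weights[self.spec.slices["pop"]]


def _adam_fit(X, y, w0, b0, lr=1e-3, epochs=300, val_frac=0.1,
              patience=25, seed=0):
    """Full-batch ADAM on MSE of relu(Xw + b), early stopping on a held-out
    in-fold slice.  Returns (w, b, converged)."""
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    idx = rng.permutation(n)
    n_val = max(int(val_frac * n), 1)
    vi, ti = idx[:n_val], idx[n_val:]
    Xt, yt, Xv, yv = X[ti], y[ti], X[vi], y[vi]
    theta = np.concatenate([w0, [b0]])
    m = np.zeros_like(theta)
    v = np.zeros_like(theta)
    best = theta.copy()
    best_loss = np.inf
    wait = 0
    b1, b2, eps = 0.9, 0.999, 1e-8
    for ep in range(1, epochs + 1):
        z = Xt @ theta[:-1] + theta[-1]
        pred = np.maximum(z, 0.0)
        err = (pred - yt) * (z > 0)
        g = np.concatenate([Xt.T @ err, [err.sum()]]) * (2.0 / yt.size)
        m = b1 * m + (1 - b1) * g
        v = b2 * v + (1 - b2) * g * g
        mh = m / (1 - b1 ** ep)
        vh = v / (1 - b2 ** ep)
        theta -= lr * mh / (np.sqrt(vh) + eps)
        pv = np.maximum(Xv @ theta[:-1] + theta[-1], 0.0)
        loss = float(((pv - yv) ** 2).mean())
        if loss < best_loss - 1e-9:
            best_loss, best, wait = loss, theta.copy(), 0
        else:
            wait += 1
            if wait > patience:
                return best[:-1], float(best[-1]), True
    return best[:-1], float(best[-1]), False


def _ridge_init(X, y, lam=1e-3):
    n, f = X.shape
    mu = X.mean(axis=0)
    Xc = X - mu
    A = Xc.T @ Xc + lam * n * np.eye(f)
    w = np.linalg.solve(A, Xc.T @ (y - y.mean()))
    b = float(y.mean() - mu @ w)
    return w, b


def fit_model(design: DesignSpec, lr: float = 1e-3, epochs: int = 300,
              seed: int = 0, ridge_lambda: float = 1e-3) -> ModelFit:
    """Cross-validated fit: one fold per stimulus sequence.

    Each fold is fitted on the remaining sequences (ridge warm start, then
    seeded ADAM with early stopping) and predicts the held-out sequence;
    ``prediction_r`` is Pearson's R over the concatenated held-out
    predictions.  The returned weights come from a final fit to all data.
    """
    X, y, folds = design.X, design.y, design.fold_ids
    preds = np.empty_like(y)
    fold_ws = []
    converged = True
    for k, f in enumerate(np.unique(folds)):
        tr, te = folds != f, folds == f
        w0, b0 = _ridge_init(X[tr], y[tr], ridge_lambda)
        w, b, ok = _adam_fit(X[tr], y[tr], w0, b0, lr=lr, epochs=epochs,
                             seed=seed + k)
        converged &= ok
        preds[te] = np.maximum(X[te] @ w + b, 0.0)
        fold_ws.append((w, b))
    if not converged:
        warnings.warn("ADAM did not reach early stopping in some fold; "
                      "best iterate kept")
    if preds.std() == 0 or y.std() == 0:
        r = 0.0
    else:
        r = float(np.corrcoef(preds, y)[0, 1])
    w0, b0 = _ridge_init(X, y, ridge_lambda)
    w, b, _ = _adam_fit(X, y, w0, b0, lr=lr, epochs=epochs, seed=seed)
    return ModelFit(weights=w, bias=b, fold_weights=fold_ws,
                    predictions=preds, prediction_r=r, converged=converged,
                    variant=design.variant, spec=design)


def fit_variants(spectrograms, responses, target, scramble_seed=0,
                 **fit_kw) -> dict[str, ModelFit]:
    """Fit all four variants for one neuron with shared scramble shifts."""
    out = {}
    for variant in VARIANTS:
        d = build_design(spectrograms, responses, target, variant,
                         scramble_seed=scramble_seed)
        out[variant] = fit_model(d, **fit_kw)
    return out


def compare_models(fits_per_neuron: list[dict[str, "ModelFit"]]) -> pd.DataFrame:
    """Paired Wilcoxon signed-rank tests on absolute prediction R.

    All variant pairs are compared across neurons, Bonferroni-corrected
    over the number of pairs; relative-to-Full mean fractions are included
    for display parity.
    """
    if len(fits_per_neuron) < 6:
        warnings.warn("fewer than 6 neurons: p-values unreliable")
    rs = {v: np.array([abs(d[v].prediction_r) for d in fits_per_neuron])
          for v in fits_per_neuron[0]}
    variants = list(rs)
    pairs = [(a, b) for i, a in enumerate(variants)
             for b in variants[i + 1:]]
    rows = []
    full = rs.get("Full")
    for a, b in pairs:
        diff = rs[a] - rs[b]
        if np.allclose(diff, 0):
            stat, p = np.nan, 1.0
        else:
            stat, p = sps.wilcoxon(rs[a], rs[b])
        rows.append({
            "variant_a": a, "variant_b": b,
            "mean_r_a": rs[a].mean(), "mean_r_b": rs[b].mean(),
            "frac_full_a": (rs[a] / full).mean() if full is not None else np.nan,
            "frac_full_b": (rs[b] / full).mean() if full is not None else np.nan,
            "wilcoxon_stat": stat,
            "p_bonf": min(float(p) * len(pairs), 1.0) if len(pairs) > 1 else float(p),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# context-effect prediction


def predict_context_effects(fit: ModelFit, spectrograms, responses, target,
                            effects: pd.DataFrame, rec,
                            n_jackknife: int = 200,
                            fine_dt: float = 0.01) -> dict:
    """Compare predicted and actual context-effect amplitude per interval.

    The fitted model predicts the context-probe recording using the actual
    recorded histories as inputs (teacher forcing, never scrambled).  For
    each contextual instance significant in the data, |predicted probe
    response A - B| and the matching actual |difference| are integrated
    over four non-overlapping 250-ms intervals of the probe window on 0-1
    normalized responses; per interval, Pearson r(actual, predicted) is
    reported with a jackknifed std.
    """
    design = build_design(spectrograms, responses, target, variant="Full",
                          fine_dt=fine_dt)
    pred = fit.predict(design.X)
    resp = np.asarray(responses, dtype=float)[target]
    n_seq, T = resp.shape
    pred = pred.reshape(n_seq, T)

    def unit_norm(x):
        lo, hi = x.min(), x.max()
        return (x - lo) / (hi - lo) if hi > lo else np.zeros_like(x)

    pred_n = unit_norm(pred)
    act_n = unit_norm(resp)

    fine_per_sound = int(round(1.0 / fine_dt))
    iv_bins = fine_per_sound // 4
    seqs = rec.sequences.sequences
    windows = {}
    for si, seq in enumerate(seqs):
        prev = 0
        for k, s in enumerate(seq):
            sl = slice(k * fine_per_sound, (k + 1) * fine_per_sound)
            windows[(prev, s)] = (si, sl)
            prev = s
    sig = effects[(effects.neuron == target) & effects.significant]
    rows = []
    for r in sig.itertuples():
        wa = windows.get((r.context_a, r.probe))
        wb = windows.get((r.context_b, r.probe))
        if wa is None or wb is None:
            continue
        dp = np.abs(pred_n[wa[0], wa[1]] - pred_n[wb[0], wb[1]])
        da = np.abs(act_n[wa[0], wa[1]] - act_n[wb[0], wb[1]])
        entry = {"probe": r.probe, "context_a": r.context_a,
                 "context_b": r.context_b}
        for k in range(4):
            sl = slice(k * iv_bins, (k + 1) * iv_bins)
            entry[f"pred_iv{k + 1}"] = dp[sl].mean()
            entry[f"actual_iv{k + 1}"] = da[sl].mean()
        rows.append(entry)
    table = pd.DataFrame(rows)
    out = {"table": table, "interval_r": {}, "interval_r_std": {}}
    for k in range(4):
        if len(table) < 3:
            out["interval_r"][k + 1] = np.nan
            out["interval_r_std"][k + 1] = np.nan
            continue
        a = table[f"actual_iv{k + 1}"].to_numpy()
        p = table[f"pred_iv{k + 1}"].to_numpy()
        if a.std() == 0 or p.std() == 0:
            out["interval_r"][k + 1] = 0.0
            out["interval_r_std"][k + 1] = 0.0
            continue
        r_obs = float(np.corrcoef(a, p)[0, 1])
        idx = np.arange(len(a))
        jk = jackknife_ci(idx, statistic=lambda ii: np.corrcoef(
            a[ii.astype(int)], p[ii.astype(int)])[0, 1],
            n_folds=n_jackknife)
        out["interval_r"][k + 1] = r_obs
        out["interval_r_std"][k + 1] = jk["std"]
    return out


def summarize_coupling(fits_per_neuron: dict[int, "ModelFit"],
                       cell_classes: pd.Series) -> pd.DataFrame:
    """Mean incoming and outgoing population weights grouped by cell class.

    ``fits_per_neuron`` maps target neuron id to a Pop or Full fit;
    ``cell_classes`` maps neuron id to its class label.  Outgoing weights
    of a class are the w_pop entries whose *source* belongs to the class;
    incoming weights are those whose *target* does.
    """
    incoming: dict[str, list] = {}
    outgoing: dict[str, list] = {}
    for tgt, fit in fits_per_neuron.items():
        w = fit.w_pop
        tgt_cls = cell_classes.get(tgt)
        if tgt_cls is not None:
            incoming.setdefault(tgt_cls, []).extend(w.tolist())
        for src, wj in zip(fit.spec.pop_sources, w):
            src_cls = cell_classes.get(int(src))
            if src_cls is not None:
                outgoing.setdefault(src_cls, []).append(float(wj))
    classes = sorted(set(incoming) | set(outgoing))
    rows = []
    for c in classes:
        rows.append({
            "cell_class": c,
            "incoming_mean": float(np.mean(incoming[c])) if c in incoming else np.nan,
            "outgoing_mean": float(np.mean(outgoing[c])) if c in outgoing else np.nan,
            "n_incoming": len(incoming.get(c, [])),
            "n_outgoing": len(outgoing.get(c, [])),
        })
    return pd.DataFrame(rows)
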