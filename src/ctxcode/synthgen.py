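"""Synthetic population recordings with known ground-truth context effects.

The generator emulates the structure of an awake auditory-cortex recording
during context-probe sequences: tens of neurons, ~20 repetitions of each of
N sequences of N+1 one-second sounds, spike counts binned at 20 Hz for the
context-effect analyses and at 100 Hz for the encoding models, per-neuron
metadata (cortical region, spike peak-to-trough delay, optotag flag), a slow
pupil trace, and optional neuron-to-neuron lagged coupling.

Context effects are injected as per-(neuron, context, probe) modulations of
the probe-window firing rate.  Each modulation is specified in the analysis'
own units (Z-score x s of integrated absolute difference, ms of duration)
and converted to firing rate through the neuron's predicted single-trial
rate standard deviation; the returned ground truth re-expresses it through
the *empirical* normalization of the generated recording, so that in the
noise-free limit the downstream estimates match the injected values exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .stimdesign import SILENCE_ID, SequenceSet, design_sequences

__all__ = [
    "SimConfig",
    "PopulationRecording",
    "GroundTruth",
    "SegmentedResponses",
    "simulate_population",
    "simulate_pupil_condition",
    "segment_instances",
]


@dataclass
class SimConfig:
    """Parameters of the synthetic recording.

    Rates are in spikes/s; effect amplitudes in Z-score*s and durations in
    ms, matching the units of the downstream metrics.  ``effect_sparsity``
    is the target fraction of (neuron, contextual-instance) pairs carrying a
    true effect.
    """

    n_neurons: int = 20
    n_reps: int = 20
    n_sounds: int = 4
    bin_dt: float = 0.05  # 20 Hz analysis rate
    fine_dt: float = 0.01  # 100 Hz encoding-model rate
    baseline_rate: float = 5.0
    probe_gain: float = 10.0  # scale of per neuron x sound evoked rates
    effect_sparsity: float = 0.1
    effect_amplitude_range: tuple[float, float] = (0.05, 0.8)
    effect_duration_range: tuple[float, float] = (50.0, 1000.0)
    effect_shape: str = "exponential-decay"  # | late-onset | multi-peak | mixed
    effect_sign: str = "both"  # | positive (avoids rate clipping at 0)
    noise_model: str = "poisson"  # | gaussian | none
    noise_sigma: float = 1.0  # gaussian: std of 50-ms-binned single-trial rate
    region_labels: tuple[str, str] = ("A1", "dPEG")
    dpeg_amplitude_scale: float = 1.1  # secondary field carries larger effects
    dpeg_duration_scale: float = 1.05
    ptd_modes_ms: tuple[float, float] = (0.25, 0.70)
    ptd_stds_ms: tuple[float, float] = (0.04, 0.08)
    narrow_fraction: float = 0.2
    optotag_fraction: float = 0.3  # of narrow-spiking neurons
    pupil_params: dict = field(default_factory=lambda: {
        "baseline": 1.0, "drift_amp": 0.3, "drift_period": 40.0,
        "noise": 0.05, "evoked": 0.05,
    })
    pupil_gain_range: tuple[float, float] = (0.0, 0.0)
    coupling: Optional[np.ndarray] = None  # (I, I) rate-per-rate weights
    coupling_window: tuple[float, float] = (0.15, 0.30)  # s before t
    seed: int = 0

    def __post_init__(self):
        if min(self.n_neurons, self.n_reps, self.n_sounds) < 1:
            raise ValueError("counts must be >= 1")
        if not 0 <= self.effect_sparsity <= 1:
            raise ValueError("effect_sparsity must lie in [0, 1]")
        if self.baseline_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.noise_model not in ("poisson", "gaussian", "none"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        steps = self.bin_dt / self.fine_dt
        if abs(steps - round(steps)) > 1e-9:
            raise ValueError("bin_dt must be a multiple of fine_dt")


@dataclass
class PopulationRecording:
    """Binned spike counts plus aligned trial/neuron metadata."""

    counts: np.ndarray  # (neurons, trials, time) at bin_dt
    fine_counts: np.ndarray  # (neurons, trials, time) at fine_dt
    trial_table: pd.DataFrame  # sequence index, repetition, order
    neuron_table: pd.DataFrame  # region, ptd_ms, optotagged, true_class
    pupil: np.ndarray  # (trials, time) at bin_dt
    sequences: SequenceSet
    bin_dt: float = 0.05
    fine_dt: float = 0.01

    @property
    def n_neurons(self) -> int:
        return self.counts.shape[0]

    @property
    def n_trials(self) -> int:
        return self.counts.shape[1]

    def rates(self) -> np.ndarray:
        """Single-trial spike rate (spikes/s) at the analysis bin width."""
        return self.counts / self.bin_dt


@dataclass
class GroundTruth:
    """Injected effects re-expressed in the analysis units.

    ``effect_map`` has one row per (neuron, probe, context_a, context_b)
    instance with the true amplitude (Z-score*s), duration (ms) and whether
    any effect was injected.  ``z_profiles`` holds the per-(neuron, context,
    probe) modulation profiles in Z units on the 20 Hz probe grid.
    """

    effect_map: pd.DataFrame
    z_profiles: np.ndarray  # (neurons, n_contexts, n_sounds, n_probe_bins)
    tuning: np.ndarray  # (neurons, n_sounds) evoked rate scale
    coupling: Optional[np.ndarray]
    pupil_gain: np.ndarray  # per neuron
    sigma_hat: np.ndarray  # empirical per-neuron rate std used for Z units
    n_rate_clips: int = 0


# ---------------------------------------------------------------------------


def _sound_envelope(sound_id: int, n_fine: int, fine_dt: float,
                    seed: int) -> np.ndarray:
    """Smooth positive response envelope for one sound: onset transient plus
    modulated sustained component, deterministic per (sound, seed)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7, sound_id]))
    t = np.arange(n_fine) * fine_dt
    onset = np.exp(-t / rng.uniform(0.05, 0.15))
    f = rng.uniform(2, 8)
    sustained = 0.4 + 0.25 * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    return onset + sustained


def _effect_profile(shape: str, dur_bins: int, n_bins: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Unit-scale |profile| over the probe window; nonzero exactly on the
    bins defining the effect, last nonzero bin = dur_bins - 1."""
    w = np.zeros(n_bins)
    if shape == "mixed":
        shape = rng.choice(["exponential-decay", "late-onset", "multi-peak"])
    if shape == "flat":
        w[:dur_bins] = 1.0
    elif shape == "exponential-decay":
        tt = np.arange(dur_bins)
        w[:dur_bins] = np.exp(-3.0 * tt / max(dur_bins, 1))
    elif shape == "late-onset":
        start = int(rng.integers(0, max(dur_bins // 2, 1)))
        tt = np.arange(dur_bins - start)
        w[start:dur_bins] = np.exp(-2.0 * tt / max(dur_bins - start, 1))
    elif shape == "multi-peak":
        c1 = dur_bins * 0.25
        c2 = dur_bins - 1
        width = max(dur_bins / 6.0, 0.6)
        tt = np.arange(dur_bins)
        w[:dur_bins] = (np.exp(-0.5 * ((tt - c1) / width) ** 2)
                        + 0.7 * np.exp(-0.5 * ((tt - c2) / width) ** 2))
        w[:dur_bins] = np.where(w[:dur_bins] < 0.05, 0.0, w[:dur_bins])
        w[dur_bins - 1] = max(w[dur_bins - 1], 0.1)  # keep duration exact
    else:
        raise ValueError(f"unknown effect shape {shape!r}")
    return w


def _pupil_trace(cfg: SimConfig, n_trials: int, n_bins: int,
                 order: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    p = cfg.pupil_params
    drift = p["baseline"] + p["drift_amp"] * np.sin(
        2 * np.pi * order / max(p["drift_period"], 1e-6))
    slow_noise = rng.standard_normal(n_trials) * p["noise"]
    # smooth across presentation order so the state is slow
    idx = np.argsort(order)
    sm = np.copy(slow_noise)
    sm[idx] = np.convolve(slow_noise[idx], np.ones(5) / 5, mode="same")
    level = drift + sm
    t = np.arange(n_bins) * cfg.bin_dt
    evoked = p.get("evoked", 0.0) * np.sin(2 * np.pi * t / max(t[-1], 1e-6))
    trace = level[:, None] + evoked[None, :]
    return np.clip(trace, 1e-3, None)


def simulate_pupil_condition(config: SimConfig) -> tuple[np.ndarray, pd.DataFrame]:
    """Pupil trace (trials x bins) and a per-trial state table.

    The per-trial state is the median pupil over the trial; ``degenerate``
    flags a constant trace, for which a median split is undefined.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    n_trials = config.n_sounds * config.n_reps
    n_bins = int(round((config.n_sounds + 1) / config.bin_dt))
    order = rng.permutation(n_trials)
    trace = _pupil_trace(config, n_trials, n_bins, order, rng)
    med = np.median(trace, axis=1)
    degenerate = np.ptp(med) < 1e-12
    table = pd.DataFrame({
        "trial": np.arange(n_trials),
        "order": order,
        "pupil_median": med,
        "degenerate": degenerate,
    })
    return trace, table


def simulate_population(config: SimConfig) -> tuple[PopulationRecording, GroundTruth]:
    """Generate a recording and its ground truth.

    Probe responses are baseline + per-sound tuning + injected context
    modulation (a function of the preceding sound) + optional lagged
    coupling, passed through the configured noise model.  Reproducible
    given ``config.seed``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_sounds
    I = cfg.n_neurons
    seqset = design_sequences(n, seed=cfg.seed)

    steps = int(round(cfg.bin_dt / cfg.fine_dt))
    fine_per_sound = int(round(1.0 / cfg.fine_dt))
    bins_per_sound = int(round(1.0 / cfg.bin_dt))
    n_pos = n + 1
    T_fine = n_pos * fine_per_sound
    T_bins = n_pos * bins_per_sound
    n_trials = n * cfg.n_reps

    # --- neuron metadata -------------------------------------------------
    region = np.array([cfg.region_labels[i % 2] for i in range(I)])
    is_narrow = rng.random(I) < cfg.narrow_fraction
    ptd = np.where(
        is_narrow,
        rng.normal(cfg.ptd_modes_ms[0], cfg.ptd_stds_ms[0], I),
        rng.normal(cfg.ptd_modes_ms[1], cfg.ptd_stds_ms[1], I),
    ).clip(0.05, None)
    optotagged = is_narrow & (rng.random(I) < cfg.optotag_fraction)
    neuron_table = pd.DataFrame({
        "neuron": np.arange(I),
        "region": region,
        "ptd_ms": ptd,
        "optotagged": optotagged,
        "true_class": np.where(is_narrow, "narrow", "broad"),
    })

    # --- tuning and base rates -------------------------------------------
    baseline = cfg.baseline_rate * rng.uniform(0.5, 1.5, I)
    tuning = cfg.probe_gain * rng.lognormal(mean=-0.3, sigma=0.5, size=(I, n))
    envelopes = np.stack([
        _sound_envelope(s, fine_per_sound, cfg.fine_dt, cfg.seed)
        for s in range(1, n + 1)
    ])  # (n_sounds, fine_per_sound)

    # base rate per sequence (I, n, T_fine); position 0..n are sounds
    base_rate = np.empty((I, n, T_fine))
    for si, seq in enumerate(seqset.sequences):
        for k, s in enumerate(seq):
            sl = slice(k * fine_per_sound, (k + 1) * fine_per_sound)
            base_rate[:, si, sl] = (baseline[:, None]
                                    + tuning[:, s - 1, None] * envelopes[s - 1][None, :])

    # --- predicted single-trial rate std (for Z -> rate conversion) ------
    if cfg.noise_model == "poisson":
        sigma_ref = np.sqrt(base_rate.mean(axis=(1, 2)) / cfg.bin_dt
                            + base_rate.var(axis=(1, 2)))
    elif cfg.noise_model == "gaussian":
        sigma_ref = np.sqrt(cfg.noise_sigma ** 2 + base_rate.var(axis=(1, 2)))
    else:
        sigma_ref = base_rate.std(axis=(1, 2))
    sigma_ref = np.where(sigma_ref > 0, sigma_ref, 1.0)

    # --- injected context modulations ------------------------------------
    # modulating a (context, probe) event touches every instance pairing that
    # context with another; per-event probability q gives instance-level
    # sparsity ~ 1 - (1-q)^2
    q = 1.0 - np.sqrt(max(1.0 - cfg.effect_sparsity, 0.0))
    dur_lo = max(cfg.effect_duration_range[0], cfg.bin_dt * 1e3)
    dur_hi = min(cfg.effect_duration_range[1], bins_per_sound * cfg.bin_dt * 1e3)
    # rate-domain modulation profiles, (I, n_contexts, n_probes, bins_per_sound)
    delta_rate = np.zeros((I, n + 1, n, bins_per_sound))
    for i in range(I):
        for c in range(0, n + 1):
            for p in range(1, n + 1):
                if rng.random() >= q:
                    continue
                amp = rng.uniform(*cfg.effect_amplitude_range)
                dur_ms = rng.uniform(dur_lo, dur_hi)
                if region[i] == cfg.region_labels[1]:
                    amp *= cfg.dpeg_amplitude_scale
                    dur_ms = min(dur_ms * cfg.dpeg_duration_scale, dur_hi)
                dur_bins = int(np.ceil(dur_ms / (cfg.bin_dt * 1e3)))
                dur_bins = min(max(dur_bins, 1), bins_per_sound)
                w = _effect_profile(cfg.effect_shape, dur_bins, bins_per_sound, rng)
                scale = amp / (np.abs(w).sum() * cfg.bin_dt)
                sign = 1.0 if cfg.effect_sign == "positive" else rng.choice([-1.0, 1.0])
                delta_rate[i, c, p - 1] = sign * scale * w * sigma_ref[i]

    # --- pupil -------------------------------------------------------------
    order = rng.permutation(n_trials)
    prng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3]))
    pupil = _pupil_trace(cfg, n_trials, T_bins, order, prng)
    pupil_gain = rng.uniform(*cfg.pupil_gain_range, size=I)
    pupil_z = (pupil - pupil.mean()) / (pupil.std() + 1e-12)

    # --- assemble per-trial rates ----------------------------------------
    trial_seq = np.repeat(np.arange(n), cfg.n_reps)
    trial_rep = np.tile(np.arange(cfg.n_reps), n)
    rate = base_rate[:, trial_seq, :].copy()  # (I, n_trials, T_fine)
    for si, seq in enumerate(seqset.sequences):
        tr = np.where(trial_seq == si)[0]
        prev = SILENCE_ID
        for k, s in enumerate(seq):
            sl = slice(k * fine_per_sound, (k + 1) * fine_per_sound)
            d = np.repeat(delta_rate[:, prev, s - 1], steps, axis=-1)
            rate[:, tr, sl] += d[:, None, :]
            prev = s
    # pupil gain acts multiplicatively on rate
    if np.any(pupil_gain != 0):
        gain = 1.0 + pupil_gain[:, None, None] * np.repeat(pupil_z, steps, axis=1)[None]
        rate = rate * np.clip(gain, 0.0, None)
    n_clips = int((rate < 0).sum())
    if n_clips:
        warnings.warn(f"{n_clips} rate samples clipped at 0 after modulation")
    rate = np.clip(rate, 0.0, None)

    # --- noise / coupling --------------------------------------------------
    if cfg.coupling is not None:
        fine_counts = _generate_coupled(rate, cfg, rng)
    else:
        lam = rate * cfg.fine_dt
        if cfg.noise_model == "poisson":
            fine_counts = rng.poisson(lam).astype(float)
        elif cfg.noise_model == "gaussian":
            s = cfg.noise_sigma * np.sqrt(cfg.fine_dt * cfg.bin_dt)
            fine_counts = lam + rng.normal(0.0, s, lam.shape)
        else:
            fine_counts = lam
    counts = fine_counts.reshape(I, n_trials, T_bins, steps).sum(axis=-1)

    trial_table = pd.DataFrame({
        "trial": np.arange(n_trials),
        "sequence": trial_seq,
        "repetition": trial_rep,
        "order": order,
    })
    rec = PopulationRecording(
        counts=counts, fine_counts=fine_counts, trial_table=trial_table,
        neuron_table=neuron_table, pupil=pupil, sequences=seqset,
        bin_dt=cfg.bin_dt, fine_dt=cfg.fine_dt,
    )

    # --- ground truth in the analysis' empirical Z units -------------------
    rates_flat = (counts / cfg.bin_dt).reshape(I, -1)
    sigma_hat = rates_flat.std(axis=1, ddof=0)
    sigma_safe = np.where(sigma_hat > 0, sigma_hat, 1.0)
    z_profiles = delta_rate / sigma_safe[:, None, None, None]
    rows = []
    for p in range(1, n + 1):
        pairs = [(a, b) for a in range(0, n + 1) for b in range(a + 1, n + 1)]
        for ca, cb in pairs:
            dz = z_profiles[:, ca, p - 1] - z_profiles[:, cb, p - 1]
            nz = np.abs(dz) > 0
            amp = (np.abs(dz) * nz).sum(axis=1) * cfg.bin_dt
            last = np.where(nz.any(axis=1),
                            nz.shape[1] - np.argmax(nz[:, ::-1], axis=1), 0)
            for i in range(I):
                rows.append((i, p, ca, cb, amp[i],
                             last[i] * cfg.bin_dt * 1e3, bool(nz[i].any())))
    effect_map = pd.DataFrame(
        rows, columns=["neuron", "probe", "context_a", "context_b",
                       "amplitude_zs", "duration_ms", "has_effect"])
    gt = GroundTruth(effect_map=effect_map, z_profiles=z_profiles,
                     tuning=tuning, coupling=cfg.coupling,
                     pupil_gain=pupil_gain, sigma_hat=sigma_hat,
                     n_rate_clips=n_clips)
    return rec, gt


def _generate_coupled(rate: np.ndarray, cfg: SimConfig,
                      rng: np.random.Generator) -> np.ndarray:
    """Sequential generation with lagged neuron-to-neuron influence.

    At each 100-Hz step the rate of neuron i gains sum_j W[i, j] * h_j where
    h_j is neuron j's mean spike rate over the coupling window before t.
    History is per trial (no carry-over across trials).
    """
    I, n_trials, T = rate.shape
    W = np.asarray(cfg.coupling, dtype=float)
    if W.shape != (I, I):
        raise ValueError("coupling matrix must be (n_neurons, n_neurons)")
    lo = int(round(cfg.coupling_window[0] / cfg.fine_dt))
    hi = int(round(cfg.coupling_window[1] / cfg.fine_dt))
    counts = np.zeros((I, n_trials, T))
    hist_rate = np.zeros((I, n_trials, T))  # realized rate in spikes/s
    for t in range(T):
        a, b = max(t - hi, 0), max(t - lo + 1, 0)
        if b > a:
            h = hist_rate[:, :, a:b].mean(axis=2)  # (I, n_trials)
            lam = rate[:, :, t] + np.einsum("ij,jk->ik", W, h)
        else:
            lam = rate[:, :, t]
        lam = np.clip(lam, 0.0, None) * cfg.fine_dt
        if cfg.noise_model == "poisson":
            c = rng.poisson(lam).astype(float)
        elif cfg.noise_model == "gaussian":
            s = cfg.noise_sigma * np.sqrt(cfg.fine_dt * cfg.bin_dt)
            c = lam + rng.normal(0.0, s, lam.shape)
        else:
            c = lam
        counts[:, :, t] = c
        hist_rate[:, :, t] = c / cfg.fine_dt
    return counts


# ---------------------------------------------------------------------------


@dataclass
class SegmentedResponses:
    """Probe-window responses aligned by (context, probe) event.

    ``tensor`` is (neurons, n_events, n_reps, bins_per_probe); ``events``
    lists context, probe, sequence and position for each event slot.
    """

    tensor: np.ndarray
    events: pd.DataFrame
    bin_dt: float

    def get(self, context: int, probe: int) -> np.ndarray:
        m = (self.events.context == context) & (self.events.probe == probe)
        if not m.any():
            raise KeyError(f"event (context={context}, probe={probe}) not covered")
        return self.tensor[:, self.events.index[m][0]]

    def grid(self) -> np.ndarray:
        """(neurons, n_contexts, n_probes, n_reps, bins) dense event grid."""
        n = int(self.events.probe.max())
        I, _, R, B = self.tensor.shape
        out = np.full((I, n + 1, n, R, B), np.nan)
        for e, row in self.events.iterrows():
            out[:, row.context, row.probe - 1] = self.tensor[:, e]
        return out


def segment_instances(rec: PopulationRecording,
                      data: Optional[np.ndarray] = None) -> SegmentedResponses:
    """Align probe windows by their (context, probe) event.

    ``data`` defaults to ``rec.counts``; pass a Z-scored array of the same
    shape to segment normalized responses, or a (trials, time) array for a
    single pseudo-neuron.  The probe window at sequence position k covers
    [k, k+1) s.  Every covered event contributes exactly ``n_reps`` trials.
    """
    x = rec.counts if data is None else np.asarray(data)
    if x.ndim == 2:
        x = x[None]
    bins_per_sound = int(round(1.0 / rec.bin_dt))
    seqs = rec.sequences.sequences
    events = []
    chunks = []
    for si, seq in enumerate(seqs):
        tr = rec.trial_table.trial[rec.trial_table.sequence == si].to_numpy()
        prev = SILENCE_ID
        for k, s in enumerate(seq):
            sl = slice(k * bins_per_sound, (k + 1) * bins_per_sound)
            events.append({"context": prev, "probe": s,
                           "sequence": si, "position": k})
            chunks.append(x[:, tr, sl])
            prev = s
    ev = pd.DataFrame(events)
    n = rec.sequences.n_sounds
    required = {(c, p) for c in range(n + 1) for p in range(1, n + 1)}
    covered = set(zip(ev.context, ev.probe))
    if required - covered:
        raise ValueError(f"sequence design does not cover events {required - covered}")
    tensor = np.stack(chunks, axis=1)  # (I, n_events, n_reps, bins)
    return SegmentedResponses(tensor=tensor, events=ev, bin_dt=rec.bin_dt)
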