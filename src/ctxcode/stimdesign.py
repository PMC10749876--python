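"""Balanced context-probe stimulus sequences and descriptive sound metrics.

A context-probe experiment presents sequences of 1-s natural sounds so that
the response to each *probe* sound can be compared across every possible
*context* (the immediately preceding sound, including silence at sequence
onset and the probe itself).  For ``N`` sounds, full sampling of the
``N*(N+1)`` ordered (context, probe) events is achieved with ``N`` sequences
of ``N+1`` sounds, each sequence beginning with a different sound (which
therefore receives its silence context exactly once).

Finding such sequences is an exact-cover problem over the ordered sound
pairs (the complete digraph with self-loops).  The implementation solves it
constructively with a difference family: sequences share one increment
pattern that is a permutation of the residues mod ``N``, which covers every
ordered pair exactly once while giving each sequence a distinct start; the
randomization over increment patterns and sound relabelings is seeded.

The module also synthesizes stand-in log-compressed spectrograms for the
sounds and computes the three descriptive metrics used to summarize natural
sound libraries: bandwidth (octaves spanning 70% of spectral power),
temporal stationarity, and spectral correlation.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SoundLibrary",
    "SequenceSet",
    "Spectrogram",
    "SoundMetrics",
    "SILENCE_ID",
    "enumerate_instances",
    "design_sequences",
    "validate_sequences",
    "synthesize_sound_spectrogram",
    "compute_sound_metrics",
]

SILENCE_ID = 0


class UnsatisfiableDesignError(RuntimeError):
    """No valid sequence design was found (should not occur for N >= 1)."""


@dataclass(frozen=True)
class SoundLibrary:
    """Identity and metadata of the sounds in an experiment.

    Sound ids are 1..N; id 0 is reserved for silence, which may act as a
    context but never as a probe and is never a vocalization.
    """

    n_sounds: int
    is_vocalization: dict[int, bool] = field(default_factory=dict)
    display_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.n_sounds < 1:
            raise ValueError("library needs at least one sound")
        if self.is_vocalization.get(SILENCE_ID, False):
            raise ValueError("silence cannot be flagged as a vocalization")
        for sid in self.is_vocalization:
            if sid != SILENCE_ID and not 1 <= sid <= self.n_sounds:
                raise ValueError(f"unknown sound id {sid}")

    @property
    def sound_ids(self) -> list[int]:
        return list(range(1, self.n_sounds + 1))

    def vocal(self, sound_id: int) -> bool:
        if sound_id == SILENCE_ID:
            return False
        if not 1 <= sound_id <= self.n_sounds:
            raise KeyError(f"unknown sound id {sound_id}")
        return bool(self.is_vocalization.get(sound_id, False))


@dataclass(frozen=True)
class SequenceSet:
    """``n_sounds`` ordered sequences of ``n_sounds + 1`` sound ids."""

    n_sounds: int
    sequences: tuple[tuple[int, ...], ...]
    seed: int = 0

    def events(self) -> list[tuple[int, int]]:
        """Ordered (context, probe) events, silence context for initial sounds."""
        out = []
        for seq in self.sequences:
            prev = SILENCE_ID
            for sound in seq:
                out.append((prev, sound))
                prev = sound
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_sounds": self.n_sounds,
                "seed": self.seed,
                "sequences": [list(s) for s in self.sequences],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "SequenceSet":
        d = json.loads(text)
        return cls(
            n_sounds=int(d["n_sounds"]),
            sequences=tuple(tuple(int(x) for x in s) for s in d["sequences"]),
            seed=int(d.get("seed", 0)),
        )


def enumerate_instances(n_sounds: int) -> list[tuple[int, tuple[int, int]]]:
    """All contextual instances: (probe, unordered pair of distinct contexts).

    Contexts range over silence plus the ``n_sounds`` sounds, probes over the
    sounds only, giving ``n_sounds * C(n_sounds + 1, 2)`` instances (40 for
    4 sounds, 550 for 10).
    """
    if n_sounds < 1:
        raise ValueError("n_sounds must be >= 1")
    contexts = range(SILENCE_ID, n_sounds + 1)
    instances = []
    for probe in range(1, n_sounds + 1):
        for ca, cb in itertools.combinations(contexts, 2):
            instances.append((probe, (ca, cb)))
    return instances


def design_sequences(library: SoundLibrary | int, seed: int = 0) -> SequenceSet:
    """Design ``N`` sequences of ``N+1`` sounds covering every
    (context, probe) event exactly once.

    The ordered sound pairs (self-pairs included) form the complete digraph
    with self-loops, every vertex of in- and out-degree ``N``; the design
    is a decomposition of its edges into ``N`` paths of ``N`` edges with
    distinct start vertices.  A difference-family construction solves this
    directly: with vertices as residues mod N, sequence ``i`` starts at
    ``i`` and all sequences share one increment sequence that is a
    permutation of the residues, so the ordered pair (a, b) is covered
    exactly once — at the unique step whose increment is ``b - a`` mod N,
    in the sequence whose walk passes ``a`` at that step.  The increment
    permutation and a vertex relabeling are drawn from ``seed``; the result
    is re-validated before return.
    """
    n = library.n_sounds if isinstance(library, SoundLibrary) else int(library)
    if n < 1:
        raise ValueError("need at least one sound")
    rng = np.random.default_rng(seed)
    increments = rng.permutation(n)  # one step per difference class
    relabel = rng.permutation(n)  # residue -> sound id - 1
    seqs = []
    for i in range(n):
        walk = [i]
        for d in increments:
            walk.append((walk[-1] + int(d)) % n)
        seqs.append(tuple(int(relabel[v]) + 1 for v in walk))
    out = SequenceSet(n_sounds=n, sequences=tuple(seqs), seed=seed)
    report = validate_sequences(out)
    if not report["valid"]:  # pragma: no cover - construction is exact
        raise UnsatisfiableDesignError(f"no valid design found for N={n}")
    return out


def validate_sequences(seqset: SequenceSet) -> dict:
    """Check the exact-coverage contract; returns a report dict.

    The report lists structural violations (wrong counts/lengths, invalid
    ids, repeated initial sounds) and missing/duplicated (context, probe)
    events; ``report['valid']`` is True iff all lists are empty.
    """
    n = seqset.n_sounds
    structural: list[str] = []
    if len(seqset.sequences) != n:
        structural.append(f"expected {n} sequences, found {len(seqset.sequences)}")
    for i, seq in enumerate(seqset.sequences):
        if len(seq) != n + 1:
            structural.append(f"sequence {i} has length {len(seq)}, expected {n + 1}")
        bad = [s for s in seq if not 1 <= s <= n]
        if bad:
            structural.append(f"sequence {i} contains invalid ids {bad}")
    firsts = [seq[0] for seq in seqset.sequences if len(seq) > 0]
    if sorted(firsts) != list(range(1, n + 1)) and not structural:
        structural.append(f"initial sounds {sorted(firsts)} are not exactly 1..{n}")

    required = {
        (c, p) for c in range(0, n + 1) for p in range(1, n + 1)
    }
    seen: dict[tuple[int, int], int] = {}
    for ev in seqset.events():
        seen[ev] = seen.get(ev, 0) + 1
    missing = sorted(required - set(seen))
    duplicated = sorted(ev for ev, k in seen.items() if k > 1)
    extra = sorted(set(seen) - required)
    valid = not (structural or missing or duplicated or extra)
    return {
        "valid": valid,
        "structural": structural,
        "missing": missing,
        "duplicated": duplicated,
        "extra": extra,
        "n_events": len(seqset.events()),
    }


# ---------------------------------------------------------------------------
# spectrograms and sound metrics


@dataclass
class Spectrogram:
    """Log-compressed power, channels x time, with log-spaced center freqs."""

    values: np.ndarray
    channel_freqs: np.ndarray
    dt: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.channel_freqs = np.asarray(self.channel_freqs, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be channels x time")
        if self.values.shape[0] != self.channel_freqs.size:
            raise ValueError("channel_freqs length must match channel count")
        if self.values.shape[0] < 2:
            raise ValueError("need at least 2 channels")
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_times(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class SoundMetrics:
    bandwidth: float  # octaves
    temporal_stationarity: float  # std units
    spectral_correlation: float  # mean pairwise Pearson r


def default_channel_freqs(n_channels: int = 18, f_lo: float = 200.0,
                          f_hi: float = 20000.0) -> np.ndarray:
    return np.geomspace(f_lo, f_hi, n_channels)


def synthesize_sound_spectrogram(
    sound_id: int,
    duration: float = 1.0,
    dt: float = 0.01,
    n_channels: int = 18,
    family: str = "naturalistic",
    seed: int = 0,
    floor: float = 0.0,
) -> Spectrogram:
    """Synthetic stand-in spectrogram for a sound id.

    Families: ``narrowband`` (single active channel), ``bandnoise``
    (static band of channels with temporal noise), ``naturalistic``
    (smooth random spectral envelope with amplitude modulation).  Silence
    (id 0) yields a constant floor.  Per-sound signatures are deterministic
    in ``(sound_id, seed)``.
    """
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be positive")
    n_t = int(round(duration / dt))
    freqs = default_channel_freqs(n_channels)
    if sound_id == SILENCE_ID:
        return Spectrogram(np.full((n_channels, n_t), floor), freqs, dt)
    rng = np.random.default_rng(np.random.SeedSequence([seed, sound_id]))
    vals = np.full((n_channels, n_t), floor, dtype=float)
    if family == "narrowband":
        ch = int(rng.integers(0, n_channels))
        vals[ch] = floor + 1.0 + 0.2 * np.sin(
            2 * np.pi * rng.uniform(1, 5) * np.arange(n_t) * dt
        )
    elif family == "bandnoise":
        lo = int(rng.integers(0, n_channels - 1))
        hi = int(rng.integers(lo + 1, n_channels))
        band = slice(lo, hi + 1)
        vals[band] = floor + 1.0 + 0.3 * rng.standard_normal((hi + 1 - lo, n_t))
    elif family == "naturalistic":
        # smooth spectral envelope x slow amplitude modulation + roughness
        center = rng.uniform(0, n_channels - 1)
        width = rng.uniform(1.5, n_channels / 2)
        env = np.exp(-0.5 * ((np.arange(n_channels) - center) / width) ** 2)
        t = np.arange(n_t) * dt
        am = 1.0 + 0.6 * np.sin(2 * np.pi * rng.uniform(2, 8) * t + rng.uniform(0, 2 * np.pi))
        rough = 0.25 * rng.standard_normal((n_channels, n_t))
        vals = floor + np.outer(env, am) + rough * env[:, None]
    else:
        raise ValueError(f"unknown spectral family {family!r}")
    return Spectrogram(vals, freqs, dt)


def _band_percentile_octaves(power: np.ndarray, log2f: np.ndarray,
                             q: float) -> float:
    """Octave position of the q-th percentile of the cumulative power
    distribution, treating each channel as a uniform bin in log2 frequency
    (edges midway between centers, end bins extended symmetrically)."""
    k = power.size
    # bin edges in octave units
    mids = log2f
    edges = np.empty(k + 1)
    edges[1:-1] = 0.5 * (mids[:-1] + mids[1:])
    edges[0] = mids[0] - (edges[1] - mids[0])
    edges[-1] = mids[-1] + (mids[-1] - edges[-2])
    cum = np.concatenate([[0.0], np.cumsum(power)]) / power.sum()
    return float(np.interp(q, cum, edges))


def compute_sound_metrics(spec: Spectrogram) -> SoundMetrics:
    """Bandwidth, temporal stationarity, spectral correlation of a spectrogram.

    Bandwidth is the octave span between the 15th and 85th percentiles of
    total spectral power (the 70% band).  Stationarity is the temporal std
    of each in-band channel averaged over channels; spectral correlation is
    the mean pairwise Pearson r over time among in-band channels.  Channels
    whose centers fall outside the 70% band are excluded from the latter two.
    """
    if spec.n_times < 2:
        raise ValueError("need at least 2 time bins")
    vals = spec.values
    if vals.min() < 0:  # log-compressed values may sit below zero
        vals = vals - vals.min()
    power = vals.sum(axis=1)
    if power.sum() <= 0:
        raise ValueError("zero total power: metrics undefined")
    log2f = np.log2(spec.channel_freqs)
    lo = _band_percentile_octaves(power, log2f, 0.15)
    hi = _band_percentile_octaves(power, log2f, 0.85)
    bandwidth = hi - lo

    in_band = (log2f >= lo) & (log2f <= hi)
    if not in_band.any():
        in_band[np.argmax(power)] = True
    band_vals = spec.values[in_band]
    stationarity = float(band_vals.std(axis=1, ddof=0).mean())

    if band_vals.shape[0] < 2:
        corr = 1.0
    else:
        sd = band_vals.std(axis=1)
        keep = sd > 0
        if keep.sum() < 2:
            corr = 1.0
        else:
            c = np.corrcoef(band_vals[keep])
            iu = np.triu_indices_from(c, k=1)
            corr = float(c[iu].mean())
    return SoundMetrics(bandwidth=float(bandwidth),
                        temporal_stationarity=stationarity,
                        spectral_correlation=corr)
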