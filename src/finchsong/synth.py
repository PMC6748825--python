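"""Synthetic tutor stimuli and simulated tutee corpora.

The canonical tutor stimulus mimics the structure of Bengalese finch song:
two short introductory syllables followed by three repetitions of a
stereotyped seven-syllable motif, for 9 categorically distinct syllable
types in total (short noisy intro notes, harmonic stacks at distinct
fundamentals, band-limited noise syllables, and FM sweeps). Inter-syllable
gaps have naturalistic means and standard deviations; the canonical gap
pattern is scaled so the nominal tempo is 8.5 syl/s. Variants at other
tempos are produced by *gap-only retiming*: every gap mean and SD is scaled
by one common factor while syllable waveforms are left untouched, so
spectral content is identical across tempo conditions.

Simulated tutees sing the tutor song at a tempo pulled toward their
heritable bias (the father's tempo) and with spectral corruption (frequency
jitter, syllable-type substitution, syllable dropout). The effective
corruption grows with the mismatch between tutor tempo and the bird's
tempo bias when ``mismatch_coupling`` > 0, giving the corpus generator a
recoverable gene-by-experience interaction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .audio import Waveform

__all__ = [
    "SyllableSpec",
    "SongSpec",
    "TuteeSpec",
    "RenderedBout",
    "SongCorpus",
    "CANONICAL_PALETTE",
    "canonical_song_spec",
    "render_syllable",
    "render_song",
    "retime",
    "generate_tutee_corpus",
    "generate_reference_corpus",
]

DEFAULT_RATE = 32000.0

#: Silence padding at each end of a rendered bout; exceeds the 250 ms bout gap.
EDGE_PAD_S = 0.300

#: Gaps are truncated below at 2 ms when jittered.
MIN_GAP_S = 0.002


@dataclass(frozen=True)
class SyllableSpec:
    """One syllable type.

    kind
        'intro'  — short band-limited noise burst with a fast decay.
        'harmonic' — harmonic stack; ``f_lo`` is the fundamental, ``f_hi``
        caps the highest harmonic.
        'noise' — stationary noise band between ``f_lo`` and ``f_hi``.
        'sweep' — linear FM sweep from ``f_lo`` to ``f_hi`` (either direction).
    """

    type_id: int
    kind: str
    duration: float
    f_lo: float
    f_hi: float

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.kind not in ("intro", "harmonic", "noise", "sweep"):
            raise ValueError(f"unknown syllable kind {self.kind!r}")

    @property
    def max_frequency(self) -> float:
        return max(self.f_lo, self.f_hi)


#: Canonical nine-type palette: 2 intro, 3 harmonic, 2 noise-band, 2 FM sweep.
CANONICAL_PALETTE: tuple[SyllableSpec, ...] = (
    SyllableSpec(1, "intro", 0.025, 1500.0, 3500.0),
    SyllableSpec(2, "intro", 0.025, 3000.0, 5500.0),
    SyllableSpec(3, "harmonic", 0.090, 700.0, 7000.0),
    SyllableSpec(4, "harmonic", 0.070, 1100.0, 8800.0),
    SyllableSpec(5, "harmonic", 0.100, 1600.0, 11200.0),
    SyllableSpec(6, "noise", 0.060, 2000.0, 4000.0),
    SyllableSpec(7, "noise", 0.070, 5000.0, 8000.0),
    SyllableSpec(8, "sweep", 0.080, 2000.0, 6000.0),
    SyllableSpec(9, "sweep", 0.090, 7000.0, 3000.0),
)

# Relative gap-duration pattern: shorter after intro notes, slightly longer
# between motif repetitions; scaled as a whole to hit the nominal tempo.
_MOTIF_INTERNAL_WEIGHTS = (1.0, 0.9, 1.1, 0.95, 1.05, 1.0)
_INTRO_WEIGHTS = (0.6, 0.8)
_BETWEEN_MOTIF_WEIGHT = 1.3


@dataclass(frozen=True)
class SongSpec:
    """A bout blueprint: intro syllables, a motif repeated ``n_motifs`` times,
    and per-gap mean/SD durations in seconds."""

    intro: tuple[SyllableSpec, ...]
    motif: tuple[SyllableSpec, ...]
    n_motifs: int
    gap_means: tuple[float, ...]
    gap_sds: tuple[float, ...]

    def __post_init__(self):
        if self.n_motifs < 1:
            raise ValueError("need at least one motif repetition")
        n_gaps = len(self.syllables) - 1
        if len(self.gap_means) != n_gaps or len(self.gap_sds) != n_gaps:
            raise ValueError(f"expected {n_gaps} gap means/SDs")
        if any(g <= 0 for g in self.gap_means):
            raise ValueError("gap means must be positive")

    @property
    def syllables(self) -> tuple[SyllableSpec, ...]:
        return self.intro + self.motif * self.n_motifs

    @property
    def n_syllables(self) -> int:
        return len(self.intro) + self.n_motifs * len(self.motif)

    @property
    def total_syllable_time(self) -> float:
        return sum(s.duration for s in self.syllables)

    @property
    def nominal_tempo(self) -> float:
        """Syllable count over nominal bout duration (all gaps at their means)."""
        return self.n_syllables / (self.total_syllable_time + sum(self.gap_means))


@dataclass(frozen=True)
class TuteeSpec:
    """Generator settings for a simulated learner.

    ``corruption`` is the baseline spectral-copy infidelity in [0, 1];
    ``tempo_bias`` is the heritable (father) tempo in syl/s; ``tempo_pull``
    is how strongly the sung tempo is drawn toward the bias (0 = sings at
    tutor tempo, 1 = sings at the father's tempo); ``mismatch_coupling``
    converts |tutor tempo − bias| (syl/s) into extra corruption.
    ``fast_mismatch_weight`` multiplies the coupling when the tutor is
    faster than the bias (values > 1 make fast-tutor mismatch more harmful
    than slow-tutor mismatch of the same size). ``improvised`` syllable
    types, if any, are appended to every bout in addition to the full tutor
    content.
    """

    tutor: SongSpec
    corruption: float = 0.0
    tempo_bias: float | None = None
    tempo_pull: float = 0.75
    mismatch_coupling: float = 0.0
    fast_mismatch_weight: float = 1.0
    improvised: tuple[SyllableSpec, ...] = ()
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.corruption <= 1.0:
            raise ValueError("corruption must lie in [0, 1]")
        if self.mismatch_coupling < 0:
            raise ValueError("mismatch_coupling must be non-negative")

    @property
    def effective_corruption(self) -> float:
        bias = self.tempo_bias
        if bias is None:
            return min(1.0, self.corruption)
        tutor_tempo = self.tutor.nominal_tempo
        mismatch = abs(tutor_tempo - bias)
        weight = self.fast_mismatch_weight if tutor_tempo > bias else 1.0
        return min(1.0, self.corruption + weight * self.mismatch_coupling * mismatch)


@dataclass(frozen=True)
class RenderedBout:
    """A rendered bout waveform plus its ground-truth syllable layout."""

    waveform: Waveform
    onsets: tuple[float, ...]
    offsets: tuple[float, ...]
    type_ids: tuple[int, ...]


@dataclass(frozen=True)
class SongCorpus:
    """A bird's corpus of rendered song bouts (nominally >= 60 for scoring)."""

    bouts: tuple[RenderedBout, ...]
    bird_id: str = ""

    def __post_init__(self):
        if not self.bouts:
            raise ValueError("corpus must contain at least one bout")

    @property
    def rate(self) -> float:
        return self.bouts[0].waveform.rate

    @property
    def n_bouts(self) -> int:
        return len(self.bouts)

    @property
    def waveforms(self) -> tuple[Waveform, ...]:
        return tuple(b.waveform for b in self.bouts)


def canonical_song_spec(
    tempo: float = 8.5, gap_rel_sd: float = 0.15, n_motifs: int = 3
) -> SongSpec:
    """The canonical tutor blueprint at a given nominal tempo.

    Gap means follow the fixed relative pattern and are scaled so that the
    nominal tempo (all gaps at their means) equals ``tempo`` exactly; each
    gap SD is ``gap_rel_sd`` times its mean.
    """
    intro = CANONICAL_PALETTE[:2]
    motif = CANONICAL_PALETTE[2:]
    weights = list(_INTRO_WEIGHTS)
    for rep in range(n_motifs):
        weights.extend(_MOTIF_INTERNAL_WEIGHTS)
        if rep < n_motifs - 1:
            weights.append(_BETWEEN_MOTIF_WEIGHT)
    weights_arr = np.asarray(weights)
    n_syll = len(intro) + n_motifs * len(motif)
    syllable_time = sum(s.duration for s in intro) + n_motifs * sum(
        s.duration for s in motif
    )
    total_gap = n_syll / tempo - syllable_time
    if total_gap <= 0:
        raise ValueError(f"tempo {tempo} syl/s infeasible: no time left for gaps")
    gap_means = tuple(total_gap * weights_arr / weights_arr.sum())
    gap_sds = tuple(gap_rel_sd * g for g in gap_means)
    return SongSpec(intro, motif, n_motifs, gap_means, gap_sds)


def _taper(n: int, rate: float, ramp_s: float = 0.005) -> np.ndarray:
    alpha = min(1.0, 2 * ramp_s * rate / max(n, 1))
    return signal.windows.tukey(n, alpha)


def render_syllable(spec: SyllableSpec, rate: float, seed: int) -> np.ndarray:
    """Render one syllable; deterministic for a given (spec, rate, seed).

    Raises ValueError if the spec's top frequency reaches Nyquist (aliasing).
    """
    if spec.max_frequency >= rate / 2:
        raise ValueError(
            f"aliasing: {spec.max_frequency} Hz >= Nyquist ({rate / 2} Hz)"
        )
    rng = np.random.default_rng(seed)
    n = int(round(spec.duration * rate))
    t = np.arange(n) / rate
    if spec.kind == "harmonic":
        f0 = spec.f_lo
        n_harm = int(spec.f_hi // f0)
        y = np.zeros(n)
        for h in range(1, n_harm + 1):
            phase = rng.uniform(0, 2 * np.pi)
            y += (1.0 / h) * np.sin(2 * np.pi * h * f0 * t + phase)
    elif spec.kind == "sweep":
        y = signal.chirp(t, f0=spec.f_lo, t1=spec.duration, f1=spec.f_hi, method="linear")
        # weak second harmonic for timbre, kept below Nyquist
        if 2 * spec.max_frequency < rate / 2:
            y += 0.3 * signal.chirp(
                t, f0=2 * spec.f_lo, t1=spec.duration, f1=2 * spec.f_hi, method="linear"
            )
    else:  # 'noise' and 'intro': band-limited noise
        lo, hi = sorted((spec.f_lo, spec.f_hi))
        sos = signal.butter(4, [lo, hi], btype="bandpass", fs=rate, output="sos")
        y = signal.sosfiltfilt(sos, rng.standard_normal(n))
        if spec.kind == "intro":
            y *= np.exp(-t / (0.4 * spec.duration))
    y *= _taper(n, rate)
    peak = np.max(np.abs(y))
    return 0.7 * y / peak if peak > 0 else y


def render_song(
    spec: SongSpec,
    rate: float = DEFAULT_RATE,
    seed: int = 0,
    noise_floor: float = 1e-4,
) -> RenderedBout:
    """Render one bout: syllables separated by gaps drawn from the spec's
    per-gap means and SDs (truncated at 2 ms), padded with 300 ms of
    near-silence at both ends, over a low background-noise floor."""
    rng = np.random.default_rng(seed)
    sylls = spec.syllables
    gaps = np.maximum(
        rng.normal(np.asarray(spec.gap_means), np.asarray(spec.gap_sds)), MIN_GAP_S
    )
    pieces: list[np.ndarray] = []
    onsets, offsets, type_ids = [], [], []
    cursor = EDGE_PAD_S
    pieces.append(np.zeros(int(round(EDGE_PAD_S * rate))))
    for i, s in enumerate(sylls):
        y = render_syllable(s, rate, int(rng.integers(0, 2 ** 31)))
        onsets.append(cursor)
        offsets.append(cursor + y.size / rate)
        type_ids.append(s.type_id)
        pieces.append(y)
        cursor += y.size / rate
        if i < len(sylls) - 1:
            gap_n = int(round(gaps[i] * rate))
            pieces.append(np.zeros(gap_n))
            cursor += gap_n / rate
    pieces.append(np.zeros(int(round(EDGE_PAD_S * rate))))
    samples = np.concatenate(pieces)
    if noise_floor > 0:
        samples = samples + noise_floor * rng.standard_normal(samples.size)
    return RenderedBout(
        Waveform(samples, rate), tuple(onsets), tuple(offsets), tuple(type_ids)
    )


def retime(spec: SongSpec, target: float) -> SongSpec:
    """Gap-only retiming to a target nominal tempo (syl/s).

    Every gap mean and SD is scaled by the single factor
    g = (N/target − Σ syllable durations) / Σ original gap means, leaving
    syllable specs (and hence durations and spectral content) untouched.
    Raises ValueError when the target would require non-positive gaps.
    """
    if target <= 0:
        raise ValueError("target tempo must be positive")
    gap_budget = spec.n_syllables / target - spec.total_syllable_time
    if gap_budget <= 0:
        raise ValueError(
            f"target {target} syl/s infeasible: syllable time alone exceeds the bout"
        )
    g = gap_budget / sum(spec.gap_means)
    return replace(
        spec,
        gap_means=tuple(g * m for m in spec.gap_means),
        gap_sds=tuple(g * s for s in spec.gap_sds),
    )


#: Always-on rendition-to-rendition frequency scatter (log-scale SD); real
#: song varies slightly between renditions even in a stereotyped adult.
RENDITION_JITTER_SD = 0.02

#: Per-unit-corruption magnitudes of the three copy errors.
MISCOPY_JITTER_SD = 0.25  # systematic per-type frequency displacement
SUBSTITUTION_RATE = 0.3  # per-type chance of consistently singing another type
DROPOUT_RATE = 0.2  # per-rendition chance of omitting a syllable


def _scale_freqs(s: SyllableSpec, scale: float, rate: float) -> SyllableSpec:
    scale = min(scale, 0.45 * rate / s.max_frequency)
    if scale == 1.0:
        return s
    return replace(s, f_lo=s.f_lo * scale, f_hi=s.f_hi * scale)


def _miscopy_map(
    palette: tuple[SyllableSpec, ...],
    c: float,
    rng: np.random.Generator,
    rate: float,
) -> dict[int, SyllableSpec]:
    """A bird's systematic copy errors: each syllable type is either
    consistently substituted by another type or consistently displaced in
    frequency, with magnitudes scaled by the corruption level c."""
    mapping: dict[int, SyllableSpec] = {}
    for s in palette:
        if rng.random() < SUBSTITUTION_RATE * c:
            others = [p for p in palette if p.type_id != s.type_id]
            target = others[rng.integers(len(others))]
            mapping[s.type_id] = replace(target, type_id=s.type_id)
        else:
            factor = float(np.exp(rng.normal(0.0, MISCOPY_JITTER_SD * c)))
            mapping[s.type_id] = _scale_freqs(s, factor, rate)
    return mapping


def generate_tutee_corpus(
    t: TuteeSpec,
    n_bouts: int,
    rate: float = DEFAULT_RATE,
    bird_id: str = "",
) -> SongCorpus:
    """Simulate a tutee's song corpus.

    The sung tempo is tutor tempo pulled toward ``tempo_bias`` by
    ``tempo_pull``; each bout's syllables are corrupted independently at the
    effective corruption level (baseline + mismatch-coupled). Deterministic
    for a given TuteeSpec (including its seed).
    """
    if n_bouts < 1:
        raise ValueError("n_bouts must be at least 1")
    rng = np.random.default_rng(t.seed)
    tutor_tempo = t.tutor.nominal_tempo
    if t.tempo_bias is None:
        sung_tempo = tutor_tempo
    else:
        sung_tempo = tutor_tempo + t.tempo_pull * (t.tempo_bias - tutor_tempo)
    base = retime(t.tutor, sung_tempo) if sung_tempo != tutor_tempo else t.tutor
    c = t.effective_corruption
    palette = tuple(dict.fromkeys(base.syllables))  # distinct types, order kept
    miscopy = _miscopy_map(palette, c, rng, rate)
    bouts = []
    for _ in range(n_bouts):
        sylls: list[SyllableSpec] = []
        for s in base.syllables:
            if rng.random() < DROPOUT_RATE * c:
                continue
            copied = miscopy[s.type_id]
            rendition = float(np.exp(rng.normal(0.0, RENDITION_JITTER_SD)))
            sylls.append(_scale_freqs(copied, rendition, rate))
        if not sylls:  # total dropout: keep at least one syllable
            sylls = [miscopy[base.syllables[0].type_id]]
        sylls.extend(t.improvised)
        n_gaps = max(len(sylls) - 1, 0)
        # reuse the base gap statistics, cycled to the realized syllable count
        means = (list(base.gap_means) * 2)[:n_gaps]
        sds = (list(base.gap_sds) * 2)[:n_gaps]
        bout_spec = SongSpec((), tuple(sylls), 1, tuple(means), tuple(sds))
        bouts.append(render_song(bout_spec, rate, int(rng.integers(0, 2 ** 31))))
    return SongCorpus(tuple(bouts), bird_id=bird_id)


def generate_reference_corpus(
    tutor: SongSpec,
    n_bouts: int,
    seed: int = 0,
    rate: float = DEFAULT_RATE,
    bird_id: str = "reference",
) -> SongCorpus:
    """Corpus of a bird that learned the tutor song perfectly (corruption 0).

    Used as the scoring reference for computer-tutored cohorts: tutees are
    compared against this well-learned corpus rather than the one-exemplar
    stimulus itself.
    """
    spec = TuteeSpec(tutor=tutor, corruption=0.0, mismatch_coupling=0.0, seed=seed)
    return generate_tutee_corpus(spec, n_bouts, rate=rate, bird_id=bird_id)
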