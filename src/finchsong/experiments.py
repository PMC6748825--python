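"""Experiment orchestration: the background x tutor-tempo tutoring grid.

Simulates the full 3x3 design: cohorts from slow / medium / fast genetic
backgrounds (father tempos 7.18, 7.89, 10.31 syl/s) are computer-tutored
with the canonical song retimed to slow / medium / fast tempos (6.5, 8.5,
10.5 syl/s). Every simulated bird is scored with the Song Divergence
against a single designated reference corpus (a simulated bird that learned
the 8.5 syl/s stimulus perfectly), mirroring the scoring convention for
one-exemplar computer tutors. The resulting records feed
:func:`finchsong.stats.grid_analysis` and
:func:`finchsong.stats.tradeoff_tests`.
"""

from __future__ import annotations

from dataclasses import replace

from .divergence import DivergenceConfig, song_divergence
from .segmentation import group_bouts, segment_syllables
from .audio import amplitude_envelope, highpass
from .stats import NestRecord
from .synth import (
    SongSpec,
    TuteeSpec,
    canonical_song_spec,
    generate_reference_corpus,
    generate_tutee_corpus,
    retime,
)
from .tempo import song_tempo

__all__ = [
    "BACKGROUND_TEMPOS",
    "TUTOR_TEMPOS",
    "measure_corpus_tempo",
    "run_grid_experiment",
]

#: Father-song tempos of the three genetic backgrounds (syl/s): lower decile,
#: median, and upper decile of colony song tempos.
BACKGROUND_TEMPOS = {"slow": 7.18, "medium": 7.89, "fast": 10.31}

#: Tutor-stimulus tempos (syl/s); the 8.5 syl/s medium stimulus is canonical,
#: the others are gap-only retimed variants.
TUTOR_TEMPOS = {"slow": 6.5, "medium": 8.5, "fast": 10.5}


def measure_corpus_tempo(corpus, config: DivergenceConfig | None = None) -> float:
    """Mean syl/s of a corpus, measured through the segmentation pipeline."""
    cfg = config or DivergenceConfig()
    bouts = []
    for bout in corpus.bouts:
        env = amplitude_envelope(highpass(bout.waveform))
        bouts.extend(group_bouts(segment_syllables(env, cfg.segmentation),
                                 cfg.segmentation))
    return song_tempo(bouts).tempo


def run_grid_experiment(
    n_per_cell: int = 3,
    n_bouts: int = 30,
    corruption: float = 0.05,
    mismatch_coupling: float = 0.08,
    fast_mismatch_weight: float = 2.0,
    seed: int = 0,
    config: DivergenceConfig | None = None,
    measure_tempo: bool = True,
) -> list[NestRecord]:
    """Simulate and score the full 3x3 tutoring experiment.

    Returns one NestRecord per simulated bird, carrying its father tempo
    (genetic background), tutor tempo, SD score against the shared
    reference, and (optionally) its measured song tempo. ``seed`` controls
    every source of randomness; bird seeds are derived from it.

    Defaults give a generator with a positive gene-by-experience coupling
    (mismatch degrades spectral copying) and a fast-tutor asymmetry
    (tutoring above the bias is more harmful than below), the regime the
    grid analysis is designed to detect.
    """
    cfg = config or DivergenceConfig()
    canonical = canonical_song_spec()
    tutor_specs: dict[str, SongSpec] = {
        name: canonical if tempo == canonical.nominal_tempo else retime(canonical, tempo)
        for name, tempo in TUTOR_TEMPOS.items()
    }
    reference = generate_reference_corpus(canonical, n_bouts, seed=seed * 9973 + 7)
    records: list[NestRecord] = []
    bird_index = 0
    for bg_name, bg_tempo in BACKGROUND_TEMPOS.items():
        for tutor_name, tutor_tempo in TUTOR_TEMPOS.items():
            for i in range(n_per_cell):
                bird_seed = (seed * 131071 + bird_index * 8191 + 17) % (2 ** 31)
                bird_index += 1
                spec = TuteeSpec(
                    tutor=tutor_specs[tutor_name],
                    corruption=corruption,
                    tempo_bias=bg_tempo,
                    mismatch_coupling=mismatch_coupling,
                    fast_mismatch_weight=fast_mismatch_weight,
                    seed=bird_seed,
                )
                bird_id = f"{bg_name}_{tutor_name}_{i}"
                corpus = generate_tutee_corpus(spec, n_bouts, bird_id=bird_id)
                sd = song_divergence(reference, corpus,
                                     replace(cfg, seed=bird_seed))
                tutee_tempo = (
                    measure_corpus_tempo(corpus, cfg) if measure_tempo else None
                )
                records.append(
                    NestRecord(
                        bird_id=bird_id,
                        nest_id=bg_name,
                        father_tempo=bg_tempo,
                        condition="computer",
                        sd_bits=sd.bits,
                        tutor_tempo=tutor_tempo,
                        tutee_tempo=tutee_tempo,
                    )
                )
    return records
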