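"""Song tempo (syllables per second) and heritable-bias tempo bins.

Tempo for one bout is the syllable count divided by the bout duration
(first onset to last offset). A bird's song tempo is the mean over bouts,
nominally at least 60 of them; fewer are allowed but flagged. Father-song
tempos are binned into slow (<7.5 syl/s), medium (7.5-9.5 syl/s, edges
inclusive) and fast (>9.5 syl/s) relative to a canonical 8.5 syl/s tutor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .segmentation import Bout

__all__ = ["TempoEstimate", "BIAS_EDGES", "bout_tempo", "song_tempo", "classify_bias"]

#: Bias-bin edges in syl/s; both edges belong to "medium".
BIAS_EDGES = (7.5, 9.5)

MIN_BOUTS = 60


@dataclass(frozen=True)
class TempoEstimate:
    """Mean song tempo with per-bout values; ``reliable`` is False below 60 bouts."""

    tempo: float
    n_bouts: int
    per_bout: tuple[float, ...]

    @property
    def reliable(self) -> bool:
        return self.n_bouts >= MIN_BOUTS


def bout_tempo(bout: Bout) -> float:
    """Syllables per second for one bout: count / (last offset - first onset)."""
    duration = bout.duration
    if duration <= 0:
        raise ValueError("bout has zero duration")
    return bout.n_syllables / duration


def song_tempo(bouts: Sequence[Bout]) -> TempoEstimate:
    """Mean of per-bout tempos across a corpus of bouts."""
    if not bouts:
        raise ValueError("song_tempo requires at least one bout")
    per_bout = tuple(bout_tempo(b) for b in bouts)
    return TempoEstimate(float(np.mean(per_bout)), len(per_bout), per_bout)


def classify_bias(father_tempo: float) -> str:
    """Bin a father's song tempo: 'slow' (<7.5), 'medium' (7.5-9.5), 'fast' (>9.5)."""
    if father_tempo <= 0:
        raise ValueError("tempo must be positive")
    lo, hi = BIAS_EDGES
    if father_tempo < lo:
        return "slow"
    if father_tempo > hi:
        return "fast"
    return "medium"
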