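"""Syllable segmentation and bout grouping from amplitude envelopes.

Syllables are uninterrupted supra-threshold regions of the amplitude
envelope. Candidate regions separated by gaps of at most 5 ms are merged
first; regions are then kept only if strictly longer than 10 ms. A run of
syllables with no inter-syllable gap larger than 250 ms forms a song bout.

Boundary conventions: merge iff gap <= merge_gap_s; keep iff duration
> min_syllable_s (strict); same bout iff gap <= bout_gap_s. Intervals are
half-open [onset, offset) in seconds; sample i maps to time i / rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .audio import Envelope

__all__ = [
    "SyllableInterval",
    "Bout",
    "SegmentationParams",
    "auto_threshold",
    "segment_syllables",
    "group_bouts",
    "write_intervals_tsv",
    "read_intervals_tsv",
]


@dataclass(frozen=True)
class SyllableInterval:
    onset: float
    offset: float

    def __post_init__(self):
        if not self.offset > self.onset:
            raise ValueError("offset must exceed onset")

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass(frozen=True)
class Bout:
    """An ordered, non-overlapping run of syllables with small internal gaps."""

    syllables: tuple[SyllableInterval, ...]

    def __post_init__(self):
        sylls = tuple(self.syllables)
        object.__setattr__(self, "syllables", sylls)
        if not sylls:
            raise ValueError("bout must contain at least one syllable")
        for a, b in zip(sylls, sylls[1:]):
            if b.onset < a.offset:
                raise ValueError("syllables must be sorted and non-overlapping")

    @property
    def n_syllables(self) -> int:
        return len(self.syllables)

    @property
    def duration(self) -> float:
        """First onset to last offset; terminal silence excluded."""
        return self.syllables[-1].offset - self.syllables[0].onset


@dataclass(frozen=True)
class SegmentationParams:
    """Threshold/merge/duration rules for segmentation.

    threshold: explicit envelope-units scalar, or "auto" for a percentile rule.
    """

    threshold: float | str = "auto"
    min_syllable_s: float = 0.010
    merge_gap_s: float = 0.005
    bout_gap_s: float = 0.250
    # auto-threshold rule: floor + k * (robust peak - floor)
    auto_floor_pct: float = 10.0
    auto_peak_pct: float = 95.0
    auto_k: float = 0.1

    def __post_init__(self):
        if self.min_syllable_s <= 0 or self.merge_gap_s <= 0 or self.bout_gap_s <= 0:
            raise ValueError("durations must be positive")
        if not self.merge_gap_s < self.bout_gap_s:
            raise ValueError("merge gap must be smaller than bout gap")


def auto_threshold(e: Envelope, params: SegmentationParams | None = None) -> float:
    """Scale-equivariant amplitude threshold between noise floor and peak.

    threshold = floor + k * (robust_peak - floor), with the floor and robust
    peak taken as envelope percentiles. Raises ValueError on a flat envelope
    (no silence/vocalization bimodality to separate).
    """
    p = params or SegmentationParams()
    floor = float(np.percentile(e.values, p.auto_floor_pct))
    peak = float(np.percentile(e.values, p.auto_peak_pct))
    if peak <= floor:
        raise ValueError("no bimodality: envelope has no amplitude contrast")
    return floor + p.auto_k * (peak - floor)


def _runs_above(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index runs where mask is True."""
    if not mask.any():
        return []
    padded = np.diff(np.concatenate(([0], mask.astype(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    stops = np.flatnonzero(padded == -1)
    return list(zip(starts, stops))


def segment_syllables(
    e: Envelope, params: SegmentationParams | None = None
) -> list[SyllableInterval]:
    """Extract syllable intervals from an envelope.

    Supra-threshold runs are merged across gaps <= merge_gap_s, then filtered
    to duration > min_syllable_s (merge happens before the duration filter, so
    two short objects close together can survive as one syllable).
    """
    p = params or SegmentationParams()
    thr = auto_threshold(e, p) if p.threshold == "auto" else float(p.threshold)
    runs = _runs_above(e.values > thr)
    if not runs:
        return []
    max_gap = p.merge_gap_s * e.rate
    merged = [list(runs[0])]
    for start, stop in runs[1:]:
        if start - merged[-1][1] <= max_gap:
            merged[-1][1] = stop
        else:
            merged.append([start, stop])
    min_len = p.min_syllable_s * e.rate
    return [
        SyllableInterval(start / e.rate, stop / e.rate)
        for start, stop in merged
        if stop - start > min_len
    ]


def group_bouts(
    syllables: Sequence[SyllableInterval], params: SegmentationParams | None = None
) -> list[Bout]:
    """Partition sorted syllables into bouts at gaps > bout_gap_s (250 ms)."""
    p = params or SegmentationParams()
    if not syllables:
        return []
    bouts: list[list[SyllableInterval]] = [[syllables[0]]]
    for prev, cur in zip(syllables, syllables[1:]):
        if cur.onset - prev.offset > p.bout_gap_s:
            bouts.append([cur])
        else:
            bouts[-1].append(cur)
    return [Bout(tuple(b)) for b in bouts]


def write_intervals_tsv(path, bouts: Sequence[Bout]) -> None:
    """Write intervals as tab-separated onset_s, offset_s, bout_id with header."""
    with open(path, "w") as fh:
        fh.write("onset_s\toffset_s\tbout_id\n")
        for bout_id, bout in enumerate(bouts):
            for s in bout.syllables:
                fh.write(f"{s.onset:.6f}\t{s.offset:.6f}\t{bout_id}\n")


def read_intervals_tsv(path) -> list[Bout]:
    """Read bouts from the dialect written by :func:`write_intervals_tsv`."""
    groups: dict[int, list[SyllableInterval]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["onset_s", "offset_s", "bout_id"]:
            raise ValueError(f"unexpected interval file header: {header}")
        for line in fh:
            onset, offset, bout_id = line.split("\t")
            groups.setdefault(int(bout_id), []).append(
                SyllableInterval(float(onset), float(offset))
            )
    return [Bout(tuple(groups[k])) for k in sorted(groups)]
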