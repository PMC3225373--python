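"""Position-weighted penalty scoring of miRNA/transcript complementarity.

The miRNA is aligned antiparallel against transcript windows; each aligned
position contributes a penalty (mismatch 1.0, G:U wobble 0.5, gap 2.0)
multiplied by a positional weight that doubles penalties over the 5'/central
"core" of the miRNA (positions 2-13 from its 5' end), following the standard
plant-target scoring convention.  A perfect complement scores 0; sites are
reported below a cutoff (3.5 by default).  Without gaps every score is a
multiple of 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from ._seq import is_complement, is_wobble, normalize
from .io_formats import SequenceRecord

STATE_MATCH = "match"
STATE_MISMATCH = "mismatch"
STATE_GU = "GU"
STATE_GAP_IN_MIRNA = "gap_in_mirna"  # extra (bulged) target base
STATE_GAP_IN_TARGET = "gap_in_target"  # unpaired miRNA base


@dataclass(frozen=True)
class ScoringWeights:
    mismatch: float = 1.0
    gu: float = 0.5
    gap: float = 2.0
    core_start: int = 2
    core_end: int = 13
    core_weight: float = 2.0

    def position_weight(self, mirna_pos: int) -> float:
        return (
            self.core_weight
            if self.core_start <= mirna_pos <= self.core_end
            else 1.0
        )


DEFAULT_WEIGHTS = ScoringWeights()


@dataclass(frozen=True)
class TargetAlignment:
    """Alignment state vector, indexed by miRNA position from the 5' end.

    Each element is ``(state, mirna_pos)``; gap states carry the position of
    the adjacent miRNA base used for weighting.
    """

    mirna: str
    transcript_id: str
    start: int  # 1-based closed, transcript coordinates
    end: int
    states: tuple[tuple[str, int], ...]

    def paired_string(self) -> str:
        marks = {
            STATE_MATCH: "|",
            STATE_GU: "o",
            STATE_MISMATCH: " ",
            STATE_GAP_IN_MIRNA: "-",
            STATE_GAP_IN_TARGET: "-",
        }
        return "".join(marks[s] for s, _ in self.states)


@dataclass(frozen=True)
class TargetSite:
    alignment: TargetAlignment
    score: float

    @property
    def start(self) -> int:
        return self.alignment.start

    @property
    def end(self) -> int:
        return self.alignment.end

    @property
    def transcript_id(self) -> str:
        return self.alignment.transcript_id


def score_alignment(
    alignment: TargetAlignment | Iterable[tuple[str, int]],
    weights: ScoringWeights = DEFAULT_WEIGHTS,
) -> float:
    """Sum of per-state penalties times positional weights."""
    states = alignment.states if isinstance(alignment, TargetAlignment) else alignment
    penalty = {
        STATE_MATCH: 0.0,
        STATE_MISMATCH: weights.mismatch,
        STATE_GU: weights.gu,
        STATE_GAP_IN_MIRNA: weights.gap,
        STATE_GAP_IN_TARGET: weights.gap,
    }
    return sum(penalty[s] * weights.position_weight(p) for s, p in states)


def _pair_state(mirna_base: str, target_base: str) -> str:
    if is_complement(mirna_base, target_base):
        return STATE_MATCH
    if is_wobble(mirna_base, target_base):
        return STATE_GU
    return STATE_MISMATCH


def _ungapped_states(mirna: str, window: str) -> tuple[tuple[str, int], ...]:
    # antiparallel: miRNA position i (1-based from 5') faces window base
    # len(window) - i (0-based)
    L = len(mirna)
    return tuple(
        (_pair_state(mirna[i], window[L - 1 - i]), i + 1) for i in range(L)
    )


def _gap_in_target_states(
    mirna: str, window: str, gap_pos: int
) -> tuple[tuple[str, int], ...]:
    # miRNA base at 1-based gap_pos is unpaired; window length = L - 1
    states = []
    wlen = len(window)
    w = wlen  # next window index from the 3' side (consumed downward)
    for i in range(len(mirna)):
        pos = i + 1
        if pos == gap_pos:
            states.append((STATE_GAP_IN_TARGET, pos))
        else:
            w -= 1
            states.append((_pair_state(mirna[i], window[w]), pos))
    return tuple(states)


def _gap_in_mirna_states(
    mirna: str, window: str, after_pos: int
) -> tuple[tuple[str, int], ...]:
    # one extra target base bulged between miRNA positions after_pos and
    # after_pos + 1; window length = L + 1
    states: list[tuple[str, int]] = []
    w = len(window)
    for i in range(len(mirna)):
        pos = i + 1
        w -= 1
        states.append((_pair_state(mirna[i], window[w]), pos))
        if pos == after_pos:
            w -= 1
            states.append((STATE_GAP_IN_MIRNA, pos + 1))
    return tuple(states)


def _candidate_alignments(
    mirna: str, transcript: SequenceRecord, max_gaps: int
) -> Iterable[TargetAlignment]:
    seq = transcript.sequence
    L = len(mirna)
    for start in range(len(seq) - L + 1):
        window = seq[start : start + L]
        yield TargetAlignment(
            mirna, transcript.id, start + 1, start + L, _ungapped_states(mirna, window)
        )
    if max_gaps >= 1:
        for start in range(len(seq) - (L - 1) + 1):
            window = seq[start : start + L - 1]
            for gap_pos in range(2, L):  # terminal gaps are just overhangs
                yield TargetAlignment(
                    mirna,
                    transcript.id,
                    start + 1,
                    start + L - 1,
                    _gap_in_target_states(mirna, window, gap_pos),
                )
        for start in range(len(seq) - (L + 1) + 1):
            window = seq[start : start + L + 1]
            for after_pos in range(1, L):
                yield TargetAlignment(
                    mirna,
                    transcript.id,
                    start + 1,
                    start + L + 1,
                    _gap_in_mirna_states(mirna, window, after_pos),
                )


def find_sites(
    mirna: str,
    transcript: SequenceRecord,
    cutoff: float = 3.5,
    max_gaps: int = 1,
    weights: ScoringWeights = DEFAULT_WEIGHTS,
) -> list[TargetSite]:
    """All non-overlapping target sites with score <= cutoff, best first
    (ties by leftmost start)."""
    mirna = normalize(mirna)
    if len(transcript.sequence) < len(mirna):
        return []
    hits = [
        TargetSite(aln, score)
        for aln in _candidate_alignments(mirna, transcript, max_gaps)
        if (score := score_alignment(aln, weights)) <= cutoff
    ]
    hits.sort(key=lambda s: (s.score, s.start, s.end))
    chosen: list[TargetSite] = []
    for hit in hits:
        if all(hit.end < c.start or hit.start > c.end for c in chosen):
            chosen.append(hit)
    return chosen


def predict_targets(
    mirnas: Sequence[SequenceRecord],
    transcripts: Sequence[SequenceRecord],
    cutoff: float = 3.5,
    max_gaps: int = 1,
    weights: ScoringWeights = DEFAULT_WEIGHTS,
) -> pd.DataFrame:
    """Cross-product site scan; one row per (miRNA, transcript) pair with at
    least one site, listing the best score and all site scores."""
    rows = []
    for mir in mirnas:
        for tx in transcripts:
            sites = find_sites(mir.sequence, tx, cutoff, max_gaps, weights)
            if sites:
                rows.append(
                    {
                        "mirna": mir.id,
                        "transcript": tx.id,
                        "n_sites": len(sites),
                        "best_score": min(s.score for s in sites),
                        "scores": ",".join(
                            f"{s.score:g}" for s in sorted(sites, key=lambda x: x.start)
                        ),
                    }
                )
    return pd.DataFrame(
        rows, columns=["mirna", "transcript", "n_sites", "best_score", "scores"]
    )
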