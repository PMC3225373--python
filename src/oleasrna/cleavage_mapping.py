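"""Mapping of RACE-derived 5' ends onto a target transcript.

RNA-ligase-mediated 5' RACE clones the 3' fragment left by AGO-guided
endonucleolytic cleavage; its first nucleotide marks the cut.  Positions are
expressed both in transcript coordinates and in miRNA-duplex coordinates:
with the miRNA 5' end opposite the 3' end of its site, miRNA position k
faces transcript position ``site_end - k + 1``, so a clone starting at
``site_end - 9`` maps to the canonical "10/11" slicing boundary.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

from ._seq import normalize
from .io_formats import SequenceRecord
from .target_prediction import TargetSite


@dataclass
class CleavageMap:
    transcript_id: str
    site: TargetSite
    by_label: Counter = field(default_factory=Counter)
    by_position: Counter = field(default_factory=Counter)
    unmapped: int = 0

    @property
    def n_mapped(self) -> int:
        return sum(self.by_position.values())


def map_race_ends(
    clones: Sequence[SequenceRecord | str],
    transcript: SequenceRecord,
    max_mismatches: int = 0,
) -> tuple[list[int], int]:
    """Transcript coordinate (1-based) of each clone's first nucleotide.

    Clones are 5'-anchored fragments running toward the transcript 3' end;
    matching is exact by default (RACE products are sequenced), with an
    optional mismatch allowance.  Returns (positions, n_unmapped).
    """
    seq = transcript.sequence
    positions: list[int] = []
    unmapped = 0
    for clone in clones:
        c = normalize(clone.sequence if isinstance(clone, SequenceRecord) else clone)
        pos = _map_one(c, seq, max_mismatches)
        if pos is None:
            unmapped += 1
        else:
            positions.append(pos)
    return positions, unmapped


def _map_one(clone: str, seq: str, max_mismatches: int) -> int | None:
    if max_mismatches == 0:
        pos = seq.find(clone)
        return pos + 1 if pos != -1 else None
    best = None
    for start in range(len(seq) - len(clone) + 1):
        mm = sum(a != b for a, b in zip(clone, seq[start : start + len(clone)]))
        if mm <= max_mismatches and (best is None or mm < best[1]):
            best = (start + 1, mm)
    return best[0] if best else None


def position_in_duplex(transcript_position: int, site: TargetSite) -> str:
    """Duplex label for a mapped 5' end.

    Inside the site the label is "k/k+1": the clone's first nucleotide faces
    miRNA position k, i.e. the cut fell between the target bases paired to
    miRNA positions k and k+1.  Outside: "upstream n nt" / "downstream n nt"
    relative to the site boundaries.
    """
    t = transcript_position
    if t < site.start:
        return f"upstream {site.start - t} nt"
    if t > site.end:
        return f"downstream {t - site.end} nt"
    k = site.end - t + 1
    return f"{k}/{k + 1}"


def build_cleavage_map(
    clones: Sequence[SequenceRecord | str],
    transcript: SequenceRecord,
    site: TargetSite,
    max_mismatches: int = 0,
) -> CleavageMap:
    positions, unmapped = map_race_ends(clones, transcript, max_mismatches)
    cmap = CleavageMap(transcript.id, site, unmapped=unmapped)
    for pos in positions:
        cmap.by_position[pos] += 1
        cmap.by_label[position_in_duplex(pos, site)] += 1
    return cmap


@dataclass
class CleavageSummary:
    dominant_labels: list[str]
    dominant_count: int
    n_mapped: int

    @property
    def fraction(self) -> str:
        """Figure-style clone fraction, e.g. "16/16"."""
        return f"{self.dominant_count}/{self.n_mapped}"

    @property
    def tied(self) -> bool:
        return len(self.dominant_labels) > 1


def tally_cleavage(cmap: CleavageMap) -> CleavageSummary:
    """Dominant cleavage position(s) with their clone fraction."""
    if not cmap.by_label:
        raise ValueError("no mapped clones to tally")
    top = max(cmap.by_label.values())
    dominants = sorted(k for k, v in cmap.by_label.items() if v == top)
    return CleavageSummary(dominants, top, cmap.n_mapped)
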