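"""TAS3 "two-hit" architecture detection and tasiRNA phase registers.

A TAS3 precursor carries two miR390 complementary sites flanking the
tasiRNA-producing region.  Cleavage at the 3' site (between the target bases
paired to miR390 positions 10 and 11) sets a 21-nt phase register; counting
consecutive 21-nt windows from that anchor toward the 5' site, the
ARF-targeting tasiRNAs (tasiARFs) occupy phases D7(+) and D8(+).  The
anchoring direction is configurable because the D-position nomenclature in
the literature is counted from either site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from ._seq import hamming, normalize
from .io_formats import SequenceRecord
from . import target_prediction
from .target_prediction import TargetSite

PHASE_LENGTH = 21

TOWARD_5P = "toward-5p-site"
TOWARD_3P = "toward-3p-end"


def find_mir390_sites(
    transcript: SequenceRecord,
    mir390: str,
    cutoff: float = 4.0,
) -> list[TargetSite]:
    """miR390 complementary sites ordered 5'->3'.  The cutoff is elevated
    relative to the global 3.5 because functional miR390 sites (the 5' one
    in particular) tolerate more mispairing."""
    sites = target_prediction.find_sites(mir390, transcript, cutoff=cutoff)
    return sorted(sites, key=lambda s: s.start)


def cleavage_point(site: TargetSite) -> int:
    """Transcript coordinate of the last nucleotide 5' of the cut.

    With the miRNA 5' end opposite ``site.end``, miRNA position k faces
    transcript position ``site.end - k + 1``; slicing between the bases
    paired to positions 10 and 11 puts the phosphodiester boundary between
    ``site.end - 10`` and ``site.end - 9``.
    """
    if site.end - site.start + 1 < 11:
        raise ValueError("site too short to hold a 10/11 cleavage boundary")
    return site.end - 10


@dataclass
class PhaseRegister:
    """Consecutive non-overlapping phase windows D1..Dn from an anchor.

    ``anchor`` is a cut boundary: the cut lies between transcript positions
    ``anchor`` and ``anchor + 1``.  Toward the 3' end, D1 starts at
    ``anchor + 1``; toward the 5' site, D1 ends at ``anchor``.
    """

    anchor: int
    direction: str
    phase_length: int
    windows: list[tuple[int, int, int]]  # (k, start, end), 1-based closed
    truncated: bool = False

    def window(self, k: int) -> tuple[int, int]:
        for idx, start, end in self.windows:
            if idx == k:
                return start, end
        raise KeyError(f"phase D{k} not enumerated")


def enumerate_phases(
    anchor: int,
    direction: str,
    n: int,
    phase_length: int = PHASE_LENGTH,
    transcript_length: int | None = None,
) -> PhaseRegister:
    """Windows D1..Dn counted from the cleavage anchor; windows that would
    run off the transcript are dropped and the register flagged truncated."""
    if n < 1:
        raise ValueError("need at least one phase window")
    windows = []
    truncated = False
    for k in range(1, n + 1):
        if direction == TOWARD_3P:
            start = anchor + (k - 1) * phase_length + 1
            end = anchor + k * phase_length
        elif direction == TOWARD_5P:
            start = anchor - k * phase_length + 1
            end = anchor - (k - 1) * phase_length
        else:
            raise ValueError(f"unknown direction {direction!r}")
        if start < 1 or (transcript_length is not None and end > transcript_length):
            truncated = True
            continue
        windows.append((k, start, end))
    return PhaseRegister(anchor, direction, phase_length, windows, truncated)


@dataclass
class TasiarfHit:
    start: int  # transcript coordinates, 1-based closed
    end: int
    reference_id: str
    mismatches: int
    phase: int | None = None  # integer phase index when in register
    phase_offset: int | None = None  # residue (nt) when off register


@dataclass
class TAS3Annotation:
    transcript_id: str
    five_prime_site: TargetSite | None
    three_prime_site: TargetSite | None
    tasiarf_hits: list[TasiarfHit] = field(default_factory=list)
    verdict: str = "fail"  # "full" | "partial" | "fail"


def _scan_tasiarf(
    transcript: SequenceRecord,
    references: Sequence[SequenceRecord],
    max_mm: int,
) -> list[TasiarfHit]:
    """Best-scoring homologous 21-mer windows (<= max_mm vs any reference);
    overlapping windows are reduced to local-minimum mismatch hits."""
    seq = transcript.sequence
    raw: list[TasiarfHit] = []
    for ref in references:
        r = normalize(ref.sequence)
        L = len(r)
        for start in range(len(seq) - L + 1):
            mm = hamming(seq[start : start + L], r)
            if mm <= max_mm:
                raw.append(TasiarfHit(start + 1, start + L, ref.id, mm))
    raw.sort(key=lambda h: (h.mismatches, h.start))
    chosen: list[TasiarfHit] = []
    for hit in raw:
        if all(hit.end < c.start or hit.start > c.end for c in chosen):
            chosen.append(hit)
    chosen.sort(key=lambda h: h.start)
    return chosen


def assign_tasiarf_phases(
    transcript: SequenceRecord,
    mir390_sites: Sequence[TargetSite],
    tasiarf_refs: Sequence[SequenceRecord],
    max_mm: int = 3,
    anchor_site: str = "3p",
    phase_length: int = PHASE_LENGTH,
) -> TAS3Annotation:
    """Locate tasiARF-homologous windows and place them on the phase
    register anchored at the 3' miR390 site (configurable to the 5' site).

    Verdict: "full" when dual sites flank two adjacent tasiARF windows at
    consecutive integer phases; "partial" when tasiARFs are found but the
    site architecture is incomplete; else "fail".
    """
    if not mir390_sites:
        raise ValueError("need at least one miR390 site")
    sites = sorted(mir390_sites, key=lambda s: s.start)
    site5 = sites[0] if len(sites) >= 2 else None
    site3 = sites[-1]
    hits = _scan_tasiarf(transcript, tasiarf_refs, max_mm)

    if anchor_site == "3p":
        anchor = cleavage_point(site3)
        direction = TOWARD_5P
    else:
        if site5 is None:
            raise ValueError("5' anchoring requested but only one site found")
        anchor = cleavage_point(site5)
        direction = TOWARD_3P

    for hit in hits:
        if direction == TOWARD_5P:
            # Dk ends at anchor - (k-1)*21
            resid = (anchor - hit.end) % phase_length
            k = (anchor - hit.end) // phase_length + 1
        else:
            resid = (hit.start - anchor - 1) % phase_length
            k = (hit.start - anchor - 1) // phase_length + 1
        if resid == 0 and k >= 1:
            hit.phase = k
            hit.phase_offset = 0
        else:
            hit.phase = None
            hit.phase_offset = resid

    annotation = TAS3Annotation(
        transcript_id=transcript.id,
        five_prime_site=site5,
        three_prime_site=site3,
        tasiarf_hits=hits,
    )
    phased = sorted((h for h in hits if h.phase is not None), key=lambda h: h.phase)
    adjacent = any(
        b.phase == a.phase + 1 for a, b in zip(phased, phased[1:])
    )
    between = (
        site5 is not None
        and all(site5.end < h.start and h.end < site3.start for h in hits)
        if hits
        else False
    )
    if site5 is not None and len(phased) >= 2 and adjacent and between:
        annotation.verdict = "full"
    elif hits and site5 is None:
        # tasiARFs found but the dual-site architecture cannot be mapped
        annotation.verdict = "partial"
    else:
        annotation.verdict = "fail"
    return annotation


@dataclass
class DualSiteReport:
    transcript_id: str
    n_sites: int
    scores: list[float]
    has_dual_sites: bool


def find_tasiarf_targets(
    tasiarf: str,
    transcripts: Sequence[SequenceRecord],
    cutoff: float = 3.5,
) -> list[DualSiteReport]:
    """Per transcript, count tasiARF-complementary sites under the cutoff
    and flag transcripts with exactly two (the conserved ARF3/ARF4
    dual-site layout)."""
    reports = []
    for tx in transcripts:
        sites = target_prediction.find_sites(tasiarf, tx, cutoff=cutoff)
        sites = sorted(sites, key=lambda s: s.start)
        reports.append(
            DualSiteReport(
                transcript_id=tx.id,
                n_sites=len(sites),
                scores=[s.score for s in sites],
                has_dual_sites=len(sites) == 2,
            )
        )
    return reports
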