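"""Candidate miRNA precursor extraction, folding and stem-loop criteria.

Windows of 50-200 nt flanking a candidate sRNA are excised from its host
transcript and folded.  Two backends share the
``fold(sequence) -> (structure, energy_score)`` contract (lower = more
stable): a self-contained dynamic program maximizing weighted base pairs
(GC=3, AU=2, GU=1; hairpin loops of at least 3 nt; no pseudoknots;
``energy_score`` = negated total weight), and ViennaRNA minimum-free-energy
folding (kcal/mol), which hairpin verdicts use by default.

A candidate PASSes when the sRNA sits in a single stem arm without touching
the terminal loop, pairs with its star arm with few unpaired bases and small
asymmetric bulges, and folds more stably than the mean of seeded
dinucleotide-shuffled versions of its window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from ._seq import normalize
from .io_formats import SequenceRecord

_ENC = {"A": 0, "C": 1, "G": 2, "U": 3, "N": 4}
_PAIRW = np.zeros((5, 5), dtype=np.int32)
_PAIRW[_ENC["G"], _ENC["C"]] = _PAIRW[_ENC["C"], _ENC["G"]] = 3
_PAIRW[_ENC["A"], _ENC["U"]] = _PAIRW[_ENC["U"], _ENC["A"]] = 2
_PAIRW[_ENC["G"], _ENC["U"]] = _PAIRW[_ENC["U"], _ENC["G"]] = 1

MIN_LOOP = 3


@njit(cache=False)
def _fill(enc, pairw, minloop):  # pragma: no cover - exercised via fold()
    n = enc.shape[0]
    m = np.zeros((n, n), dtype=np.int32)
    for span in range(minloop + 1, n):
        for i in range(n - span):
            j = i + span
            best = m[i + 1, j]
            if m[i, j - 1] > best:
                best = m[i, j - 1]
            w = pairw[enc[i], enc[j]]
            if w > 0:
                t = m[i + 1, j - 1] + w
                if t > best:
                    best = t
            for k in range(i + 1, j):
                t = m[i, k] + m[k + 1, j]
                if t > best:
                    best = t
            m[i, j] = best
    return m


def _traceback(m, enc, pairw, minloop):
    n = enc.shape[0]
    pairs = np.full(n, -1, dtype=np.int64)
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= minloop:
            continue
        v = m[i, j]
        if v == m[i + 1, j]:
            stack.append((i + 1, j))
            continue
        if v == m[i, j - 1]:
            stack.append((i, j - 1))
            continue
        w = pairw[enc[i], enc[j]]
        if w > 0 and v == m[i + 1, j - 1] + w:
            pairs[i], pairs[j] = j, i
            stack.append((i + 1, j - 1))
            continue
        for k in range(i + 1, j):
            if v == m[i, k] + m[k + 1, j]:
                stack.append((i, k))
                stack.append((k + 1, j))
                break
    return pairs


@dataclass
class FoldResult:
    sequence: str
    structure: str
    energy_score: float
    pairs: np.ndarray  # partner index per position, -1 if unpaired

    def partner(self, i: int) -> int:
        """1-based partner of 1-based position ``i`` (0 if unpaired)."""
        p = int(self.pairs[i - 1])
        return p + 1 if p >= 0 else 0


def fold(sequence: str, min_loop: int = MIN_LOOP) -> FoldResult:
    """Fold with the weighted maximum-pairing backend (deterministic).

    This self-contained backend has an exact contract (energy_score is the
    negated total pair weight) and is cross-checked against exhaustive
    structure enumeration; being a pure pairing count, however, it admits
    many co-optimal structures on natural sequences, so hairpin *verdicts*
    default to the thermodynamic backend (:func:`fold_vienna`).
    """
    seq = normalize(sequence)
    if len(seq) < 2:
        raise ValueError("sequence too short to fold")
    enc = np.array([_ENC[c] for c in seq], dtype=np.int8)
    m = _fill(enc, _PAIRW, min_loop)
    pairs = _traceback(m, enc, _PAIRW, min_loop)
    structure = "".join(
        "." if p < 0 else ("(" if p > i else ")") for i, p in enumerate(pairs)
    )
    return FoldResult(seq, structure, -float(m[0, len(seq) - 1]), pairs)


def _pairs_from_dotbracket(structure: str) -> np.ndarray:
    pairs = np.full(len(structure), -1, dtype=np.int64)
    stack: list[int] = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            j = stack.pop()
            pairs[i], pairs[j] = j, i
    if stack:
        raise ValueError("unbalanced dot-bracket structure")
    return pairs


def fold_vienna(sequence: str) -> FoldResult:
    """Minimum-free-energy fold via ViennaRNA; energy_score in kcal/mol."""
    import RNA

    seq = normalize(sequence)
    structure, energy = RNA.fold(seq)
    return FoldResult(seq, structure, float(energy), _pairs_from_dotbracket(structure))


BACKENDS = {"maxpair": fold, "vienna": fold_vienna}


# -- dinucleotide shuffle ----------------------------------------------------

def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle preserving exact dinucleotide counts (Altschul-Erickson).

    For each symbol except the last one, a terminal out-edge is drawn at
    random and redrawn until the terminal edges form a tree into the last
    symbol; the remaining edges are randomly ordered.  Walking the resulting
    edge lists yields a uniform random Eulerian path, i.e. a sequence with
    identical dinucleotide (and hence mononucleotide) composition.
    """
    if len(seq) < 3:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    vertices = sorted(edges)
    last = seq[-1]
    terminal: dict[str, str] = {}
    while True:
        terminal = {
            v: edges[v][int(rng.integers(len(edges[v])))]
            for v in vertices
            if v != last
        }
        if all(_reaches(v, last, terminal) for v in vertices if v != last):
            break
    lists: dict[str, list[str]] = {}
    for v in vertices:
        rest = list(edges[v])
        if v != last:
            rest.remove(terminal[v])
        rng.shuffle(rest)
        if v != last:
            rest.append(terminal[v])
        lists[v] = rest
    out = [seq[0]]
    ptr = {v: 0 for v in vertices}
    cur = seq[0]
    for _ in range(len(seq) - 1):
        nxt = lists[cur][ptr[cur]]
        ptr[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def _reaches(v: str, last: str, terminal: dict[str, str]) -> bool:
    seen = set()
    while v != last:
        if v in seen or v not in terminal:
            return False
        seen.add(v)
        v = terminal[v]
    return True


# -- windows and criteria ----------------------------------------------------

@dataclass(frozen=True)
class PrecursorWindow:
    """Candidate precursor excised around an sRNA hit (1-based closed)."""

    transcript_id: str
    start: int
    end: int
    sequence: str
    srna_start: int  # position of the sRNA within the window, 1-based
    srna_end: int
    flank: int
    truncated_5p: bool = False
    truncated_3p: bool = False


def extract_precursor_windows(
    srna: str,
    transcript: SequenceRecord,
    flanks: tuple[int, ...] = (50, 100, 150, 200),
    whole_transcript_fallback: bool = True,
) -> list[PrecursorWindow]:
    """One window per sRNA occurrence per flank setting (then the whole
    transcript as a final fallback).  Truncated flanks are flagged."""
    srna = normalize(srna)
    seq = transcript.sequence
    occurrences = []
    pos = seq.find(srna)
    while pos != -1:
        occurrences.append(pos)
        pos = seq.find(srna, pos + 1)
    windows: list[PrecursorWindow] = []
    settings: list[int | None] = list(flanks)
    if whole_transcript_fallback:
        settings.append(None)
    for occ in occurrences:
        for flank in settings:
            if flank is None:
                start, end = 0, len(seq)
                fl = max(occ, len(seq) - (occ + len(srna)))
            else:
                start = max(0, occ - flank)
                end = min(len(seq), occ + len(srna) + flank)
                fl = flank
            windows.append(
                PrecursorWindow(
                    transcript_id=transcript.id,
                    start=start + 1,
                    end=end,
                    sequence=seq[start:end],
                    srna_start=occ - start + 1,
                    srna_end=occ - start + len(srna),
                    flank=fl,
                    truncated_5p=flank is not None and occ < flank,
                    truncated_3p=flank is not None
                    and len(seq) - (occ + len(srna)) < flank,
                )
            )
    return windows


@dataclass(frozen=True)
class HairpinCriteria:
    """Stem-loop acceptance thresholds (config-exposed; the criteria family
    follows the standard plant-miRNA annotation checklist)."""

    max_unpaired_mirna_bases: int = 4
    max_asymmetric_bulge: int = 2
    n_shuffles: int = 100
    shuffle_seed: int = 2011
    require_shuffle_null: bool = True
    backend: str = "vienna"


@dataclass
class DuplexStats:
    n_unpaired_mirna_bases: int
    max_asymmetric_bulge: int
    loop_overlap: bool
    arm: str | None  # "5p" | "3p" | None


@dataclass
class HairpinCandidate:
    window: PrecursorWindow
    structure: str
    energy_score: float
    arm: str | None
    star_start: int | None  # window coordinates, 1-based
    star_end: int | None
    duplex: DuplexStats
    verdict: str  # "PASS" | "FAIL"
    failed_criteria: list[str] = field(default_factory=list)
    shuffle_null_mean: float | None = None


def _duplex_stats(pairs: np.ndarray, s0: int, e0: int) -> DuplexStats:
    """Pairing statistics for the sRNA occupying 0-based [s0, e0]."""
    partners = [(i, int(pairs[i])) for i in range(s0, e0 + 1) if pairs[i] >= 0]
    if not partners:
        return DuplexStats(e0 - s0 + 1, 0, False, None)
    left = [p for _, p in partners if p < s0]
    right = [p for _, p in partners if p > e0]
    internal = [p for _, p in partners if s0 <= p <= e0]
    if internal or (left and right):
        # pairs within itself or partners on both sides: spans the loop
        return DuplexStats(
            (e0 - s0 + 1) - len(partners), 0, True, None
        )
    arm = "5p" if right else "3p"
    unpaired = (e0 - s0 + 1) - len(partners)
    max_bulge = 0
    for (i1, p1), (i2, p2) in zip(partners, partners[1:]):
        gap_mirna = i2 - i1 - 1
        gap_star = abs(p1 - p2) - 1
        max_bulge = max(max_bulge, abs(gap_mirna - gap_star))
    return DuplexStats(unpaired, max_bulge, False, arm)


def find_star(
    fold_result: FoldResult, mirna_start: int, mirna_end: int
) -> tuple[int, int, DuplexStats] | None:
    """Star coordinates (1-based, within the folded sequence) for the miRNA
    at [mirna_start, mirna_end], using the 2-nt 3' overhang convention of
    DCL duplexes; None when the miRNA is fully unpaired."""
    s0, e0 = mirna_start - 1, mirna_end - 1
    pairs = fold_result.pairs
    stats = _duplex_stats(pairs, s0, e0)
    partners = [int(pairs[i]) for i in range(s0, e0 + 1) if pairs[i] >= 0]
    if not partners:
        return None
    n = len(fold_result.sequence)
    star_start = min(partners) + 2
    star_end = max(partners) + 2
    star_start = max(0, min(star_start, n - 1))
    star_end = max(0, min(star_end, n - 1))
    return star_start + 1, star_end + 1, stats


def evaluate_hairpin(
    window: PrecursorWindow,
    fold_result: FoldResult | None = None,
    criteria: HairpinCriteria = HairpinCriteria(),
    short_circuit: bool = True,
) -> HairpinCandidate:
    """Apply the stem-loop criteria to one precursor window.

    Criteria, cheapest first: (i) sRNA confined to one stem arm without
    touching the terminal loop; (ii) at most ``max_unpaired_mirna_bases``
    sRNA bases unpaired against the star arm; (iii) largest asymmetric bulge
    in the duplex <= ``max_asymmetric_bulge``; (iv) window folds more stably
    than the mean of seeded dinucleotide shuffles.  With ``short_circuit``
    the expensive shuffle null is only computed when (i)-(iii) hold.

    Verdicts default to the thermodynamic backend: under pure base-pair
    maximization the optimum is massively degenerate on natural sequences,
    so which partners the sRNA receives is a tie-break artifact rather than
    a property of the locus.
    """
    backend = BACKENDS[criteria.backend]
    if fold_result is None:
        fold_result = backend(window.sequence)
    s0, e0 = window.srna_start - 1, window.srna_end - 1
    stats = _duplex_stats(fold_result.pairs, s0, e0)
    failed: list[str] = []
    if stats.loop_overlap or stats.arm is None:
        failed.append("loop_overlap")
    if stats.n_unpaired_mirna_bases > criteria.max_unpaired_mirna_bases:
        failed.append("unpaired_mirna_bases")
    if stats.max_asymmetric_bulge > criteria.max_asymmetric_bulge:
        failed.append("asymmetric_bulge")

    null_mean: float | None = None
    if criteria.require_shuffle_null and not (failed and short_circuit):
        rng = np.random.default_rng(criteria.shuffle_seed)
        scores = [
            backend(dinucleotide_shuffle(fold_result.sequence, rng)).energy_score
            for _ in range(criteria.n_shuffles)
        ]
        null_mean = float(np.mean(scores))
        if not fold_result.energy_score < null_mean:
            failed.append("shuffle_null")

    star = find_star(fold_result, window.srna_start, window.srna_end)
    return _make_candidate(window, fold_result, stats, star, failed, null_mean)


def _make_candidate(window, fold_result, stats, star, failed, null_mean):
    return HairpinCandidate(
        window=window,
        structure=fold_result.structure,
        energy_score=fold_result.energy_score,
        arm=stats.arm,
        star_start=star[0] if star else None,
        star_end=star[1] if star else None,
        duplex=stats,
        verdict="FAIL" if failed else "PASS",
        failed_criteria=failed,
        shuffle_null_mean=null_mean,
    )


def evaluate_candidate(
    srna: str,
    transcript: SequenceRecord,
    flanks: tuple[int, ...] = (50, 100, 150, 200),
    criteria: HairpinCriteria = HairpinCriteria(),
) -> HairpinCandidate | None:
    """Evaluate an sRNA's precursor potential over increasing window sizes.

    Mirrors the usual annotation procedure: fold the smallest window first
    and move to larger flanks when no acceptable local foldback appears.
    Returns the first PASSing candidate, the last FAILing one when none
    passes, or None when the sRNA does not occur in the transcript.
    """
    last: HairpinCandidate | None = None
    for window in extract_precursor_windows(srna, transcript, flanks):
        last = evaluate_hairpin(window, criteria=criteria)
        if last.verdict == "PASS":
            return last
    return last
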