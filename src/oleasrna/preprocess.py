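"""Raw-read cleaning: adapter excision, artifact triage and the filter
cascade (size, complexity, non-coding-RNA), with exact bookkeeping.

The cascade mirrors a 454 sRNA library workflow: every raw read is either an
adapter artifact (empty construct, adapter multimer, unrecognizable) or
yields an insert, which is then removed by the FIRST failing filter among
N-content, size (18-25 nt), complexity (>=3 distinct bases) and ncRNA
homology.  Counts therefore close exactly:
``adapter_removed = filtered + sum(per-filter removals)``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from ._seq import normalize
from .io_formats import AdapterConfig, SequenceRecord

ARTIFACT_NO_INSERT = "no_insert"
ARTIFACT_MULTIMER = "multimer"
ARTIFACT_UNRECOGNIZED = "unrecognized"

FILTER_CONTAINS_N = "contains_n"
FILTER_SIZE = "size"
FILTER_COMPLEXITY = "complexity"
FILTER_NCRNA = "ncrna"

FILTER_ORDER = (FILTER_CONTAINS_N, FILTER_SIZE, FILTER_COMPLEXITY, FILTER_NCRNA)


@dataclass
class StripResult:
    """Outcome of adapter excision: an insert, or an artifact class."""

    insert: str | None
    artifact: str | None = None

    @property
    def is_artifact(self) -> bool:
        return self.artifact is not None


@dataclass
class LibraryStats:
    """Per-stage accounting for one library run (raw / adapter-removed /
    filtered, with per-class artifact and removal counts)."""

    raw_reads: int = 0
    artifacts: Counter = field(default_factory=Counter)
    adapter_removed_reads: int = 0
    removed: Counter = field(default_factory=Counter)
    filtered_reads: int = 0
    unique_sequences: int = 0

    def check_closure(self) -> None:
        if self.raw_reads != self.adapter_removed_reads + sum(self.artifacts.values()):
            raise AssertionError("artifact accounting does not close")
        if self.adapter_removed_reads != self.filtered_reads + sum(self.removed.values()):
            raise AssertionError("filter accounting does not close")


@dataclass
class SRNALibrary:
    """A cleaned, de-duplicated sRNA library: sequence -> read count."""

    label: str
    entries: dict[str, int]
    stats: LibraryStats

    @property
    def total_reads(self) -> int:
        return sum(self.entries.values())

    @property
    def unique_sequences(self) -> int:
        return len(self.entries)


def _adapter_at(read: str, pos: int, adapter: str, min_anchor: int) -> bool:
    """Adapter call: exact match on the first ``min_anchor`` bases, then at
    most one mismatch over the rest of the adapter (truncation at the read
    end is tolerated, as 454 reads may stop inside the 3' adapter)."""
    if read[pos : pos + min_anchor] != adapter[:min_anchor]:
        return False
    tail = adapter[min_anchor:]
    got = read[pos + min_anchor : pos + len(adapter)]
    mismatches = sum(a != b for a, b in zip(got, tail))
    return mismatches <= 1


def _find_all(read: str, adapter: str, start: int, min_anchor: int) -> list[int]:
    hits = []
    pos = start
    while True:
        pos = read.find(adapter[:min_anchor], pos)
        if pos == -1:
            return hits
        if _adapter_at(read, pos, adapter, min_anchor):
            hits.append(pos)
        pos += 1


def strip_adapters(read: SequenceRecord | str, adapters: AdapterConfig) -> StripResult:
    """Excise the insert between the 5' and 3' adapters of one raw read.

    Classifications (never errors): ``no_insert`` when the adapters abut
    (empty construct), ``multimer`` when more than one copy of an adapter is
    present, ``unrecognized`` when either adapter is missing.
    """
    seq = normalize(read.sequence if isinstance(read, SequenceRecord) else read)
    anchor = adapters.min_anchor
    end5 = None
    for variant in adapters.five_prime_variants:
        if _adapter_at(seq, 0, variant, anchor):
            end5 = len(variant)
            break
    if end5 is None:
        return StripResult(None, ARTIFACT_UNRECOGNIZED)
    # extra 5' adapter copies downstream -> multimer
    for variant in adapters.five_prime_variants:
        if _find_all(seq, variant, end5, anchor):
            return StripResult(None, ARTIFACT_MULTIMER)
    hits3 = _find_all(seq, adapters.three_prime, end5, anchor)
    if not hits3:
        return StripResult(None, ARTIFACT_UNRECOGNIZED)
    if len(hits3) > 1:
        return StripResult(None, ARTIFACT_MULTIMER)
    insert = seq[end5 : hits3[0]]
    if not insert:
        return StripResult(None, ARTIFACT_NO_INSERT)
    return StripResult(insert)


def filter_size(seq: str, min_len: int = 18, max_len: int = 25) -> bool:
    """Keep iff ``min_len <= len(seq) <= max_len`` (both inclusive)."""
    if min_len <= 0 or min_len > max_len:
        raise ValueError("size bounds must be positive with min <= max")
    return min_len <= len(seq) <= max_len


def filter_complexity(seq: str, min_distinct_bases: int = 3) -> bool:
    """Keep iff the sequence uses at least ``min_distinct_bases`` distinct
    nucleotides (drops homopolymers and two-letter repeats)."""
    return len(set(seq)) >= min_distinct_bases


class NcrnaIndex:
    """Seed-and-extend substring matcher against a non-coding RNA reference
    set (rRNA/tRNA/snRNA/snoRNA contaminants).

    Exact k-mer seeding (seed length 12, shrunk by pigeonhole to
    ``len(query) // (m + 1)`` when needed so that a query within ``m``
    mismatches of a reference window always shares an exact seed chunk),
    followed by ungapped Hamming verification.
    """

    SEED = 12

    def __init__(self, refs: Sequence[SequenceRecord], check_revcomp: bool = False):
        if not refs:
            raise ValueError("ncRNA reference set is empty")
        self.refs = [(r.id, r.sequence) for r in refs]
        if check_revcomp:
            from ._seq import revcomp

            self.refs += [(r.id + "|rc", revcomp(r.sequence)) for r in refs]
        self._indexes: dict[int, dict[str, list[tuple[int, int]]]] = {}

    def _index_for(self, k: int) -> dict[str, list[tuple[int, int]]]:
        if k not in self._indexes:
            idx: dict[str, list[tuple[int, int]]] = {}
            for ri, (_, seq) in enumerate(self.refs):
                for pos in range(len(seq) - k + 1):
                    idx.setdefault(seq[pos : pos + k], []).append((ri, pos))
            self._indexes[k] = idx
        return self._indexes[k]

    def match(self, seq: str, max_mismatches: int = 0) -> str | None:
        """Return the id of a matching reference, or None.

        A match is an occurrence of ``seq`` as an ungapped substring of a
        reference with at most ``max_mismatches`` mismatches.
        """
        m = max_mismatches
        chunk = len(seq) // (m + 1)
        if chunk < 1:
            return None
        k = min(self.SEED, chunk)
        idx = self._index_for(k)
        # one seed per pigeonhole chunk: if the query matches a reference
        # window with <= m mismatches, at least one chunk is mismatch-free.
        for c in range(m + 1):
            off = c * chunk
            seed = seq[off : off + k]
            for ri, pos in idx.get(seed, ()):
                start = pos - off
                if start < 0 or start + len(seq) > len(self.refs[ri][1]):
                    continue
                window = self.refs[ri][1][start : start + len(seq)]
                if sum(a != b for a, b in zip(seq, window)) <= m:
                    return self.refs[ri][0]
        return None


def filter_ncrna(
    seq: str,
    ncrna_refs: Sequence[SequenceRecord] | NcrnaIndex,
    max_mismatches: int = 0,
    check_revcomp: bool = False,
) -> str | None:
    """Return the matched reference id when ``seq`` should be dropped as an
    ncRNA degradation fragment, else None (keep)."""
    index = (
        ncrna_refs
        if isinstance(ncrna_refs, NcrnaIndex)
        else NcrnaIndex(ncrna_refs, check_revcomp)
    )
    return index.match(seq, max_mismatches)


@dataclass(frozen=True)
class PreprocessParams:
    min_len: int = 18
    max_len: int = 25
    min_distinct_bases: int = 3
    ncrna_max_mismatches: int = 0
    ncrna_check_revcomp: bool = False


def run_preprocess(
    raw_reads: Iterable[SequenceRecord],
    adapters: AdapterConfig | None,
    ncrna_refs: Sequence[SequenceRecord] | NcrnaIndex | None,
    params: PreprocessParams = PreprocessParams(),
    label: str = "library",
) -> SRNALibrary:
    """Full cascade: strip adapters -> size -> complexity -> ncRNA, then
    de-duplicate.  Each removed read is attributed to the first failing
    filter, which makes the per-stage statistics deterministic.

    With ``adapters=None`` the input is taken as pre-trimmed inserts and the
    artifact stage is skipped (rerunning on an already-clean library is then
    the identity on its entries)."""
    stats = LibraryStats()
    index: NcrnaIndex | None
    if ncrna_refs is None:
        index = None
    elif isinstance(ncrna_refs, NcrnaIndex):
        index = ncrna_refs
    else:
        index = NcrnaIndex(ncrna_refs, params.ncrna_check_revcomp)

    entries: Counter = Counter()
    for read in raw_reads:
        stats.raw_reads += 1
        if adapters is not None:
            res = strip_adapters(read, adapters)
            if res.is_artifact:
                stats.artifacts[res.artifact] += 1
                continue
            insert = res.insert
            assert insert is not None
        else:
            insert = normalize(
                read.sequence if isinstance(read, SequenceRecord) else read
            )
        stats.adapter_removed_reads += 1
        if "N" in insert:
            stats.removed[FILTER_CONTAINS_N] += 1
        elif not filter_size(insert, params.min_len, params.max_len):
            stats.removed[FILTER_SIZE] += 1
        elif not filter_complexity(insert, params.min_distinct_bases):
            stats.removed[FILTER_COMPLEXITY] += 1
        elif index is not None and index.match(insert, params.ncrna_max_mismatches):
            stats.removed[FILTER_NCRNA] += 1
        else:
            stats.filtered_reads += 1
            entries[insert] += 1

    stats.unique_sequences = len(entries)
    stats.check_closure()
    return SRNALibrary(label=label, entries=dict(sorted(entries.items())), stats=stats)
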