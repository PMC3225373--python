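"""Homology classification of sRNAs against a mature-miRNA reference.

A query is slid ungapped over each canonical sequence with 5'/3' overhangs of
up to three bases on either end; up to three internal mismatches are allowed
over the overlapped region (overhanging bases are tolerated, not penalized).
Matches are typed as canonical / internal-mismatch / length variants, and
star-strand reads (family labels ending in ``*``) merge into their mature
family for the roll-ups.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .io_formats import CountTableRow, SequenceRecord
from ._seq import normalize


class VariantClass(str, Enum):
    canonical = "canonical"
    internal_mismatch = "internal_mismatch"
    length_variant_5p = "length_variant_5p"
    length_variant_3p = "length_variant_3p"
    length_variant_both = "length_variant_both"


@dataclass(frozen=True)
class MiRNAMatch:
    """Best ungapped assignment of a query to a canonical mature sequence.

    Offsets are signed: positive = extension beyond the canonical end,
    negative = truncation.  ``n_internal_mismatches`` counts only the
    overlapped region.
    """

    query: str
    family: str
    reference: str
    n_internal_mismatches: int
    five_prime_offset: int
    three_prime_offset: int
    is_star: bool = False

    @property
    def total_offset(self) -> int:
        return abs(self.five_prime_offset) + abs(self.three_prime_offset)


def mature_family(label: str) -> str:
    """Star labels (``miR166*``) collapse onto their mature family."""
    return label[:-1] if label.endswith("*") else label


def match_mirna(
    seq: str,
    references: Sequence[SequenceRecord],
    max_mismatches: int = 3,
    max_overhang: int = 3,
) -> MiRNAMatch | None:
    """Best match of ``seq`` over the reference set, or None.

    Best = fewest internal mismatches, ties broken by smaller total absolute
    offset, then by lexicographically smallest family name.
    """
    if not references:
        raise ValueError("reference set is empty")
    q = normalize(seq)
    best: tuple[tuple[int, int, str, str], MiRNAMatch] | None = None
    for ref in references:
        r = ref.sequence
        family = mature_family(ref.id)
        for f in range(-max_overhang, max_overhang + 1):
            # query base i (0-based) faces reference base i - f
            t3 = len(q) - f - len(r)
            if abs(t3) > max_overhang:
                continue
            lo = max(0, f)
            hi = min(len(q), len(r) + f)
            if hi - lo <= 0:
                continue
            mm = sum(q[i] != r[i - f] for i in range(lo, hi))
            if mm > max_mismatches:
                continue
            match = MiRNAMatch(
                query=q,
                family=family,
                reference=r,
                n_internal_mismatches=mm,
                five_prime_offset=f,
                three_prime_offset=t3,
                is_star=ref.id.endswith("*"),
            )
            key = (mm, match.total_offset, family, r)
            if best is None or key < best[0]:
                best = (key, match)
    return best[1] if best else None


def classify_variant(match: MiRNAMatch) -> VariantClass:
    """Type a match; nonzero end offsets take precedence over internal
    mismatches (a length variant may additionally carry mismatches)."""
    f, t = match.five_prime_offset, match.three_prime_offset
    if f == 0 and t == 0:
        if match.n_internal_mismatches == 0:
            return VariantClass.canonical
        return VariantClass.internal_mismatch
    if f != 0 and t != 0:
        return VariantClass.length_variant_both
    return VariantClass.length_variant_5p if f != 0 else VariantClass.length_variant_3p


@dataclass
class FamilyTally:
    """Per-family roll-up: read and unique-sequence counts per library."""

    family: str
    read_count: dict[str, int]
    unique_count: dict[str, int]
    northern_only: bool = False

    @property
    def total_reads(self) -> int:
        return sum(self.read_count.values())


def tally_families(rows: Iterable[CountTableRow]) -> list[FamilyTally]:
    """Roll count-table rows up into per-family tallies, merging star-strand
    rows into their mature family; sorted by family name."""
    tallies: dict[str, FamilyTally] = {}
    for row in rows:
        if row.family is None:
            raise ValueError(f"row {row.sequence} lacks a family label")
        fam = mature_family(row.family)
        tally = tallies.setdefault(fam, FamilyTally(fam, {}, {}))
        for lib, count in row.count_per_library.items():
            tally.read_count[lib] = tally.read_count.get(lib, 0) + count
            tally.unique_count.setdefault(lib, 0)
            if count > 0:
                tally.unique_count[lib] += 1
        if row.northern_only:
            tally.northern_only = True
    return [tallies[f] for f in sorted(tallies)]


@dataclass
class KnownSummary:
    total_reads: int
    families_total: int
    families_per_library: dict[str, int]
    reads_per_library: dict[str, int]
    unique_per_library: dict[str, int]


def summarize_known(
    tallies: Sequence[FamilyTally],
    include_northern_only: bool = False,
) -> KnownSummary:
    """Overall roll-up of the known-miRNA component.

    A family counts toward existence when it has at least one sequenced read;
    northern-blot-only families (all counts zero) are included only with
    ``include_northern_only``.  Per-library family counts always require a
    sequenced read in that library.
    """
    libs = sorted({lib for t in tallies for lib in t.read_count})
    reads_per_lib = {
        lib: sum(t.read_count.get(lib, 0) for t in tallies) for lib in libs
    }
    unique_per_lib = {
        lib: sum(t.unique_count.get(lib, 0) for t in tallies) for lib in libs
    }
    fams_per_lib = {
        lib: sum(1 for t in tallies if t.read_count.get(lib, 0) > 0) for lib in libs
    }
    n_total = sum(
        1
        for t in tallies
        if t.total_reads > 0 or (include_northern_only and t.northern_only)
    )
    return KnownSummary(
        total_reads=sum(t.total_reads for t in tallies),
        families_total=n_total,
        families_per_library=fams_per_lib,
        reads_per_library=reads_per_lib,
        unique_per_library=unique_per_lib,
    )


def family_read_total(tallies: Sequence[FamilyTally], family: str) -> int:
    """Total reads of one family summed over libraries."""
    for t in tallies:
        if t.family == mature_family(family):
            return t.total_reads
    raise KeyError(f"family {family!r} not present")


def most_abundant_sequence(
    rows: Iterable[CountTableRow], family: str
) -> tuple[str, int]:
    """The family's most frequently sampled sequence and its total count."""
    fam = mature_family(family)
    best: tuple[str, int] | None = None
    for row in rows:
        if row.family is None or mature_family(row.family) != fam:
            continue
        total = row.total()
        if best is None or total > best[1]:
            best = (row.sequence, total)
    if best is None:
        raise KeyError(f"family {family!r} not present")
    return best
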