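"""Size-class and composition statistics plus read-count normalization.

Abundances are normalized as reads per thousand (rpt):
``rpt = 1000 * count / filtered_library_total``, so a whole library sums to
1000 rpt.  Display rounding follows the conventions of the source study:
size-class shares to the nearest integer percent, sub-percent classes to one
decimal, rpt to two decimals.
"""

from __future__ import annotations

from collections import Counter
from typing import Mapping

import pandas as pd

from .preprocess import SRNALibrary

RNA_BASES = ("A", "C", "G", "U")


class SizeProfile:
    """Per-length tallies for one library: total reads, unique sequences and
    their percentage shares."""

    def __init__(self, table: pd.DataFrame, label: str = ""):
        self.table = table
        self.label = label

    @classmethod
    def from_counts(
        cls,
        per_length: Mapping[int, tuple[int, int]],
        label: str = "",
    ) -> "SizeProfile":
        """Build from ``{length: (total_reads, unique_sequences)}``."""
        lengths = sorted(per_length)
        total = sum(v[0] for v in per_length.values())
        unique = sum(v[1] for v in per_length.values())
        rows = []
        for ln in lengths:
            t, u = per_length[ln]
            rows.append(
                {
                    "length": ln,
                    "total_reads": t,
                    "unique_sequences": u,
                    "pct_total": 100.0 * t / total if total else 0.0,
                    "pct_unique": 100.0 * u / unique if unique else 0.0,
                }
            )
        return cls(pd.DataFrame(rows).set_index("length"), label)

    def pct_total(self, length: int) -> float:
        return float(self.table.loc[length, "pct_total"])

    def pct_unique(self, length: int) -> float:
        return float(self.table.loc[length, "pct_unique"])

    def uniqueness(self, length: int) -> float:
        """Unique sequences as a fraction of total reads within one class."""
        row = self.table.loc[length]
        return float(row["unique_sequences"] / row["total_reads"])


def size_profile(lib: SRNALibrary) -> SizeProfile:
    """Exact integer tallies of the library by insert length."""
    if not lib.entries:
        raise ValueError(f"library {lib.label!r} is empty")
    totals: Counter = Counter()
    uniques: Counter = Counter()
    for seq, count in lib.entries.items():
        totals[len(seq)] += count
        uniques[len(seq)] += 1
    per_length = {ln: (totals[ln], uniques[ln]) for ln in totals}
    return SizeProfile.from_counts(per_length, lib.label)


def five_prime_composition(lib: SRNALibrary, length_class: int) -> dict[str, float]:
    """5'-terminal base proportions over the *unique* sequences of one size
    class (the 24-nt class of heterochromatic siRNAs is typically 5'-A
    enriched, reflecting AGO4 loading preference)."""
    seqs = [s for s in lib.entries if len(s) == length_class]
    if not seqs:
        raise ValueError(f"no sequences of length {length_class} in {lib.label!r}")
    counts = Counter(s[0] for s in seqs)
    n = len(seqs)
    return {b: counts.get(b, 0) / n for b in RNA_BASES if counts.get(b, 0)}


def normalize_rpt(count: int, library_total: int) -> float:
    """Reads per thousand: ``1000 * count / library_total``."""
    if library_total <= 0:
        raise ValueError("library total must be positive")
    return 1000.0 * count / library_total


def abundance_ratio(a_rpt: float, b_rpt: float) -> float:
    """Ratio of two normalized abundances (a/b)."""
    if b_rpt <= 0:
        raise ZeroDivisionError("denominator abundance is zero")
    return a_rpt / b_rpt


def mean_share(shares: list[float]) -> float:
    """Unweighted mean of per-library percentage shares ("on average" over
    the libraries compared)."""
    return sum(shares) / len(shares)


# -- display rounding --------------------------------------------------------

def round_share(pct: float) -> int:
    """Size-class share, nearest integer percent."""
    return int(round(pct))


def round_subpercent(pct: float) -> float:
    """Sub-percent class share, one decimal."""
    return round(pct, 1)


def round_rpt(rpt: float) -> float:
    """Normalized abundance, two decimals."""
    return round(rpt, 2)
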