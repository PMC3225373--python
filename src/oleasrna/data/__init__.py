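"""Packaged fixtures: the published per-sequence miRNA count table and
library summary statistics of the two olive shoot sRNA libraries (GEO series
GSE27093, juvenile vs adult), transcribed from the published summary tables,
plus a canonical mature-miRNA reference derived from them.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from ..io_formats import CountTableRow, SequenceRecord, read_count_table, read_fasta

__all__ = [
    "load_known_mirna_table",
    "load_mature_reference",
    "load_library_summary",
    "load_size_class_counts",
]


def _path(name: str):
    return resources.files(__package__) / name


def load_known_mirna_table() -> list[CountTableRow]:
    """Per-sequence polymorphism count table for the known-miRNA matches
    (51 species, juvenile/adult counts; star strands labelled ``family*``)."""
    with resources.as_file(_path("known_mirna_polymorphisms.tsv")) as p:
        return read_count_table(p)


def load_mature_reference() -> list[SequenceRecord]:
    """Representative canonical mature sequence per family."""
    with resources.as_file(_path("mature_reference.fa")) as p:
        return read_fasta(p)


def load_library_summary() -> pd.DataFrame:
    """Published per-library sequencing yields (raw / adapter-removed /
    filtered; total and unique), indexed by library label."""
    with resources.as_file(_path("library_summary.tsv")) as p:
        return pd.read_csv(p, sep="\t", index_col="library")


def load_size_class_counts() -> pd.DataFrame:
    """Published per-length read tallies (total and unique) for the size
    classes quoted in the study (21, 22 and 24 nt)."""
    with resources.as_file(_path("size_class_counts.tsv")) as p:
        return pd.read_csv(p, sep="\t")
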