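"""Readers and writers for every external representation the pipeline touches.

FASTA (via Biopython), TSV count tables (via pandas), YAML adapter/threshold
configs, and generic tabular reports.  All sequences are normalized to the
RNA alphabet on ingest; coordinates in reports are 1-based, fully closed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml
from Bio import SeqIO

from ._seq import normalize


class FastaParseError(ValueError):
    """Malformed FASTA; message names the offending line."""


class CountTableError(ValueError):
    """Count table row violating an invariant."""


@dataclass(frozen=True)
class SequenceRecord:
    """One FASTA record; sequence over {A,C,G,U,N} after normalization."""

    id: str
    sequence: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CountTableRow:
    """One row of a per-sequence count table.

    ``count_per_library`` maps library label -> read count.  A count cell of
    "N" in the file means the species was seen only on a northern blot; it is
    stored as 0 with ``northern_only`` set.
    """

    sequence: str
    length: int
    family: str | None
    count_per_library: Mapping[str, int]
    northern_only: bool = False

    def total(self) -> int:
        return sum(self.count_per_library.values())


@dataclass(frozen=True)
class AdapterConfig:
    """Ligation adapters used to excise the sRNA insert from a raw read.

    ``min_anchor`` is the number of leading adapter bases that must match
    exactly for the adapter to be called at a position.
    """

    three_prime: str
    five_prime_variants: tuple[str, ...]
    min_anchor: int = 10

    def __post_init__(self) -> None:
        object.__setattr__(self, "three_prime", normalize(self.three_prime))
        object.__setattr__(
            self, "five_prime_variants",
            tuple(normalize(v) for v in self.five_prime_variants),
        )
        if self.min_anchor < 6:
            raise ValueError("min_anchor must be >= 6")
        for ad in (self.three_prime, *self.five_prime_variants):
            if len(ad) < self.min_anchor:
                raise ValueError(
                    f"adapter {ad!r} shorter than min_anchor={self.min_anchor}"
                )


#: 454 library adapters: pre-adenylated 3' adapter and the two chimeric
#: 5' adapter variants, RNA-normalized.
DEFAULT_ADAPTERS = AdapterConfig(
    three_prime="CTGTAGGCACCATCAAT",
    five_prime_variants=("atcgtAGGCACCUGAUA", "atcgtAGGCCACUGAUA"),
    min_anchor=10,
)


def read_fasta(path: str | Path, as_rna: bool = True) -> list[SequenceRecord]:
    """Parse a multi-record FASTA file.

    Sequences are upper-cased; with ``as_rna`` (default) T is converted to U.
    Raises :class:`FastaParseError` naming the line number for a malformed
    header, an empty sequence, or a duplicate id.
    """
    path = Path(path)
    text = path.read_text()
    _validate_fasta_lines(text, str(path))
    records: list[SequenceRecord] = []
    seen: dict[str, int] = {}
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        seq = str(rec.seq).upper()
        if as_rna:
            seq = normalize(seq)
        if rec.id in seen:
            raise FastaParseError(f"{path}: duplicate record id {rec.id!r}")
        seen[rec.id] = 1
        desc = rec.description
        if desc == rec.id:
            desc = ""
        elif desc.startswith(rec.id + " "):
            desc = desc[len(rec.id) + 1 :]
        records.append(SequenceRecord(rec.id, seq, desc))
    return records


def _validate_fasta_lines(text: str, name: str) -> None:
    header_line = None
    body_seen = True  # no dangling header yet
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith(">"):
            if not body_seen:
                raise FastaParseError(
                    f"{name}: empty sequence for header at line {header_line}"
                )
            if stripped == ">":
                raise FastaParseError(f"{name}: malformed header at line {lineno}")
            header_line = lineno
            body_seen = False
        else:
            if header_line is None:
                raise FastaParseError(
                    f"{name}: sequence data before any header at line {lineno}"
                )
            body_seen = True
    if not body_seen:
        raise FastaParseError(f"{name}: empty sequence for header at line {header_line}")
    if header_line is None and text.strip():
        raise FastaParseError(f"{name}: no FASTA headers found")


def write_fasta(records: Sequence[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            desc = f" {rec.description}" if rec.description else ""
            fh.write(f">{rec.id}{desc}\n{rec.sequence}\n")


# -- count tables ------------------------------------------------------------

_META_COLUMNS = ("sequence", "length", "family")


def read_count_table(path: str | Path) -> list[CountTableRow]:
    """Read a TSV count table: ``sequence  length  family  <lib1> <lib2>...``

    "N" count cells (northern-blot-only species) become 0 with the
    ``northern_only`` flag set.  A row whose counts are all zero without the
    flag, or whose length column disagrees with its sequence, is an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in _META_COLUMNS[:2] if c not in df.columns]
    if missing:
        raise CountTableError(f"{path}: missing column(s) {missing}")
    libs = [c for c in df.columns if c not in _META_COLUMNS]
    if not libs:
        raise CountTableError(f"{path}: no library columns found")
    rows: list[CountTableRow] = []
    for idx, rec in df.iterrows():
        seq = normalize(rec["sequence"])
        length = int(rec["length"])
        if length != len(seq):
            raise CountTableError(
                f"{path}: row {idx + 2}: length column {length} != "
                f"sequence length {len(seq)}"
            )
        family = rec.get("family", "") or None
        northern = False
        counts: dict[str, int] = {}
        for lib in libs:
            cell = str(rec[lib]).strip()
            if cell.upper() == "N":
                counts[lib] = 0
                northern = True
            else:
                counts[lib] = int(cell or 0)
                if counts[lib] < 0:
                    raise CountTableError(f"{path}: row {idx + 2}: negative count")
        if not northern and all(v == 0 for v in counts.values()):
            raise CountTableError(
                f"{path}: row {idx + 2}: all-zero counts without northern flag"
            )
        rows.append(CountTableRow(seq, length, family, counts, northern))
    return rows


def write_count_table(rows: Sequence[CountTableRow], path: str | Path) -> None:
    libs = sorted({lib for r in rows for lib in r.count_per_library})
    data = []
    for r in rows:
        rec: dict[str, object] = {
            "sequence": r.sequence,
            "length": r.length,
            "family": r.family or "",
        }
        for lib in libs:
            count = r.count_per_library.get(lib, 0)
            rec[lib] = "N" if (r.northern_only and count == 0) else count
        data.append(rec)
    pd.DataFrame(data, columns=[*_META_COLUMNS, *libs]).to_csv(
        path, sep="\t", index=False
    )


# -- generic tabular reports -------------------------------------------------

def write_report(table: pd.DataFrame, path: str | Path) -> None:
    """Write a tabular report as TSV with a deterministic column order."""
    table.to_csv(path, sep="\t", index=False)


def read_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# -- configs -----------------------------------------------------------------

def load_adapter_config(path: str | Path) -> AdapterConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return AdapterConfig(
        three_prime=raw["three_prime"],
        five_prime_variants=tuple(raw["five_prime_variants"]),
        min_anchor=int(raw.get("min_anchor", 10)),
    )


def dump_adapter_config(config: AdapterConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {
                "three_prime": config.three_prime,
                "five_prime_variants": list(config.five_prime_variants),
                "min_anchor": config.min_anchor,
            },
            fh,
        )
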