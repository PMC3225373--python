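"""Seeded synthetic inputs with the statistical structure the analysis
assumes, so every downstream stage is testable without downloads.

The population generator emulates the structure of the deposited olive shoot
libraries (GEO series GSE27093): two libraries (juvenile/adult), a 24-nt
dominated size distribution with a 5'-adenosine bias in that class, ncRNA
degradation contamination including >25-nt fragments, a low-count
conserved-miRNA variant block, plus dedicated locus builders for hairpin
precursors, a TAS3 transcript with dual miR390 sites and tasiARFs at phases
7-8, and ARF transcripts with two tasiARF sites.

One integer seed drives everything; sub-generators derive child streams
deterministically, so a fixed seed gives byte-identical outputs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from ._seq import RNA_BASES, normalize, revcomp
from .io_formats import AdapterConfig, CountTableRow, SequenceRecord
from .preprocess import (
    FILTER_COMPLEXITY,
    FILTER_NCRNA,
    FILTER_SIZE,
)
from .target_prediction import TargetSite
from .tasirna_phasing import cleavage_point

#: canonical sequences sampled in the libraries, reused as planting material
MIR159 = "UUUGGAUUGAAGGGAGCUCUA"
MIR390 = "AAGCUCAGGAGGGAUAGCGCC"

#: size distribution of the filtered sRNA component: 24-nt dominant (~80%),
#: 23/25-nt shoulders (96% in 23-25), 21-nt ~0.8% and 22-nt ~1.3%
DEFAULT_SIZE_DISTRIBUTION = {
    18: 0.006,
    19: 0.006,
    20: 0.007,
    21: 0.008,
    22: 0.013,
    23: 0.08,
    24: 0.80,
    25: 0.08,
}

CATEGORY_CLEAN = "clean"
CATEGORY_MIRNA = "mirna"
CATEGORY_NCRNA = "ncrna"
CATEGORY_LOW_COMPLEXITY = "low_complexity"


@dataclass(frozen=True)
class VariantSpec:
    """One planted miRNA variant: kind, magnitude and per-library counts."""

    kind: str  # mismatch | ext5 | ext3 | trunc5 | trunc3
    magnitude: int
    counts: dict[str, int]


@dataclass(frozen=True)
class PlantedMiRNA:
    canonical: str
    family: str
    counts: dict[str, int]
    variants: tuple[VariantSpec, ...] = ()


def _default_mir159_block() -> PlantedMiRNA:
    """Variant spectrum mirroring the sampled miR159 family block: a
    dominant canonical, a handful of internal-mismatch singletons and
    several 5'/3' length variants, almost all juvenile-specific."""
    j = "juvenile"
    return PlantedMiRNA(
        canonical=MIR159,
        family="miR159",
        counts={"juvenile": 109, "adult": 4},
        variants=(
            VariantSpec("mismatch", 1, {j: 1}),
            VariantSpec("mismatch", 1, {j: 1}),
            VariantSpec("mismatch", 1, {j: 1}),
            VariantSpec("mismatch", 1, {j: 2}),
            VariantSpec("ext5", 1, {j: 1}),
            VariantSpec("ext3", 1, {j: 1}),
            VariantSpec("trunc3", 1, {j: 4}),
            VariantSpec("trunc5", 1, {j: 3}),
            VariantSpec("trunc3", 3, {j: 8}),
        ),
    )


@dataclass(frozen=True)
class PopulationConfig:
    seed: int = 0
    library_labels: tuple[str, ...] = ("juvenile", "adult")
    n_reads_per_library: int = 10_000
    size_distribution: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_SIZE_DISTRIBUTION)
    )
    frac_ncrna_fragments: float = 0.35
    frac_adapter_artifacts: float = 0.02
    frac_low_complexity: float = 0.01
    five_prime_A_bias_24nt: float = 0.60
    planted_mirnas: tuple[PlantedMiRNA, ...] = field(
        default_factory=lambda: (_default_mir159_block(),)
    )

    def __post_init__(self) -> None:
        total = sum(self.size_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"size distribution sums to {total}, not 1")
        for name in (
            "frac_ncrna_fragments",
            "frac_adapter_artifacts",
            "frac_low_complexity",
            "five_prime_A_bias_24nt",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass(frozen=True)
class ReadTruth:
    """One insert-level read with its planted provenance."""

    sequence: str
    category: str
    family: str | None = None


@dataclass
class PopulationResult:
    config: PopulationConfig
    libraries: dict[str, list[ReadTruth]]
    ncrna_refs: list[SequenceRecord]
    count_table: list[CountTableRow]

    def expected_stats(self, label: str) -> dict:
        """Ground-truth filter accounting for one library, applying the
        cascade's first-failing-filter attribution to the planted labels."""
        removed: Counter = Counter()
        kept: Counter = Counter()
        for read in self.libraries[label]:
            n = len(read.sequence)
            if n < 18 or n > 25:
                removed[FILTER_SIZE] += 1
            elif len(set(read.sequence)) < 3:
                removed[FILTER_COMPLEXITY] += 1
            elif read.category == CATEGORY_NCRNA:
                removed[FILTER_NCRNA] += 1
            else:
                kept[read.sequence] += 1
        return {
            "n_inserts": len(self.libraries[label]),
            "removed": dict(removed),
            "filtered_reads": sum(kept.values()),
            "unique_sequences": len(kept),
        }


def _rng(seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng([seed, *stream])


def _rand_seq(rng: np.random.Generator, length: int, first: str | None = None) -> str:
    idx = rng.integers(0, 4, size=length)
    s = "".join(RNA_BASES[i] for i in idx)
    if first is not None:
        s = first + s[1:]
    return s


def generate_ncrna_references(seed: int) -> list[SequenceRecord]:
    """Synthetic stand-ins for the abundant structural ncRNAs (rRNA, tRNA,
    snRNA, snoRNA) whose degradation products contaminate sRNA libraries."""
    rng = _rng(seed, 1)
    specs = [("rRNA-18S-like", 700), ("rRNA-26S-like", 900),
             ("tRNA-like", 80), ("snoRNA-like", 150)]
    return [SequenceRecord(name, _rand_seq(rng, n)) for name, n in specs]


def _variant_sequence(
    canonical: str, spec: VariantSpec, rng: np.random.Generator, taken: set[str]
) -> str:
    for _ in range(100):
        if spec.kind == "mismatch":
            pos = int(rng.integers(1, len(canonical) - 1))
            base = canonical[pos]
            alt = RNA_BASES[int(rng.integers(0, 4))]
            if alt == base:
                continue
            seq = canonical[:pos] + alt + canonical[pos + 1 :]
        elif spec.kind == "ext5":
            seq = _rand_seq(rng, spec.magnitude) + canonical
        elif spec.kind == "ext3":
            seq = canonical + _rand_seq(rng, spec.magnitude)
        elif spec.kind == "trunc5":
            seq = canonical[spec.magnitude :]
        elif spec.kind == "trunc3":
            seq = canonical[: -spec.magnitude]
        else:
            raise ValueError(f"unknown variant kind {spec.kind!r}")
        if seq not in taken:
            return seq
    raise RuntimeError("could not generate a distinct variant sequence")


def generate_population(config: PopulationConfig) -> PopulationResult:
    """Insert-level libraries plus ground truth.

    Clean background reads are rejection-sampled so that they pass every
    filter (>=3 distinct bases, no ncRNA reference match, no collision with
    a planted miRNA species): the expected filter accounting is then exact,
    not merely probable.
    """
    if config.n_reads_per_library < 1:
        raise ValueError("n_reads_per_library must be >= 1")
    ncrna_refs = generate_ncrna_references(config.seed)
    from .preprocess import NcrnaIndex

    index = NcrnaIndex(ncrna_refs)

    # planted miRNA species (shared across libraries)
    vrng = _rng(config.seed, 2)
    planted_rows: list[CountTableRow] = []
    planted_seqs: set[str] = set()
    for planted in config.planted_mirnas:
        canonical = normalize(planted.canonical)
        planted_seqs.add(canonical)
        planted_rows.append(
            CountTableRow(
                canonical, len(canonical), planted.family, dict(planted.counts)
            )
        )
        for spec in planted.variants:
            seq = _variant_sequence(canonical, spec, vrng, planted_seqs)
            planted_seqs.add(seq)
            planted_rows.append(
                CountTableRow(seq, len(seq), planted.family, dict(spec.counts))
            )

    lengths = sorted(config.size_distribution)
    probs = np.array([config.size_distribution[ln] for ln in lengths])
    probs = probs / probs.sum()

    libraries: dict[str, list[ReadTruth]] = {}
    for li, label in enumerate(config.library_labels):
        rng = _rng(config.seed, 3, li)
        reads: list[ReadTruth] = []
        # planted miRNA reads at their exact configured abundances
        for row in planted_rows:
            for _ in range(row.count_per_library.get(label, 0)):
                reads.append(ReadTruth(row.sequence, CATEGORY_MIRNA, row.family))
        n_planted = len(reads)
        n_rest = config.n_reads_per_library - n_planted
        if n_rest < 0:
            raise ValueError("planted miRNA counts exceed n_reads_per_library")
        n_ncrna = int(rng.binomial(n_rest, config.frac_ncrna_fragments))
        n_lowc = int(rng.binomial(n_rest - n_ncrna, config.frac_low_complexity))
        n_clean = n_rest - n_ncrna - n_lowc

        for _ in range(n_ncrna):
            ref = ncrna_refs[int(rng.integers(0, len(ncrna_refs)))]
            ln = int(rng.integers(18, 31))  # degradation incl. >25-nt pieces
            start = int(rng.integers(0, len(ref.sequence) - ln + 1))
            reads.append(
                ReadTruth(ref.sequence[start : start + ln], CATEGORY_NCRNA)
            )
        for _ in range(n_lowc):
            ln = int(rng.integers(18, 26))
            two = rng.choice(len(RNA_BASES), size=2, replace=False)
            pattern = RNA_BASES[two[0]] + RNA_BASES[two[1]]
            reads.append(
                ReadTruth((pattern * ln)[:ln], CATEGORY_LOW_COMPLEXITY)
            )
        for _ in range(n_clean):
            ln = int(lengths[int(rng.choice(len(lengths), p=probs))])
            while True:
                first = None
                if ln == 24:
                    if rng.random() < config.five_prime_A_bias_24nt:
                        first = "A"
                    else:
                        first = "CGU"[int(rng.integers(0, 3))]
                seq = _rand_seq(rng, ln, first)
                if len(set(seq)) < 3:
                    continue
                if seq in planted_seqs:
                    continue
                if index.match(seq, 0):
                    continue
                break
            reads.append(ReadTruth(seq, CATEGORY_CLEAN))
        # shuffle read order; accounting is order-independent anyway
        order = rng.permutation(len(reads))
        libraries[label] = [reads[i] for i in order]

    return PopulationResult(config, libraries, ncrna_refs, planted_rows)


@dataclass
class RawReadTruth:
    records: list[SequenceRecord]
    n_no_insert: int
    n_multimer: int

    @property
    def n_artifacts(self) -> int:
        return self.n_no_insert + self.n_multimer


def generate_raw_reads(
    inserts: list[ReadTruth] | list[str],
    adapters: AdapterConfig,
    seed: int = 0,
    frac_artifacts: float = 0.02,
) -> RawReadTruth:
    """Adapter-flanked raw reads: ``5'adapter + insert + 3'adapter``, with a
    configured fraction of ligation artifacts (adapter dimers without an
    insert, and double-3'-adapter multimers)."""
    rng = _rng(seed, 4)
    seqs = [
        r.sequence if isinstance(r, ReadTruth) else normalize(r) for r in inserts
    ]
    n_art = int(rng.binomial(len(seqs), frac_artifacts)) if seqs else 0
    n_no_insert = n_art // 2
    n_multimer = n_art - n_no_insert
    reads: list[str] = []
    for seq in seqs:
        five = adapters.five_prime_variants[
            int(rng.integers(0, len(adapters.five_prime_variants)))
        ]
        reads.append(five + seq + adapters.three_prime)
    for _ in range(n_no_insert):
        five = adapters.five_prime_variants[
            int(rng.integers(0, len(adapters.five_prime_variants)))
        ]
        reads.append(five + adapters.three_prime)
    for _ in range(n_multimer):
        five = adapters.five_prime_variants[
            int(rng.integers(0, len(adapters.five_prime_variants)))
        ]
        filler = _rand_seq(rng, 21)
        reads.append(five + filler + adapters.three_prime + adapters.three_prime)
    order = rng.permutation(len(reads))
    records = [
        SequenceRecord(f"read{idx:06d}", reads[i]) for idx, i in enumerate(order)
    ]
    return RawReadTruth(records, n_no_insert, n_multimer)


# -- planted loci ------------------------------------------------------------

@dataclass
class PlantedLocus:
    kind: str
    transcript: SequenceRecord
    truth: dict


def _mutate(seq: str, pos0: int, rng: np.random.Generator) -> str:
    """Substitute the base at 0-based ``pos0`` with a different one."""
    alternatives = [b for b in RNA_BASES if b != seq[pos0]]
    alt = alternatives[int(rng.integers(0, 3))]
    return seq[:pos0] + alt + seq[pos0 + 1 :]


def _site_with_mispairs(
    mirna: str, mispair_positions: tuple[int, ...], rng: np.random.Generator
) -> str:
    """Reverse-complement site for ``mirna`` with mismatches planted at the
    given miRNA positions (1-based from the miRNA 5' end)."""
    site = revcomp(mirna)
    L = len(mirna)
    for p in mispair_positions:
        site = _mutate(site, L - p, rng)  # target base opposite miRNA pos p
    return site


def generate_tas3_locus(
    seed: int,
    mir390: str = MIR390,
    tasiarf_ref: SequenceRecord | None = None,
    in_register: bool = True,
    tasiarf_shift: int = 0,
    omit_five_prime_site: bool = False,
    d7_mismatches: int = 0,
    d8_mismatches: int = 1,
) -> PlantedLocus:
    """A synthetic TAS3 transcript with the two-hit architecture.

    A perfect miR390 site near the 3' end sets the phase register; counting
    21-nt phases from its cleavage point toward the mispairing-tolerant 5'
    site, tasiARF windows are written at phases D7 (``d7_mismatches`` vs the
    reference) and D8 (``d8_mismatches``).  ``in_register`` controls whether
    the two cleavage points are a multiple of 21 nt apart;
    ``tasiarf_shift`` displaces the tasiARF windows off the register, and
    ``omit_five_prime_site`` produces the scrambled single-site control.
    """
    mir390 = normalize(mir390)
    if not 20 <= len(mir390) <= 21:
        raise ValueError("miR390 must be 20-21 nt")
    rng = _rng(seed, 5)
    if tasiarf_ref is None:
        tasiarf_ref = SequenceRecord(
            "tasiARF-ref", _rand_seq(rng, 21), "synthetic tasiARF reference"
        )
    ref = normalize(tasiarf_ref.sequence)
    L = len(mir390)

    flank5, flank3 = 60, 40
    site5_start = flank5 + 1
    site5_end = site5_start + L - 1
    a5 = site5_end - 10
    shift = 0 if in_register else 3
    a3 = a5 + 9 * 21 + shift
    site3_end = a3 + 10
    site3_start = site3_end - L + 1
    n = site3_end + flank3
    # phases toward the 5' site: Dk = [a3 - 21k + 1, a3 - 21(k-1)]
    d7 = (a3 - 7 * 21 + 1 + tasiarf_shift, a3 - 6 * 21 + tasiarf_shift)
    d8 = (a3 - 8 * 21 + 1 + tasiarf_shift, a3 - 7 * 21 + tasiarf_shift)
    if d8[0] <= site5_end:
        raise ValueError("transcript too short to hold 8 phases past the 5' site")

    seq = list(_rand_seq(rng, n))

    def _write(start1: int, fragment: str) -> None:
        seq[start1 - 1 : start1 - 1 + len(fragment)] = fragment

    if not omit_five_prime_site:
        _write(site5_start, _site_with_mispairs(mir390, (15, 17), rng))
    d7_seq, d8_seq = ref, ref
    for _ in range(d7_mismatches):
        d7_seq = _mutate(d7_seq, int(rng.integers(2, 19)), rng)
    for _ in range(d8_mismatches):
        d8_seq = _mutate(d8_seq, int(rng.integers(2, 19)), rng)
    _write(d8[0], d8_seq)
    _write(d7[0], d7_seq)
    _write(site3_start, revcomp(mir390))

    transcript = SequenceRecord(f"TAS3-synthetic-{seed}", "".join(seq))
    truth = {
        "mir390": mir390,
        "tasiarf_ref": SequenceRecord(tasiarf_ref.id, ref, tasiarf_ref.description),
        "site5": None if omit_five_prime_site else (site5_start, site5_end),
        "site3": (site3_start, site3_end),
        "anchor3": a3,
        "d7": d7,
        "d8": d8,
        "d7_mismatches": d7_mismatches,
        "d8_mismatches": d8_mismatches,
        "in_register": in_register,
        "tasiarf_shift": tasiarf_shift,
    }
    return PlantedLocus("TAS3", transcript, truth)


def generate_arf_locus(
    seed: int, tasiarf_ref: SequenceRecord, spacer: int = 90
) -> PlantedLocus:
    """An ARF-like mRNA carrying two tasiARF-complementary sites (one
    perfect, one with a single 3'-region mispair), the conserved layout of
    ARF3/ARF4 transcripts."""
    rng = _rng(seed, 6)
    ref = normalize(tasiarf_ref.sequence)
    site_a = revcomp(ref)
    site_b = _site_with_mispairs(ref, (16,), rng)
    flank = 50
    seq = list(_rand_seq(rng, flank + 21 + spacer + 21 + flank))
    a_start = flank + 1
    b_start = flank + 21 + spacer + 1
    seq[a_start - 1 : a_start + 20] = site_a
    seq[b_start - 1 : b_start + 20] = site_b
    transcript = SequenceRecord(f"ARF-synthetic-{seed}", "".join(seq))
    truth = {
        "tasiarf_ref": ref,
        "site_a": (a_start, a_start + 20),
        "site_b": (b_start, b_start + 20),
    }
    return PlantedLocus("ARF", transcript, truth)


def generate_hairpin_transcript(
    mirna: str,
    seed: int,
    flank_min: int = 50,
    flank_max: int = 200,
    star_mismatches: int = 2,
    loop_length: int = 9,
    lower_stem: int = 12,
    upper_stem: int = 4,
    span_loop: bool = False,
) -> PlantedLocus:
    """A transcript embedding a miRNA/miRNA* stem-loop in random flanks.

    The construct mirrors real precursor geometry: the miRNA/star duplex
    sits inside a longer hairpin, anchored by a perfectly complementary
    ``lower_stem`` below the duplex and a short ``upper_stem`` between the
    duplex and the terminal loop — without these anchors the pairing
    register of an imperfect duplex can slip under folding, which would
    break the correspondence between planted and folded coordinates.  The
    star arm is the reverse complement of the miRNA with
    ``star_mismatches`` substitutions placed opposite A/C miRNA bases,
    kept well separated so that the imperfections fold as small internal
    loops rather than merging.  With ``span_loop`` the recorded "miRNA"
    instead straddles the terminal loop (a deliberate criteria violation).
    """
    mirna = normalize(mirna)
    if not 20 <= len(mirna) <= 24:
        raise ValueError("miRNA must be 20-24 nt")
    rng = _rng(seed, 7)
    loop = "".join("AC"[int(rng.integers(0, 2))] for _ in range(loop_length))
    n5 = int(rng.integers(flank_min, flank_max + 1))
    n3 = int(rng.integers(flank_min, flank_max + 1))
    flank5, flank3 = _rand_seq(rng, n5), _rand_seq(rng, n3)

    if span_loop:
        stem = _rand_seq(rng, 15)
        core = stem + loop + revcomp(stem)
        # recorded sRNA crosses the terminal loop by construction
        srna_off = 15 - 8  # 8 stem bases + loop + remainder from the 3' arm
        srna = core[srna_off : srna_off + len(mirna)]
        transcript_seq = flank5 + core + flank3
        mir_start = n5 + srna_off + 1
        truth = {
            "mirna": srna,
            "mirna_span": (mir_start, mir_start + len(mirna) - 1),
            "star_span": None,
            "loop_span": (n5 + 16, n5 + 15 + loop_length),
            "compliant": False,
        }
        return PlantedLocus(
            "hairpin", SequenceRecord(f"hp-synthetic-{seed}", transcript_seq), truth
        )

    star = revcomp(mirna)
    L = len(mirna)
    # mutate star bases opposite A/C miRNA bases, keeping mutations apart
    preferred = [p for p in range(4, L - 3) if mirna[p] in "AC"]
    others = [p for p in range(4, L - 3) if p not in preferred]
    rng.shuffle(preferred)
    rng.shuffle(others)
    # wide separation first: imperfections close together merge into one
    # large internal loop under thermodynamic folding, which would make the
    # construct non-compliant with the duplex criteria it is meant to satisfy
    chosen: list[int] = []
    for min_sep in (6, 4, 3, 2, 1):
        for p in preferred + others:
            if len(chosen) >= star_mismatches:
                break
            if p not in chosen and all(abs(p - q) >= min_sep for q in chosen):
                chosen.append(p)
    for p in chosen:
        star = _mutate(star, L - 1 - p, rng)

    low5 = _rand_seq(rng, lower_stem)
    up5 = _rand_seq(rng, upper_stem)
    transcript_seq = (
        flank5 + low5 + mirna + up5 + loop + revcomp(up5) + star
        + revcomp(low5) + flank3
    )
    mir_start = n5 + lower_stem + 1
    loop_start = mir_start + L + upper_stem
    star_start = loop_start + loop_length + upper_stem
    truth = {
        "mirna": mirna,
        "mirna_span": (mir_start, mir_start + L - 1),
        "star_span": (star_start, star_start + L - 1),
        "loop_span": (loop_start, loop_start + loop_length - 1),
        "star_mismatch_mirna_positions": sorted(p + 1 for p in chosen),
        "compliant": True,
    }
    return PlantedLocus(
        "hairpin", SequenceRecord(f"hp-synthetic-{seed}", transcript_seq), truth
    )


def generate_race_clones(
    transcript: SequenceRecord,
    site: TargetSite,
    n_clones: int,
    noise: float = 0.0,
    seed: int = 0,
    clone_length: int | None = None,
) -> list[SequenceRecord]:
    """5'-RACE clone sequences for a cleaved target.

    Clones start at the first nucleotide of the 3' cleavage fragment
    (opposite the miRNA 10/11 boundary); a ``noise`` fraction start at
    off-positions within +-3 nt, emulating minority degradation ends.
    """
    if n_clones < 1:
        raise ValueError("need at least one clone")
    rng = _rng(seed, 8)
    start = cleavage_point(site) + 1  # first nucleotide past the cut
    clones = []
    for i in range(n_clones):
        pos = start
        if noise > 0 and rng.random() < noise:
            offsets = [-3, -2, -1, 1, 2, 3]
            pos = start + offsets[int(rng.integers(0, 6))]
        end = len(transcript.sequence)
        if clone_length is not None:
            end = min(end, pos - 1 + clone_length)
        clones.append(
            SequenceRecord(f"clone{i:03d}", transcript.sequence[pos - 1 : end])
        )
    return clones
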