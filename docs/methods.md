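# Methods

This note documents the models, conventions and numerical choices behind
`oleasrna`, and what the synthetic-data tests do and do not demonstrate.

## Preprocessing model

A raw 454-style read is `5′adapter + insert + 3′adapter`. Adapter calls
require an exact match on the first `min_anchor` bases (default 10) and at
most one mismatch over the remainder; the 3′ adapter may be truncated by
the read end. Reads are classified rather than errored: `no_insert`
(adapters abutting — empty ligation construct), `multimer` (more than one
copy of an adapter), `unrecognized` (either adapter missing). Surviving
inserts then pass through, in order: N-content, size (18–25 nt inclusive,
the DCL product range), complexity (at least 3 distinct nucleotides), and
ncRNA homology. Each removed read is attributed to the *first* failing
filter, which makes the per-stage statistics deterministic and the
accounting identity `adapter_removed = filtered + Σ removals` exact. The
final set is de-duplicated into sequence → count entries; all statistics
are order-independent.

The ncRNA filter is a deterministic seed-and-extend matcher (exact k-mer
seed, default length 12, ungapped Hamming verification) rather than a
BLAST call: the contract — "occurs as a substring of a reference with ≤ m
mismatches" — is exact and testable against brute force. When a query is
too short to guarantee a 12-mer seed under m mismatches, the seed shrinks
to `len(query) // (m + 1)` (pigeonhole), so no true match can be missed.

## Profiling conventions

Normalized abundance is reads per thousand, `rpt = 1000·c/N` with `N` the
filtered total of the sequence's own library; a library's rpt values sum
to 1000 by construction. Display rounding follows the source study's
precision: size-class shares to the nearest integer percent, sub-percent
classes to one decimal, rpt to two decimals. "Average" shares across
libraries are unweighted means of per-library percentages. 5′-base
composition is computed over *unique* sequences of a size class, the
convention under which the 24-nt class of heterochromatic siRNAs shows its
~60 % adenosine bias (AGO4 loading preference).

One published value is deliberately not reproduced: the juvenile miR159
abundance printed as 1.15 rpt is not derivable from any published
count/denominator pair (113/105,794 = 1.07; 132/105,794 = 1.25), so only
the adult value (4/63,905 = 0.06 rpt) is recomputed. Similarly, the
published adult adapter-removed count appears as 280,927 in the summary
table but 280,959 in the running text; the fixture carries the table
value.

## miRNA homology and variant taxonomy

A query is slid ungapped across each canonical mature sequence with a
5′ offset `f ∈ [−3, +3]`; the 3′ offset follows as
`t = len(q) − f − len(ref)` and is likewise bounded by ±3. Positive
offsets are extensions beyond the canonical end, negative are truncations.
Mismatches are counted only over the overlapped region — overhanging
bases are tolerated, not penalized — and at most 3 are allowed. The best
match minimizes (mismatches, |f| + |t|, family name, reference sequence),
in that order, making ties deterministic. Variant classes: canonical
(identical), internal mismatch (offsets zero), or length variant (any
nonzero offset, with side; a length variant may additionally carry
mismatches). Star-strand references are labelled `family*` and merge into
the mature family in all roll-ups, so merging can only increase a
family's totals.

With a single canonical per family, distant family members can exceed the
3-mismatch tolerance: on the packaged fixture, 50 of 51 species re-match
(one divergent miR482 member does not). Roll-ups of the fixture itself use
its curated family labels and reproduce the published tallies exactly
(204/44 juvenile, 22/15 adult, 226 reads, 18/17/11 families, miR159
136/113).

## Folding backends and hairpin criteria

Two backends share the `fold(sequence) → (structure, energy_score)`
contract, lower score = more stable:

- **maxpair** — dynamic programming maximizing total pair weight (GC=3,
  AU=2, GU=1), hairpin loops ≥3 nt, no pseudoknots; `energy_score` is the
  negated weight (a perfect 20-bp GC hairpin scores −60). The fill is
  numba-compiled; the traceback resolves ties deterministically
  (unpaired-first). It is verified against exhaustive structure
  enumeration for short sequences.
- **vienna** — ViennaRNA minimum free energy, kcal/mol.

Hairpin *verdicts* use the thermodynamic backend by default. The reason is
structural, not cosmetic: on natural-composition windows the max-pairing
optimum is massively degenerate, so which partners the candidate sRNA
receives is an artifact of tie-breaking — under that backend "the planted
duplex" is not a well-defined property of the locus. MFE folding resolves
the degeneracy physically; planted-hairpin recovery is then deterministic.
The maxpair backend remains available (`HairpinCriteria(backend=
"maxpair")`) and fully tested as a self-contained primitive.

Criteria, evaluated cheapest first with optional short-circuit:
(i) the sRNA lies in a single stem arm and does not touch the terminal
loop; (ii) at most 4 sRNA bases unpaired against the star arm;
(iii) largest asymmetric bulge in the duplex ≤ 2 nt; (iv) the window folds
below the mean energy of 100 dinucleotide-shuffled versions of itself
(Altschul–Erickson sampling, fixed seed 2011, strict inequality). A
shuffle null is used instead of an absolute energy cutoff so the criterion
is meaningful in both backends' units. Candidate evaluation follows the
usual annotation procedure of trying flanks of 50, 100, 150 and 200 nt
(then the whole transcript) and accepting the first window that satisfies
the criteria.

The star is reported even when unsequenced, using the DCL duplex geometry:
the star spans the partners of the paired sRNA bases shifted by +2 toward
the 3′ side (the 2-nt 3′-overhang convention).

## Target scoring

Alignments are antiparallel: miRNA position `k` (1-based from the 5′ end)
faces target position `site_end − k + 1`. Penalties — mismatch 1.0, G:U
wobble 0.5, gap 2.0 — are multiplied by a positional weight of 2 over the
5′/central core (miRNA positions 2–13) and 1 elsewhere, and summed. A
perfect complement scores 0; without gaps every score is a multiple of
0.5. Site discovery scans every transcript window (with at most one gap by
default, enumerated explicitly on either strand of the alignment) and
reports non-overlapping sites under the cutoff, best score first, ties to
the leftmost start. The default cutoff is 3.5; miR390/TAS3 site detection
uses 4.0 because functional 5′ miR390 sites tolerate extra mispairing.

## Cleavage and phasing coordinates

All coordinates are 1-based, fully closed. AGO-guided slicing cuts the
target between the nucleotides paired to miRNA positions 10 and 11; with
the registration above that phosphodiester boundary lies between transcript
positions `site_end − 10` and `site_end − 9`. `cleavage_point` returns
`site_end − 10` (the last nucleotide of the 5′ fragment), a RACE clone of
the 3′ fragment therefore starts at `site_end − 9`, and its duplex label
is "10/11". Ends outside the site are reported as "upstream/downstream n
nt". Dominance is summarized as the clone fraction `x/N`.

The TAS3 phase register is anchored at the 3′ miR390 site's cleavage
boundary and counted toward the 5′ site in consecutive 21-nt windows:
`Dk = [anchor − 21k + 1, anchor − 21(k−1)]`. Because the literature's
`5′D7(+)` nomenclature is counted from either site depending on the
source, the anchor site is configurable (`anchor_site="5p"` counts from
the 5′-site cut toward the 3′ end). The architecture verdict is `full`
only when dual sites flank two adjacent in-register tasiARF windows,
`partial` when tasiARFs are found but the dual-site architecture cannot be
mapped (e.g. a truncated contig), and `fail` otherwise — so removing a
site can never upgrade a verdict.

## Synthetic-data generator

One integer seed drives everything through deterministic child streams;
fixed seed ⇒ byte-identical output. The population emulates the structure
of the study's two shoot libraries: per-library default 10,000 inserts;
clean-read size distribution with 80 % mass at 24 nt, 8 % at 23 and 25 nt,
1.3 % at 22, 0.8 % at 21 and the remainder at 18–20 (transcribed from the
published size profile); 60 % 5′-A bias in the 24-nt class; 35 % ncRNA
degradation fragments (18–30 nt, so some fall to the size filter) drawn
from synthetic ncRNA references; 1 % low-complexity reads; 2 % adapter
artifacts at the raw-read stage; and a planted miR159-like variant block —
canonical at 109/4 reads (juvenile/adult) with four internal-mismatch and
five length variants at single-digit counts — mirroring the published
family profile. Clean background reads are rejection-sampled to pass every
filter and to avoid colliding with planted species, which is what makes
the expected filter accounting *exact* rather than probable.

Planted loci: the TAS3 construct places a perfect 3′ miR390 site, a
mispairing-tolerant 5′ site nine phases upstream (register spacing
configurable mod 21), and tasiARF windows exactly at D7 (0 mismatches vs
the synthetic tasiARF reference) and D8 (1 mismatch). The hairpin
construct embeds the miRNA/star duplex inside a longer hairpin — a 12-bp
perfectly complementary lower stem and a 4-bp upper stem between duplex
and terminal loop — matching real precursor geometry; without these
anchors the pairing register of an imperfect duplex can slip under MFE
folding and the planted coordinates would not describe the folded
structure. Star imperfections are planted opposite A/C miRNA bases with
wide separation (≥6 nt preferred) so they fold as small internal loops.
tasiARF reference sequences are generated synthetically rather than
transcribed from figures.

What the generator does **not** emulate: 454 homopolymer errors and
quality scores, genomic multi-locus structure, realistic ncRNA secondary
structure, expression dispersion between biological replicates, and
sequence composition of real transcripts (backgrounds are i.i.d.
uniform). Passing the planted-recovery tests therefore demonstrates
correctness of the algorithms under the stated statistical structure, not
performance on real libraries.

## Problem sizes and runtime choices

The test suite and acceptance script run at desk scale: 2 × 10,000-read
synthetic populations for preprocess accounting; 20 planted plus 100
random windows (~150 nt each, 100-fold shuffle nulls) for hairpin rates;
50 seeded TAS3 loci; 16–24 RACE clones. The brute-force oracles run at
deliberately tiny sizes (folding enumeration ≤ 16 nt, homology oracle on
the 21-reference set, exhaustive site enumeration on ≤ 500-nt
transcripts).

## Known limitations

- Homology classification depends on the supplied canonical set; a single
  canonical per family under-calls divergent family members (see above).
- The gapped site scan enumerates at most one gap; multi-gap sites are out
  of scope, consistent with the near-contiguous geometry of plant sites.
- The hairpin shuffle null uses 100 shuffles; the criterion compares
  against the null mean, not a tail quantile, so it is a stability filter
  rather than a significance test.
- Phase assignment requires exact 21-nt registers; biological registers
  blurred by 1–2 nt (imprecise dicing) are reported as off-register
  offsets, not probabilistically rescued.
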