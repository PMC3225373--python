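# oleasrna

Small-RNA annotation pipeline for plants with little or no genome resource,
modelled on a 454-era survey of the olive (*Olea europaea*) small-RNA
transcriptome (GEO series GSE27093, juvenile vs adult shoots).

Plant small RNAs (sRNAs) of 18–25 nt silence genes and transposons; the
miRNA class guides endonucleolytic cleavage of target mRNAs, while 24-nt
heterochromatic siRNAs (5′-A biased, AGO4-loaded) dominate large genomes.
In a non-model species none of this can be read off a genome: annotation
has to proceed from the reads themselves plus a cDNA collection. The
package implements that workflow end to end, and ships a seeded synthetic
population generator so every stage is testable offline against planted
ground truth.

## What it computes

- **Preprocessing** (`preprocess`): adapter excision from raw 454-style
  reads (empty-construct and multimer artifacts classified, not errored),
  then a filter cascade — size (18–25 nt), complexity (≥3 distinct bases),
  ncRNA homology (seed-and-extend, seed 12) — with accounting that closes
  exactly: `adapter_removed = filtered + Σ removals`.
- **Profiling** (`profiling`): size-class tallies (total vs unique),
  5′-nucleotide composition per class, and reads-per-thousand
  normalization, `rpt = 1000 · c / N` for a sequence sampled `c` times in a
  library of `N` filtered reads.
- **miRNA homology** (`mirna_annotation`): ungapped sliding alignment of
  each sRNA against canonical mature sequences, allowing up to 3 internal
  mismatches and 5′/3′ overhangs up to 3 nt; variants typed as canonical,
  internal-mismatch, or 5′/3′ length variants; star strands merged into
  their mature family in the roll-ups.
- **Hairpin precursors** (`hairpin_prediction`): 50–200 nt windows around
  an sRNA are folded and screened with stem-loop criteria (sRNA in one arm,
  ≤4 unpaired bases against the star, asymmetric bulges ≤2, more stable
  than dinucleotide-shuffled controls). Two folding backends share one
  contract: a weighted base-pair-maximization DP (GC=3, AU=2, GU=1) and
  ViennaRNA minimum free energy (the default for verdicts).
- **Target prediction** (`target_prediction`): position-weighted penalty
  scoring of miRNA:mRNA complementarity — mismatch 1, G:U wobble 0.5,
  gap 2, doubled over miRNA positions 2–13 — with sites reported below a
  cutoff (3.5 by default); gap-free scores are always half-integers.
- **Cleavage mapping** (`cleavage_mapping`): RLM-5′-RACE clone 5′ ends
  mapped onto the target and expressed in duplex coordinates; the canonical
  slicing signature is the boundary opposite miRNA positions 10/11.
- **tasiRNA phasing** (`tasirna_phasing`): detection of the TAS3 "two-hit"
  architecture (dual miR390 sites), the 21-nt phase register anchored at
  the 3′-site cleavage point, and assignment of tasiARF windows to phases
  D7(+)/D8(+).
- **Synthetic data** (`synthetic_data`): seeded generator for raw
  libraries (24-nt-dominated size profile, 5′-A bias, ncRNA contamination,
  adapter artifacts, a planted low-count miRNA variant block) and for
  hairpin, TAS3 and ARF loci with full coordinate truth.

## Worked example

The package ships the published per-sequence count table of known-miRNA
matches (51 species) and the published library summary as fixtures:

```python
from oleasrna import data, mirna_annotation as ma, profiling as pf

rows = data.load_known_mirna_table()
tallies = ma.tally_families(rows)
s = ma.summarize_known(tallies)
print(f"known-miRNA reads: juvenile {s.reads_per_library['juvenile']} "
      f"({s.unique_per_library['juvenile']} unique), "
      f"adult {s.reads_per_library['adult']} ({s.unique_per_library['adult']} unique)")
print(f"families: {s.families_total} total "
      f"({s.families_per_library['juvenile']} juvenile, "
      f"{s.families_per_library['adult']} adult)")
print(f"miR159: {ma.family_read_total(tallies, 'miR159')} reads, "
      f"top sequence {ma.most_abundant_sequence(rows, 'miR159')[1]} reads")

summary = data.load_library_summary()
rpt = pf.normalize_rpt(4, int(summary.loc['adult', 'filtered_total']))
print(f"miR159 abundance in adult shoots: {pf.round_rpt(rpt)} rpt")
```

prints

```
known-miRNA reads: juvenile 204 (44 unique), adult 22 (15 unique)
families: 18 total (17 juvenile, 11 adult)
miR159: 136 reads, top sequence 113 reads
miR159 abundance in adult shoots: 0.06 rpt
```

i.e. the conserved-miRNA component of the two libraries rolls up to 18
families, strongly skewed toward juvenile tissue, with miR159 the most
abundant family and 4 adult reads normalizing to 0.06 reads per thousand.

A command-line layer wraps each stage (`oleasrna synth | preprocess |
profile | annotate | hairpin | targets | race | tas3`); try
`oleasrna --help`.

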