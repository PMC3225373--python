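import numpy as np
import pytest

from oleasrna import synthetic_data as sd
from oleasrna._seq import normalize
from oleasrna.io_formats import DEFAULT_ADAPTERS
from oleasrna.preprocess import strip_adapters


class TestGeneratePopulation:
    def test_determinism_same_seed(self):
        cfg = sd.PopulationConfig(seed=4, n_reads_per_library=600)
        a = sd.generate_population(cfg)
        b = sd.generate_population(cfg)
        assert a.libraries == b.libraries
        assert a.count_table == b.count_table
        assert [r.sequence for r in a.ncrna_refs] == [
            r.sequence for r in b.ncrna_refs
        ]

    def test_different_seed_differs(self):
        a = sd.generate_population(sd.PopulationConfig(seed=1, n_reads_per_library=300))
        b = sd.generate_population(sd.PopulationConfig(seed=2, n_reads_per_library=300))
        assert a.libraries != b.libraries

    def test_size_distribution_recovered(self):
        """With 80% of the mass on 24 nt, the realized share must fall in
        the 99% binomial interval at n=10,000 (~[78%, 82%])."""
        cfg = sd.PopulationConfig(
            seed=1,
            n_reads_per_library=10_000,
            frac_ncrna_fragments=0.0,
            frac_low_complexity=0.0,
            planted_mirnas=(),
        )
        pop = sd.generate_population(cfg)
        reads = pop.libraries["juvenile"]
        share = sum(1 for r in reads if len(r.sequence) == 24) / len(reads)
        assert 0.78 <= share <= 0.82

    def test_planted_counts_exact_in_count_table(self):
        cfg = sd.PopulationConfig(seed=6, n_reads_per_library=2000)
        pop = sd.generate_population(cfg)
        canonical = [r for r in pop.count_table if r.sequence == sd.MIR159]
        assert canonical[0].count_per_library == {"juvenile": 109, "adult": 4}
        # realized read multiset contains each planted species at its count
        for label in ("juvenile", "adult"):
            seqs = [r.sequence for r in pop.libraries[label]]
            for row in pop.count_table:
                assert seqs.count(row.sequence) == row.count_per_library.get(label, 0)

    def test_five_prime_a_bias(self):
        cfg = sd.PopulationConfig(
            seed=2,
            n_reads_per_library=5000,
            frac_ncrna_fragments=0.0,
            frac_low_complexity=0.0,
            planted_mirnas=(),
        )
        pop = sd.generate_population(cfg)
        reads24 = [
            r.sequence for r in pop.libraries["adult"] if len(r.sequence) == 24
        ]
        frac_a = sum(1 for s in reads24 if s[0] == "A") / len(reads24)
        assert abs(frac_a - 0.60) < 0.03

    def test_zero_reads_rejected(self):
        with pytest.raises(ValueError):
            sd.generate_population(
                sd.PopulationConfig(seed=0, n_reads_per_library=0)
            )

    def test_bad_distribution_rejected(self):
        with pytest.raises(ValueError):
            sd.PopulationConfig(size_distribution={24: 0.5})


class TestGenerateRawReads:
    def test_concatenation_layout(self):
        raw = sd.generate_raw_reads(["ACGU"], DEFAULT_ADAPTERS, seed=0,
                                    frac_artifacts=0.0)
        (rec,) = raw.records
        expected = normalize("atcgtAGGCACCUGAUA" + "ACGU" + "CTGTAGGCACCATCAAT")
        alt = normalize("atcgtAGGCCACUGAUA" + "ACGU" + "CTGTAGGCACCATCAAT")
        assert rec.sequence in (expected, alt)

    def test_artifact_count_binomial(self):
        inserts = ["ACGUACGUACGUACGUACGUA"] * 5000
        raw = sd.generate_raw_reads(inserts, DEFAULT_ADAPTERS, seed=3,
                                    frac_artifacts=0.02)
        # 99% binomial interval around 100 at n=5000, p=0.02
        assert 65 <= raw.n_artifacts <= 135
        assert len(raw.records) == 5000 + raw.n_artifacts

    def test_artifacts_all_discarded_by_preprocess(self):
        raw = sd.generate_raw_reads(
            ["ACGUACGUACGUACGUACGUA"] * 200,
            DEFAULT_ADAPTERS,
            seed=1,
            frac_artifacts=0.5,
        )
        n_artifacts = sum(
            strip_adapters(r, DEFAULT_ADAPTERS).is_artifact for r in raw.records
        )
        assert n_artifacts == raw.n_artifacts


class TestTas3Locus:
    def test_truth_invariants(self):
        loc = sd.generate_tas3_locus(seed=10)
        t = loc.truth
        n = len(loc.transcript.sequence)
        assert 1 <= t["site5"][0] < t["site5"][1] < t["d8"][0]
        assert t["d8"][1] + 1 == t["d7"][0]  # adjacent 21-nt windows
        assert t["d7"][1] < t["site3"][0] < t["site3"][1] <= n
        assert (t["d7"][1] - t["d7"][0] + 1) == 21

    def test_register_spacing_configurable(self):
        a = sd.generate_tas3_locus(seed=1, in_register=True)
        b = sd.generate_tas3_locus(seed=1, in_register=False)
        def spacing(t):
            a5 = t["site5"][1] - 10
            return t["anchor3"] - a5
        assert spacing(a.truth) % 21 == 0
        assert spacing(b.truth) % 21 != 0

    def test_mir390_length_guard(self):
        with pytest.raises(ValueError):
            sd.generate_tas3_locus(seed=0, mir390="ACGU")


class TestHairpinLocus:
    def test_star_is_near_revcomp(self):
        loc = sd.generate_hairpin_transcript(sd.MIR159, seed=1, star_mismatches=2)
        seq = loc.transcript.sequence
        s, e = loc.truth["star_span"]
        star = seq[s - 1 : e]
        from oleasrna._seq import hamming, revcomp

        assert hamming(star, revcomp(sd.MIR159)) == 2

    def test_flanks_within_bounds(self):
        lower = 12
        loc = sd.generate_hairpin_transcript(sd.MIR159, seed=2, lower_stem=lower)
        m_start, _ = loc.truth["mirna_span"]
        n = len(loc.transcript.sequence)
        assert 50 <= m_start - 1 - lower <= 200
        assert 50 <= n - loc.truth["star_span"][1] - lower <= 200

    def test_stem_anchors_flank_duplex(self):
        from oleasrna._seq import revcomp

        loc = sd.generate_hairpin_transcript(sd.MIR159, seed=4, lower_stem=12)
        seq = loc.transcript.sequence
        m_start, _ = loc.truth["mirna_span"]
        _, s_end = loc.truth["star_span"]
        low5 = seq[m_start - 13 : m_start - 1]
        low3 = seq[s_end : s_end + 12]
        assert low3 == revcomp(low5)

    def test_span_loop_truth(self):
        loc = sd.generate_hairpin_transcript(sd.MIR159, seed=3, span_loop=True)
        m = loc.truth["mirna_span"]
        loop = loc.truth["loop_span"]
        assert m[0] < loop[0] and m[1] > loop[1]  # straddles the loop
        assert not loc.truth["compliant"]


class TestRaceClones:
    def test_single_clone(self):
        from oleasrna import target_prediction as tp
        from oleasrna._seq import revcomp
        from oleasrna.io_formats import SequenceRecord

        tx = SequenceRecord("t", "A" * 60 + revcomp(sd.MIR159) + "G" * 80)
        (site,) = tp.find_sites(sd.MIR159, tx)
        (clone,) = sd.generate_race_clones(tx, site, 1, seed=0)
        assert tx.sequence.endswith(clone.sequence)
        assert tx.sequence.find(clone.sequence) + 1 == site.end - 9

    def test_n_clones_guard(self):
        from oleasrna import target_prediction as tp
        from oleasrna._seq import revcomp
        from oleasrna.io_formats import SequenceRecord

        tx = SequenceRecord("t", "A" * 60 + revcomp(sd.MIR159) + "G" * 80)
        (site,) = tp.find_sites(sd.MIR159, tx)
        with pytest.raises(ValueError):
            sd.generate_race_clones(tx, site, 0)
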