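import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oleasrna import synthetic_data as sd
from oleasrna.io_formats import DEFAULT_ADAPTERS, SequenceRecord
from oleasrna.preprocess import (
    ARTIFACT_MULTIMER,
    ARTIFACT_NO_INSERT,
    ARTIFACT_UNRECOGNIZED,
    NcrnaIndex,
    PreprocessParams,
    filter_complexity,
    filter_ncrna,
    filter_size,
    run_preprocess,
    strip_adapters,
)

AD = DEFAULT_ADAPTERS
FIVE = AD.five_prime_variants[0]
THREE = AD.three_prime
INSERT = "UUUGGAUUGAAGGGAGCUCUA"


class TestStripAdapters:
    def test_planted_insert_recovered(self):
        assert strip_adapters(FIVE + INSERT + THREE, AD).insert == INSERT

    def test_empty_construct(self):
        res = strip_adapters(FIVE + THREE, AD)
        assert res.artifact == ARTIFACT_NO_INSERT

    def test_double_three_prime_multimer(self):
        res = strip_adapters(FIVE + INSERT + THREE + THREE, AD)
        assert res.artifact == ARTIFACT_MULTIMER

    def test_double_five_prime_multimer(self):
        res = strip_adapters(FIVE + FIVE + INSERT + THREE, AD)
        assert res.artifact == ARTIFACT_MULTIMER

    def test_missing_adapter_unrecognized(self):
        assert strip_adapters(INSERT + THREE, AD).artifact == ARTIFACT_UNRECOGNIZED
        assert strip_adapters(FIVE + INSERT, AD).artifact == ARTIFACT_UNRECOGNIZED

    def test_one_mismatch_beyond_anchor_tolerated(self):
        corrupted = FIVE[:-1] + ("A" if FIVE[-1] != "A" else "C")
        assert strip_adapters(corrupted + INSERT + THREE, AD).insert == INSERT

    def test_truncated_three_prime_tolerated(self):
        # read ends inside the 3' adapter, anchor still present
        read = FIVE + INSERT + THREE[: AD.min_anchor + 2]
        assert strip_adapters(read, AD).insert == INSERT

    def test_dna_alphabet_normalized(self):
        raw = "atcgtAGGCACCUGAUA" + "ACGT" + "CTGTAGGCACCATCAAT"
        assert strip_adapters(raw, AD).insert == "ACGU"


class TestSizeFilter:
    @pytest.mark.parametrize("n,keep", [(17, False), (18, True), (25, True), (26, False)])
    def test_inclusive_bounds(self, n, keep):
        assert filter_size("A" * n) is keep

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            filter_size("ACGU", min_len=5, max_len=4)


class TestComplexityFilter:
    @pytest.mark.parametrize(
        "seq,keep",
        [
            ("A" * 18, False),
            ("AU" * 9, False),
            ("AUG" * 6, True),
        ],
    )
    def test_distinct_base_rule(self, seq, keep):
        assert filter_complexity(seq) is keep


@pytest.fixture(scope="module")
def refs():
    rng = np.random.default_rng(7)
    seq = "".join("ACGU"[i] for i in rng.integers(0, 4, size=400))
    return [SequenceRecord("rRNA-like", seq)]


class TestNcrnaFilter:
    def test_planted_substring_dropped(self, refs):
        frag = refs[0].sequence[100:121]
        assert filter_ncrna(frag, refs) == "rRNA-like"

    def test_random_absent_kept(self, refs):
        rng = np.random.default_rng(8)
        query = "".join("ACGU"[i] for i in rng.integers(0, 4, size=21))
        # oracle: exhaustive scan confirms absence
        ref = refs[0].sequence
        assert all(
            sum(a != b for a, b in zip(query, ref[i : i + 21])) > 0
            for i in range(len(ref) - 20)
        )
        assert filter_ncrna(query, refs) is None

    def test_one_mismatch_copy_vs_tolerance(self, refs):
        frag = refs[0].sequence[50:71]
        mutated = ("A" if frag[10] != "A" else "C").join([frag[:10], frag[11:]])
        assert filter_ncrna(mutated, refs, max_mismatches=1) == "rRNA-like"
        assert filter_ncrna(mutated, refs, max_mismatches=0) is None

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        start=st.integers(0, 375),
        length=st.integers(18, 25),
        n_mut=st.integers(0, 2),
        mut_seed=st.integers(0, 10_000),
    )
    def test_agrees_with_bruteforce_hamming(self, refs, start, length, n_mut, mut_seed):
        """Seed-and-extend equals a brute-force Hamming scan for any query
        derived from the reference by up to two substitutions."""
        ref = refs[0].sequence
        frag = list(ref[start : start + length])
        rng = np.random.default_rng(mut_seed)
        for pos in rng.choice(length, size=min(n_mut, length), replace=False):
            frag[pos] = "ACGU"[(("ACGU".index(frag[pos])) + 1) % 4]
        query = "".join(frag)
        for m in (0, 1, 2):
            brute = any(
                sum(a != b for a, b in zip(query, ref[i : i + length])) <= m
                for i in range(len(ref) - length + 1)
            )
            assert (filter_ncrna(query, refs, max_mismatches=m) is not None) == brute


class TestRunPreprocess:
    def test_all_artifact_input(self):
        reads = [SequenceRecord(f"r{i}", FIVE + THREE) for i in range(5)]
        lib = run_preprocess(reads, AD, None)
        assert lib.stats.filtered_reads == 0
        assert lib.unique_sequences == 0
        assert lib.stats.artifacts[ARTIFACT_NO_INSERT] == 5

    def test_monotone_and_closed(self):
        pop = sd.generate_population(
            sd.PopulationConfig(seed=3, n_reads_per_library=800)
        )
        raw = sd.generate_raw_reads(pop.libraries["juvenile"], AD, seed=3)
        lib = run_preprocess(raw.records, AD, pop.ncrna_refs)
        s = lib.stats
        assert s.raw_reads >= s.adapter_removed_reads >= s.filtered_reads
        s.check_closure()

    def test_accounting_matches_planted_truth(self):
        pop = sd.generate_population(
            sd.PopulationConfig(seed=11, n_reads_per_library=1500)
        )
        for label in ("juvenile", "adult"):
            raw = sd.generate_raw_reads(pop.libraries[label], AD, seed=11)
            lib = run_preprocess(raw.records, AD, pop.ncrna_refs, label=label)
            exp = pop.expected_stats(label)
            assert lib.stats.adapter_removed_reads == exp["n_inserts"]
            assert dict(lib.stats.removed) == exp["removed"]
            assert lib.stats.filtered_reads == exp["filtered_reads"]
            assert lib.stats.unique_sequences == exp["unique_sequences"]
            assert lib.stats.artifacts[ARTIFACT_NO_INSERT] == raw.n_no_insert
            assert lib.stats.artifacts[ARTIFACT_MULTIMER] == raw.n_multimer

    def test_shuffle_invariance(self):
        pop = sd.generate_population(
            sd.PopulationConfig(seed=5, n_reads_per_library=500)
        )
        raw = sd.generate_raw_reads(pop.libraries["adult"], AD, seed=5)
        lib1 = run_preprocess(raw.records, AD, pop.ncrna_refs)
        rng = np.random.default_rng(0)
        shuffled = [raw.records[i] for i in rng.permutation(len(raw.records))]
        lib2 = run_preprocess(shuffled, AD, pop.ncrna_refs)
        assert lib1.entries == lib2.entries
        assert dict(lib1.stats.removed) == dict(lib2.stats.removed)

    def test_idempotent_on_clean_inserts(self):
        pop = sd.generate_population(
            sd.PopulationConfig(seed=9, n_reads_per_library=400)
        )
        raw = sd.generate_raw_reads(pop.libraries["juvenile"], AD, seed=9)
        lib1 = run_preprocess(raw.records, AD, pop.ncrna_refs)
        inserts = [
            SequenceRecord(f"i{i}", seq)
            for i, (seq, c) in enumerate(lib1.entries.items())
            for _ in range(c)
        ]
        lib2 = run_preprocess(inserts, None, pop.ncrna_refs)
        assert lib2.entries == lib1.entries
        assert sum(lib2.stats.removed.values()) == 0

    def test_n_containing_reads_dropped_first(self):
        reads = [SequenceRecord("n1", FIVE + "ACGUN" + "ACGU" * 4 + THREE)]
        lib = run_preprocess(reads, AD, None)
        assert lib.stats.removed["contains_n"] == 1
        assert lib.stats.filtered_reads == 0
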