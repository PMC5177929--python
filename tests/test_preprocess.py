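"""Trimming, size selection, collapsing, RPM and contaminant filtering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stressmir.preprocess import (
    DistinctTag,
    collapse_and_name,
    compute_rpm,
    filter_known_ncRNA,
    filter_min_rpm,
    run_pipeline,
    size_distribution,
    size_select,
    trim_adapter,
)
from stressmir.simulate import ADAPTER3, full_design, revcomp_dna

DESIGN2 = full_design()[:2]

dna_seq = st.text(alphabet="ACGT", min_size=18, max_size=24)


class TestTrimAdapter:
    def test_exact_adapter_at_known_position(self):
        insert, trimmed = trim_adapter("ACGTACGT" + ADAPTER3)
        assert trimmed and insert == "ACGTACGT"

    def test_adapter_absent_returns_whole_read_flagged(self):
        read = "ACGTACGTACGTACGTACGTACGTACGTACGTAC"
        insert, trimmed = trim_adapter(read)
        assert not trimmed and insert == read

    def test_empty_read(self):
        assert trim_adapter("") == ("", False)

    def test_min_overlap_floor_enforced(self):
        with pytest.raises(ValueError):
            trim_adapter("ACGT", min_overlap=3)

    @pytest.mark.parametrize("kept", range(0, 26))
    def test_truncated_adapter_recovered_when_overlap_sufficient(self, kept):
        """Enumerate adapter truncation lengths against leftmost-match search."""
        insert = "TGTGTTCCCAGCTCGACCCCG"
        read = insert + ADAPTER3[:kept]
        got, trimmed = trim_adapter(read, min_overlap=5)
        if kept >= 5:
            assert trimmed and got == insert
        else:
            assert not trimmed and got == read

    def test_leftmost_full_match_wins(self):
        # the adapter occurs twice: cut must be at the first occurrence
        read = "AAAA" + ADAPTER3 + "CCCC" + ADAPTER3
        insert, trimmed = trim_adapter(read)
        assert trimmed and insert == "AAAA"

    def test_spurious_internal_prefix_not_cut(self):
        # a short adapter-prefix followed by non-adapter sequence is not an
        # adapter hit; the scan continues to the real adapter downstream
        read = "AAAA" + ADAPTER3[:6] + "CCCC" + ADAPTER3
        insert, trimmed = trim_adapter(read)
        assert trimmed and insert == "AAAA" + ADAPTER3[:6] + "CCCC"


class TestSizeSelect:
    def test_bounds_inclusive(self):
        lens = {17: "A" * 17, 18: "C" * 18, 24: "G" * 24, 25: "T" * 25}
        assert size_select(lens.values()) == [lens[18], lens[24]]

    def test_empty(self):
        assert size_select([]) == []

    def test_matches_brute_force_recount(self, rng):
        seqs = ["A" * int(rng.integers(10, 41)) for _ in range(1000)]
        assert len(size_select(seqs)) == sum(1 for s in seqs if 18 <= len(s) <= 24)


class TestCollapseAndName:
    def test_counts_per_library(self):
        s1, s2 = "A" * 20, "C" * 20
        tags = collapse_and_name(
            {DESIGN2[0].library_id: [s1] * 3, DESIGN2[1].library_id: [s1] * 2 + [s2]},
            DESIGN2,
        )
        by_seq = {t.sequence: t for t in tags}
        assert list(by_seq[s1].counts) == [3, 2]
        assert list(by_seq[s2].counts) == [0, 1]

    def test_tag_ids_invariant_to_library_order(self):
        s1, s2 = "ACGT" * 5, "TTTTACGT" * 3
        lib_a, lib_b = DESIGN2[0].library_id, DESIGN2[1].library_id
        t1 = collapse_and_name({lib_a: [s1], lib_b: [s2]}, DESIGN2)
        t2 = collapse_and_name({lib_b: [s2], lib_a: [s1]}, list(reversed(DESIGN2)))
        assert {t.sequence: t.tag_id for t in t1} == {t.sequence: t.tag_id for t in t2}

    def test_read_conservation(self, rng):
        reads = {
            d.library_id: ["".join(rng.choice(list("ACGT"), 20)) for _ in range(500)]
            for d in DESIGN2
        }
        tags = collapse_and_name(reads, DESIGN2)
        totals = np.sum([t.counts for t in tags], axis=0)
        assert list(totals) == [500, 500]


class TestRpm:
    def test_arithmetic(self):
        t = DistinctTag("A" * 20, "tag1", np.array([5]))
        compute_rpm([t], [500_000])
        assert t.rpm[0] == pytest.approx(10.0)

    def test_normalisation_identity(self, rng):
        counts = rng.integers(0, 100, size=(30, 2))
        tags = [DistinctTag(f"{'ACGT'[i % 4] * 20}{i:02d}", f"t{i}", counts[i]) for i in range(30)]
        compute_rpm(tags, counts.sum(axis=0))
        assert np.sum([t.rpm for t in tags], axis=0) == pytest.approx([1e6, 1e6])

    def test_zero_denominator_with_counts_is_hard_error(self):
        t = DistinctTag("A" * 20, "t", np.array([1, 0]))
        with pytest.raises(ValueError):
            compute_rpm([t], [0, 100])

    def test_matches_brute_force(self, rng):
        counts = rng.integers(0, 50, size=(20, 4))
        denom = rng.integers(1000, 5000, size=4)
        tags = [DistinctTag("A" * 20, f"t{i}", counts[i]) for i in range(20)]
        compute_rpm(tags, denom)
        for i, t in enumerate(tags):
            for j in range(4):
                assert t.rpm[j] == pytest.approx(counts[i, j] / denom[j] * 1e6)


class TestDecoyFilter:
    def test_exact_substring_removed_mismatch_retained(self):
        ref = {"rRNA_1": "GGGG" + "TGTGTTCCCAGCTCGACCCCG" + "CCCC"}
        hit = DistinctTag("TGTGTTCCCAGCTCGACCCCG", "t1", np.array([1]))
        near = DistinctTag("TGTGTTCCCAGCTCGACCCCA", "t2", np.array([1]))
        kept, removed = filter_known_ncRNA([hit, near], [ref])
        assert removed == [hit] and kept == [near]

    def test_reverse_complement_also_removed(self):
        tag = DistinctTag("TGTGTTCCCAGCTCGACCCCG", "t1", np.array([1]))
        ref = {"rRNA_1": "AA" + revcomp_dna(tag.sequence) + "TT"}
        kept, removed = filter_known_ncRNA([tag], [ref])
        assert removed == [tag]

    def test_unreadable_fasta_names_file(self, tmp_path):
        with pytest.raises(ValueError, match="nope.fasta"):
            filter_known_ncRNA([], [tmp_path / "nope.fasta"])

    def test_partition_matches_brute_force_scan(self, rng):
        refs = {
            f"r{i}": "".join(rng.choice(list("ACGT"), 200)) for i in range(10)
        }
        tags = []
        for i in range(100):
            if i % 3 == 0:  # plant a true substring
                ref = refs[f"r{i % 10}"]
                k = int(rng.integers(18, 25))
                start = int(rng.integers(0, 200 - k))
                seq = ref[start : start + k]
            else:
                seq = "".join(rng.choice(list("ACGT"), 21))
            tags.append(DistinctTag(seq, f"t{i}", np.array([1])))
        kept, removed = filter_known_ncRNA(tags, [refs])
        for t in tags:
            expected = any(
                t.sequence in r or revcomp_dna(t.sequence) in r for r in refs.values()
            )
            assert (t in removed) == expected


class TestMinRpm:
    def test_all_just_below_removed(self):
        t = DistinctTag("A" * 20, "t", np.array([1, 1]), rpm=np.array([9.99, 9.99]))
        assert filter_min_rpm([t]) == []

    def test_exactly_threshold_in_one_library_retained(self):
        t = DistinctTag("A" * 20, "t", np.array([1, 1]), rpm=np.array([10.0, 0.1]))
        assert filter_min_rpm([t]) == [t]

    def test_matches_brute_force_max_scan(self, rng):
        tags = [
            DistinctTag("A" * 20, f"t{i}", np.zeros(6, dtype=int), rpm=rng.uniform(0, 20, 6))
            for i in range(50)
        ]
        kept = filter_min_rpm(tags)
        assert set(id(t) for t in kept) == {
            id(t) for t in tags if t.rpm.max() >= 10.0
        }


class TestSizeDistribution:
    def test_single_tag(self):
        t = DistinctTag("A" * 21, "t", np.array([10, 0]))
        df = size_distribution([t], DESIGN2)
        row = df[(df.treatment == DESIGN2[0].treatment) & (df["size"] == 21)].iloc[0]
        assert row.reads == 10 and row.tags == 1

    def test_matches_brute_force_histogram(self, rng):
        design = full_design()[:6]
        tags = [
            DistinctTag(
                "C" * int(rng.integers(18, 25)), f"t{i}", rng.integers(0, 5, len(design))
            )
            for i in range(60)
        ]
        df = size_distribution(tags, design)
        for _, row in df.iterrows():
            cols = [i for i, d in enumerate(design) if d.treatment == row.treatment]
            expect_reads = sum(
                int(t.counts[cols].sum()) for t in tags if len(t.sequence) == row["size"]
            )
            assert row.reads == expect_reads


class TestEndToEndRoundTrip:
    def test_pipeline_recovers_planted_counts_exactly(self, small_study):
        """preprocess(emit_fastq(M)) = M under error-free simulation."""
        res = run_pipeline(
            small_study.fastq_paths, small_study.design,
            decoy_fastas=small_study.decoy_fastas,
        )
        truth_counts = small_study.counts
        removed = {t.sequence for t in res.removed_ncRNA}
        recovered = {t.sequence: t.counts for t in res.all_tags}
        for seq, row in truth_counts.iterrows():
            if row.sum() == 0 or seq in removed:
                continue
            assert seq in recovered, seq
            assert list(recovered[seq]) == list(row)
        # conservation: stage totals never increase
        for st_ in res.stats:
            assert st_.raw_reads >= st_.trimmed_reads >= st_.retained_reads
            assert st_.retained_reads >= st_.reads_after_decoy_removal

    def test_rpm_sums_to_million_over_all_tags(self, small_study):
        res = run_pipeline(small_study.fastq_paths, small_study.design)
        total = np.sum([t.rpm for t in res.all_tags], axis=0)
        assert total == pytest.approx(np.full(72, 1e6))
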