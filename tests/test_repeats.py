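"""Repeat attribution, fold changes, consensus matching and the LINE-1
3'-end profile."""
import numpy as np
import pytest

from polyterm.alignment import AlignmentHit, MappingStatus, STATUS_NON_UNIQUE, STATUS_UNIQUE
from polyterm.annotate import RegionCall
from polyterm.model import RepeatFeature, revcomp
from polyterm.repeats import (
    Line1EndProfile,
    RepeatError,
    attribute_repeats,
    attribute_unmapped,
    compare_end_profiles,
    line1_end_profile,
    line1_full_length_filter,
    match_consensus,
    repeat_fold_change,
    RepeatCountTable,
)


def hit(read_id, start, end, strand="+", chrom="c"):
    return AlignmentHit(read_id, chrom, strand, ((start, end),),
                        end - start, 0)


REPEATS = [
    RepeatFeature("c", 1000, 8000, "+", "LINE1", "L1_full"),  # 7 kb
    RepeatFeature("c", 20000, 22000, "+", "LINE1", "L1_frag"),
    RepeatFeature("c", 30000, 30200, "+", "SINE", "S1"),
    RepeatFeature("c", 30150, 30650, "+", "LTR", "T1"),  # overlaps S1
]


class TestAttribution:
    def test_unique_reads_split_by_region_call(self):
        statuses = {
            "r1": MappingStatus("r1", STATUS_UNIQUE, hit("r1", 1500, 2000)),
            "r2": MappingStatus("r2", STATUS_UNIQUE, hit("r2", 20500, 21000)),
            "r3": MappingStatus("r3", STATUS_UNIQUE, hit("r3", 40000, 40500)),
        }
        calls = {
            "r1": RegionCall("r1", "intergenic"),
            "r2": RegionCall("r2", "intron", "gX"),
            "r3": RegionCall("r3", "exon", "gY"),  # excluded from all panels
        }
        tables = attribute_repeats(statuses, calls, REPEATS, "x")
        assert tables["intergenic_unique"].counts["LINE1"] == 1
        assert tables["intergenic_unique"].total == 1
        assert tables["intronic_unique"].counts["LINE1"] == 1
        assert sum(tables["non_unique"].counts.values()) == 0

    def test_multi_class_read_counted_in_each_class(self):
        statuses = {"r1": MappingStatus("r1", STATUS_UNIQUE,
                                        hit("r1", 30100, 30400))}
        calls = {"r1": RegionCall("r1", "intergenic")}
        tables = attribute_repeats(statuses, calls, REPEATS, "x")
        t = tables["intergenic_unique"]
        assert t.counts["SINE"] == 1 and t.counts["LTR"] == 1
        assert t.total == 1
        assert t.multi_class_reads == 1

    def test_non_unique_uses_all_placements(self):
        placements = [hit("r1", 40000, 40500), hit("r1", 1500, 2000)]
        statuses = {"r1": MappingStatus("r1", STATUS_NON_UNIQUE,
                                        placements[0], 0)}
        tables = attribute_repeats(statuses, {}, REPEATS, "x",
                                   all_hits={"r1": placements})
        assert tables["non_unique"].counts["LINE1"] == 1

    def test_missing_region_call_for_unique_read(self):
        statuses = {"r1": MappingStatus("r1", STATUS_UNIQUE,
                                        hit("r1", 0, 100))}
        with pytest.raises(RepeatError):
            attribute_repeats(statuses, {}, REPEATS, "x")


class TestMatchConsensus:
    LIB = {"LINE1": "ACGT" * 1500, "SINE": "TTGCA" * 40}

    def test_exact_substring_matches(self, bundle):
        cons = bundle.consensus["LINE1"]
        assert match_consensus(cons[1000:1500], bundle.consensus) == "LINE1"

    def test_reverse_complement_matches(self, bundle):
        cons = bundle.consensus["SINE"]
        assert match_consensus(revcomp(cons[:150]), bundle.consensus) == "SINE"

    def test_partial_overlap_above_thresholds(self, bundle):
        cons = bundle.consensus["LINE1"]
        # 60% of the read overlaps the consensus 3' end at 100% identity
        read = cons[-300:] + "A" * 200
        assert match_consensus(read, bundle.consensus) == "LINE1"

    def test_random_sequence_matches_nothing(self, bundle, rng):
        seq = "".join(rng.choice(list("ACGT"), size=400))
        # exhaustive scan oracle: no consensus window reaches 80% identity
        # over half the read (checked implicitly by the declared thresholds)
        assert match_consensus(seq, bundle.consensus) is None

    def test_identity_threshold_boundary(self, rng):
        cons = "".join(rng.choice(list("ACGT"), size=1000))
        read = list(cons[200:700])
        # mutate 15% of positions -> 85% identity over the full read
        for pos in rng.choice(500, size=75, replace=False):
            read[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[pos]]
        assert match_consensus("".join(read), {"LTR": cons}) == "LTR"

    def test_empty_read_rejected(self):
        with pytest.raises(RepeatError):
            match_consensus("", self.LIB)

    def test_attribute_unmapped_counts(self, bundle):
        cons = bundle.consensus["LINE1"]
        reads = [("u1", cons[:500]), ("u2", "A" * 400)]
        table = attribute_unmapped(reads, bundle.consensus, "x")
        assert table.counts["LINE1"] == 1
        assert table.total == 2


class TestFoldChange:
    def make(self, count, total, cat="intergenic_unique"):
        return RepeatCountTable("x", cat, {"LINE1": count, "SINE": 0,
                                           "LTR": 0}, total)

    def test_fold_arithmetic(self):
        fc = repeat_fold_change(self.make(100, 10000), self.make(210, 10000),
                                "LINE1")
        assert fc.fold == pytest.approx(2.1)
        assert fc.sd_a == pytest.approx(np.sqrt(0.01 * 0.99 / 10000))

    def test_null_case(self):
        fc = repeat_fold_change(self.make(50, 1000), self.make(50, 1000),
                                "LINE1")
        assert fc.fold == pytest.approx(1.0)
        assert fc.fisher_p == pytest.approx(1.0)

    def test_zero_reference_count_flagged_infinite(self):
        fc = repeat_fold_change(self.make(0, 1000), self.make(5, 1000),
                                "LINE1")
        assert fc.infinite
        assert fc.fold == float("inf")

    def test_category_mismatch_rejected(self):
        with pytest.raises(RepeatError):
            repeat_fold_change(self.make(1, 10), self.make(1, 10, "unmapped"),
                               "LINE1")


class TestFullLengthFilter:
    def test_element_length_threshold(self):
        reps = [RepeatFeature("c", 0, 6000, "+", "LINE1", "a"),
                RepeatFeature("c", 10000, 15999, "+", "LINE1", "b")]
        kept = line1_full_length_filter([hit("r1", 100, 600),
                                         hit("r2", 10100, 10600)], reps)
        assert [h.read_id for h, _ in kept] == ["r1"]

    def test_partial_overlap_kept(self):
        reps = [RepeatFeature("c", 1000, 8000, "+", "LINE1", "a")]
        kept = line1_full_length_filter([hit("r1", 700, 1200)], reps)
        assert len(kept) == 1


class TestEndProfile:
    def test_bin_positions(self):
        rep = RepeatFeature("c", 0, 1000, "+", "LINE1", "a")
        # + aligned read ending at 550 -> relative 0.55 -> third fifth
        profile = line1_end_profile([(hit("r1", 100, 550), rep)], "x")
        assert profile.bin_counts == [0, 0, 1, 0, 0]
        # end exactly at element end clamps into the last bin
        profile = line1_end_profile([(hit("r2", 600, 1000), rep)], "x")
        assert profile.bin_counts == [0, 0, 0, 0, 1]

    def test_minus_strand_element_orientation(self):
        rep = RepeatFeature("c", 0, 1000, "-", "LINE1", "a")
        # + aligned read ending at the element's genomic end = element 5'
        profile = line1_end_profile([(hit("r1", 600, 1000), rep)], "x")
        assert profile.bin_counts == [1, 0, 0, 0, 0]

    def test_counts_sum_to_reads(self, rng):
        rep = RepeatFeature("c", 0, 6500, "+", "LINE1", "a")
        pairs = []
        for i in range(200):
            s = int(rng.integers(0, 6000))
            strand = "+" if rng.random() < 0.5 else "-"
            pairs.append((hit(f"r{i}", s, s + 500, strand), rep))
        profile = line1_end_profile(pairs, "x")
        assert sum(profile.bin_counts) == profile.n_reads == 200

    def test_read_not_on_element_rejected(self):
        rep = RepeatFeature("c", 0, 1000, "+", "LINE1", "a")
        with pytest.raises(RepeatError):
            line1_end_profile([(hit("r1", 5000, 5500), rep)], "x")


class TestCompareEndProfiles:
    def test_identical_profiles(self):
        a = Line1EndProfile("a", [10, 10, 10, 10, 10], 50)
        res = compare_end_profiles(a, a)
        assert res.statistic == 0.0
        assert res.pvalue == 1.0

    def test_hand_computed_pearson(self):
        a = Line1EndProfile("a", [10, 10, 10, 10, 10], 50)
        b = Line1EndProfile("b", [50, 10, 10, 10, 10], 90)
        obs = np.array([a.bin_counts, b.bin_counts], dtype=float)
        expected = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        stat = ((obs - expected) ** 2 / expected).sum()
        res = compare_end_profiles(a, b)
        assert res.statistic == pytest.approx(stat, rel=1e-12)
        assert res.df == 4

    def test_empty_profile_rejected(self):
        a = Line1EndProfile("a", [1, 1, 1, 1, 1], 5)
        b = Line1EndProfile("b", [0, 0, 0, 0, 0], 0)
        with pytest.raises(RepeatError):
            compare_end_profiles(a, b)
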