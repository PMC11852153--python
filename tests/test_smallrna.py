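"""Filter cascade accounting, tag collapsing and priority annotation."""

import pytest

from spongeworks.smallrna import (
    ANNOTATION_PRIORITY,
    CleanTag,
    FilterReport,
    QualityPolicy,
    ReadRecord,
    annotate_tags,
    collapse_tags,
    filter_reads,
    length_distribution,
)

ADAPTER3 = "TGGAATTCTCGGGTGCCAAGG"
ADAPTER5 = "GTTCAGAGTTCTACAGTCCGACGATC"
HI = "I" * 120


def read(seq, qual=None, rid="r"):
    return ReadRecord(rid, seq, (qual or HI)[: len(seq)])


def run_filter(reads):
    return filter_reads(reads, ADAPTER3, ADAPTER5)


INSERT22 = "ACGTACGTGGCCTTAGCAGTCC"  # 22 nt, no adapter keys, not polyA


@pytest.mark.parametrize(
    "seq,qual,category",
    [
        (INSERT22 + ADAPTER3, "#" * 30 + HI, "low_quality"),  # 30/43 bases < Q20
        (INSERT22 + "N" + ADAPTER3, None, "low_quality"),
        ("ACGT" * 10, None, "adapter3_null"),  # adapter never ligated
        (INSERT22[:10] + ADAPTER5[:8] + INSERT22[10:14] + ADAPTER3, None, "adapter5_hit"),
        (INSERT22[:17] + ADAPTER3, None, "insert_too_short"),
        (ADAPTER3 + "ACGT" * 5, None, "insert_too_short"),  # no insert at all
        (INSERT22 + "GGCCTTAGCAGTC" + ADAPTER3, None, "insert_too_long"),  # 35 nt
        ("A" * 20 + ADAPTER3, None, "polyA"),
        ("ACGTC" + "A" * 11 + "CGGT" + ADAPTER3, None, "polyA"),  # internal A-run
        (INSERT22 + ADAPTER3, None, "clean_tags"),
    ],
)
def test_each_read_lands_in_its_first_failing_category(seq, qual, category):
    _, report = run_filter([read(seq, qual)])
    assert report.total == 1
    assert report.counts[category] == 1
    assert sum(report.counts.values()) == 1


def test_insert_is_sequence_before_first_adapter_occurrence():
    inserts, report = run_filter([read(INSERT22 + ADAPTER3 + "T" + ADAPTER3)])
    assert inserts["S1"] == [INSERT22]
    assert report.counts["clean_tags"] == 1


def test_boundary_insert_lengths_18_and_30_are_kept():
    for n in (18, 30):
        insert = ("ACGTGGCCTTAGCAGTCCGTTAGCCGGTCA")[:n]
        inserts, report = run_filter([read(insert + ADAPTER3)])
        assert report.counts["clean_tags"] == 1, n


def test_accounting_is_order_insensitive(rng):
    reads = []
    for i in range(30):
        reads.append(read(INSERT22 + ADAPTER3, rid=f"c{i}"))
        reads.append(read("ACGT" * 12, rid=f"n{i}"))
        reads.append(read("A" * 21 + ADAPTER3, rid=f"p{i}"))
    _, before = run_filter(reads)
    perm = [reads[i] for i in rng.permutation(len(reads))]
    _, after = run_filter(perm)
    assert before.counts == after.counts


def test_empty_adapter_rejected():
    with pytest.raises(ValueError):
        filter_reads([read("ACGT")], "", ADAPTER5)


def test_quality_policy_boundary():
    policy = QualityPolicy(min_phred=20, max_low_fraction=0.2)
    # exactly 20% low bases is NOT low-quality (strictly more than 20% is)
    qual = chr(33 + 10) * 2 + chr(33 + 30) * 8
    assert not policy.is_low_quality(ReadRecord("r", "ACGTACGTAC", qual))
    qual_bad = chr(33 + 10) * 3 + chr(33 + 30) * 7
    assert policy.is_low_quality(ReadRecord("r", "ACGTACGTAC", qual_bad))


class TestCollapse:
    def test_singleton_removed_as_low_frequency(self):
        tags, report = collapse_tags({"s1": [INSERT22]})
        assert tags == []
        assert report.counts["low_frequency"] == 1
        assert report.counts["clean_tags"] == 0

    def test_total_frequency_across_samples_counts(self):
        tags, report = collapse_tags({"s1": [INSERT22], "s2": [INSERT22]})
        assert len(tags) == 1
        assert tags[0].counts == {"s1": 1, "s2": 1}
        assert report.counts["low_frequency"] == 0

    def test_sort_by_count_then_sequence(self):
        ins = {"s1": ["CCCC" * 5] * 5 + ["AAAA" * 5] * 5 + ["GGGG" * 5] * 2}
        tags, _ = collapse_tags(ins)
        assert [t.sequence for t in tags] == ["AAAA" * 5, "CCCC" * 5, "GGGG" * 5]

    def test_accounting_still_partitions_after_collapse(self):
        reads = [read(INSERT22 + ADAPTER3, rid=f"a{i}") for i in range(3)]
        reads.append(read("ACGTGGCCTTAGCAGTCCGTTAGCCGGTCA"[:20] + ADAPTER3, rid="solo"))
        inserts, report = run_filter(reads)
        _, report = collapse_tags(inserts, report)
        assert sum(report.counts.values()) == report.total == 4
        assert report.counts["clean_tags"] == 3
        assert report.counts["low_frequency"] == 1


class TestAnnotate:
    def make_tag(self, seq="ACGTACGTGGCCTTAGCA"):
        return CleanTag(seq, {"s1": 2})

    def test_priority_respected_for_every_category_pair(self):
        seq = "ACGTACGTGGCCTTAGCA"
        cats = [c for c in ANNOTATION_PRIORITY if c != "exist_miRNA_edit"]
        for i, hi_cat in enumerate(cats):
            for lo_cat in cats[i + 1 :]:
                out = annotate_tags(
                    [self.make_tag(seq)], {hi_cat: {seq}, lo_cat: {seq}}
                )
                assert out[0].category == hi_cat, (hi_cat, lo_cat)

    def test_unmatched_tag_is_unann(self):
        out = annotate_tags([self.make_tag()], {"exon": {"TTTT"}})
        assert out[0].category == "unann"
        assert not out[0].excluded

    def test_rrna_class_wins_and_is_excluded(self):
        seq = "ACGTACGTGGCCTTAGCA"
        out = annotate_tags(
            [self.make_tag(seq)], {"rRNA_etc": {seq}, "exist_miRNA": {seq}}
        )
        assert out[0].category == "rRNA_etc"
        assert out[0].excluded

    def test_edit_category_one_mismatch_outside_seed(self):
        ref = "ACGTACGTGGCCTTAGCA"
        # mismatch at position 10 (outside seed 2-7)
        edited = ref[:9] + ("A" if ref[9] != "A" else "C") + ref[10:]
        out = annotate_tags([self.make_tag(edited)], {"exist_miRNA": {ref}})
        assert out[0].category == "exist_miRNA_edit"
        # mismatch inside the seed (position 4) does not qualify
        seeded = ref[:3] + ("A" if ref[3] != "A" else "C") + ref[4:]
        out = annotate_tags([self.make_tag(seeded)], {"exist_miRNA": {ref}})
        assert out[0].category == "unann"

    def test_annotation_idempotent(self):
        seq = "ACGTACGTGGCCTTAGCA"
        sources = {"known_miRNA": {seq}}
        once = annotate_tags([self.make_tag(seq)], sources)
        twice = annotate_tags(once, sources)
        assert once == twice

    def test_unknown_source_category_raises(self):
        with pytest.raises(ValueError):
            annotate_tags([self.make_tag()], {"mystery": {"ACGT"}})


def test_length_distribution_weighted_by_counts():
    tags = [CleanTag("A" * 22, {"s1": 10}), CleanTag("C" * 22, {"s1": 3})]
    hist = length_distribution(tags)
    assert hist[22] == 13
    assert sum(hist.values()) == 13
    assert all(v == 0 for k, v in hist.items() if k != 22)


def test_length_distribution_empty():
    hist = length_distribution([])
    assert set(hist) == set(range(18, 31))
    assert sum(hist.values()) == 0


def test_report_percentages_sum_to_100():
    report = FilterReport(total=7, counts=dict.fromkeys(FilterReport().counts, 0))
    report.counts["clean_tags"] = 4
    report.counts["polyA"] = 3
    assert sum(report.percentages().values()) == pytest.approx(100.0, abs=0.01)
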