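"""Small-RNA read filtering, tag collapsing and priority annotation.

The sequencing-facing front end of the pipeline: raw reads are passed
through an ordered cascade of quality/adapter/length/composition filters
with full per-category accounting, surviving inserts are collapsed into
unique *clean tags* with per-sample counts, and every tag is assigned a
single annotation category under a fixed priority order.

Filter cascade (each read is counted in the FIRST category it fails):

1. ``low_quality``      — too many low-Phred bases, or an ``N`` call.
2. ``adapter3_null``    — no 3' adapter found; otherwise the insert is the
   sequence strictly before the first adapter occurrence.
3. ``adapter5_hit``     — the 5' adapter occurs inside the trimmed insert
   (a ligation artefact).
4. ``insert_too_short`` / ``insert_too_long`` — insert outside 18–30 nt
   (reads with no insert at all fall in ``insert_too_short``).
5. ``polyA``            — A-homopolymer-dominated insert.
6. ``low_frequency``    — applied at the collapse step: tags whose summed
   count across all samples is below 2 are dropped.

Everything left is a clean tag.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Callable, Collection, Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "ReadRecord",
    "QualityPolicy",
    "PolyAPolicy",
    "FilterReport",
    "CleanTag",
    "FILTER_CATEGORIES",
    "ANNOTATION_PRIORITY",
    "filter_reads",
    "collapse_tags",
    "annotate_tags",
    "length_distribution",
    "quantify_mirna_tags",
]

MIN_INSERT = 18
MAX_INSERT = 30

#: discard categories in cascade order, then the survivors
FILTER_CATEGORIES = (
    "low_quality",
    "adapter3_null",
    "adapter5_hit",
    "insert_too_short",
    "insert_too_long",
    "polyA",
    "low_frequency",
    "clean_tags",
)

#: single-assignment priority: a tag matching several sources gets the
#: first matching category of this list; no match at all -> "unann".
ANNOTATION_PRIORITY = (
    "rRNA_etc",
    "exist_miRNA",
    "exist_miRNA_edit",
    "known_miRNA",
    "repeat",
    "exon",
    "novel_candidate",
    "intron",
)

#: categories counted as miRNA for downstream quantification
MIRNA_CATEGORIES = frozenset(
    {"exist_miRNA", "exist_miRNA_edit", "known_miRNA", "novel_candidate"}
)


@dataclass(frozen=True)
class ReadRecord:
    """One raw small-RNA read with Phred+33 base qualities."""

    id: str
    sequence: str
    quality: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise ValueError(
                f"read {self.id!r}: sequence and quality lengths differ"
            )

    def phred_scores(self) -> list[int]:
        return [ord(c) - 33 for c in self.quality]


@dataclass(frozen=True)
class QualityPolicy:
    """A read is low-quality if more than ``max_low_fraction`` of its bases
    fall below ``min_phred``, or (by default) if it contains any 'N'."""

    min_phred: int = 20
    max_low_fraction: float = 0.2
    reject_n: bool = True

    def is_low_quality(self, read: ReadRecord) -> bool:
        if self.reject_n and "N" in read.sequence:
            return True
        scores = read.phred_scores()
        low = sum(1 for s in scores if s < self.min_phred)
        return low > self.max_low_fraction * len(scores)


@dataclass(frozen=True)
class PolyAPolicy:
    """An insert is polyA if >= ``min_a_fraction`` of bases are 'A' or it
    contains an A-run of at least ``min_a_run``."""

    min_a_fraction: float = 0.8
    min_a_run: int = 10

    def is_polya(self, insert: str) -> bool:
        if not insert:
            return False
        if insert.count("A") >= self.min_a_fraction * len(insert):
            return True
        return "A" * self.min_a_run in insert


@dataclass
class FilterReport:
    """Per-category read accounting for one filtering run.

    Counts partition the input reads: the discard categories plus
    ``clean_tags`` always sum to ``total``.
    """

    total: int = 0
    counts: dict[str, int] = field(
        default_factory=lambda: {c: 0 for c in FILTER_CATEGORIES}
    )

    def percentages(self) -> dict[str, float]:
        if self.total == 0:
            return {c: 0.0 for c in FILTER_CATEGORIES}
        return {c: 100.0 * self.counts[c] / self.total for c in FILTER_CATEGORIES}

    def validate(self) -> None:
        if sum(self.counts.values()) != self.total:
            raise AssertionError("filter accounting does not sum to total")

    def to_frame(self) -> pd.DataFrame:
        pct = self.percentages()
        return pd.DataFrame(
            {
                "category": list(FILTER_CATEGORIES),
                "reads": [self.counts[c] for c in FILTER_CATEGORIES],
                "percent": [pct[c] for c in FILTER_CATEGORIES],
            }
        )

    def to_tsv(self, path) -> None:
        df = self.to_frame()
        df.loc[len(df)] = ["total", self.total, 100.0]
        df.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class CleanTag:
    """A unique adapter-trimmed insert with per-sample counts."""

    sequence: str
    counts: Mapping[str, int]
    category: str = "unann"
    excluded: bool = False  # rRNA/tRNA-class tags are excluded downstream

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def _as_sample_map(
    reads: Mapping[str, Sequence[ReadRecord]] | Sequence[ReadRecord],
) -> Mapping[str, Sequence[ReadRecord]]:
    if isinstance(reads, Mapping):
        return reads
    return {"S1": list(reads)}


def filter_reads(
    reads: Mapping[str, Sequence[ReadRecord]] | Sequence[ReadRecord],
    adapter_3p: str,
    adapter_5p: str,
    quality: QualityPolicy | None = None,
    polya: PolyAPolicy | None = None,
    min_insert: int = MIN_INSERT,
    max_insert: int = MAX_INSERT,
    adapter_match_len: int = 8,
) -> tuple[dict[str, list[str]], FilterReport]:
    """Run the ordered filter cascade over per-sample reads.

    Adapters are matched as exact substrings of their first
    ``adapter_match_len`` bases; the insert is the sequence strictly
    before the first 3' adapter occurrence.  Returns the surviving insert
    strings per sample and the accounting report (whose ``clean_tags``
    entry still includes reads that the later frequency filter may drop —
    :func:`collapse_tags` finalises it).
    """
    if not adapter_3p or not adapter_5p:
        raise ValueError("adapter sequences must be non-empty")
    quality = quality or QualityPolicy()
    polya = polya or PolyAPolicy()
    key3 = adapter_3p[:adapter_match_len].upper()
    key5 = adapter_5p[:adapter_match_len].upper()

    per_sample = _as_sample_map(reads)
    report = FilterReport()
    inserts: dict[str, list[str]] = {s: [] for s in per_sample}
    for sample, sample_reads in per_sample.items():
        for read in sample_reads:
            report.total += 1
            seq = read.sequence.upper()
            if quality.is_low_quality(read):
                report.counts["low_quality"] += 1
                continue
            pos = seq.find(key3)
            if pos < 0:
                report.counts["adapter3_null"] += 1
                continue
            insert = seq[:pos]
            if key5 in insert:
                report.counts["adapter5_hit"] += 1
                continue
            if len(insert) < min_insert:
                report.counts["insert_too_short"] += 1
                continue
            if len(insert) > max_insert:
                report.counts["insert_too_long"] += 1
                continue
            if polya.is_polya(insert):
                report.counts["polyA"] += 1
                continue
            report.counts["clean_tags"] += 1
            inserts[sample].append(insert)
    report.validate()
    return inserts, report


def collapse_tags(
    inserts: Mapping[str, Sequence[str]],
    report: FilterReport | None = None,
    min_total: int = 2,
) -> tuple[list[CleanTag], FilterReport]:
    """Collapse identical inserts into tags and apply the frequency filter.

    Tags with summed count across ALL samples below ``min_total`` are
    dropped and their reads moved to ``low_frequency`` in the report.
    Output is sorted by total count descending, ties lexicographically.
    """
    samples = list(inserts)
    per_sample_counts = {s: Counter(inserts[s]) for s in samples}
    all_seqs = set().union(*per_sample_counts.values()) if samples else set()

    if report is None:
        report = FilterReport(total=sum(len(v) for v in inserts.values()))
        report.counts["clean_tags"] = report.total

    tags: list[CleanTag] = []
    for seq in all_seqs:
        counts = {s: per_sample_counts[s].get(seq, 0) for s in samples}
        tag = CleanTag(sequence=seq, counts=counts)
        if tag.total < min_total:
            report.counts["low_frequency"] += tag.total
            report.counts["clean_tags"] -= tag.total
        else:
            tags.append(tag)
    tags.sort(key=lambda t: (-t.total, t.sequence))
    report.validate()
    return tags, report


Lookup = Collection[str] | Callable[[str], bool]


def _matches(seq: str, lookup: Lookup) -> bool:
    if callable(lookup):
        return bool(lookup(seq))
    return seq in lookup


def _edit_match(seq: str, refs: Iterable[str], seed_span: tuple[int, int] = (2, 7)) -> bool:
    """One substitution relative to a reference, outside the seed (1-based
    positions ``seed_span`` inclusive)."""
    lo, hi = seed_span
    for ref in refs:
        if len(ref) != len(seq):
            continue
        mismatches = [i for i, (a, b) in enumerate(zip(seq, ref), start=1) if a != b]
        if len(mismatches) == 1 and not (lo <= mismatches[0] <= hi):
            return True
    return False


def annotate_tags(
    tags: Sequence[CleanTag],
    sources: Mapping[str, Lookup],
) -> list[CleanTag]:
    """Assign each tag its single highest-priority matching category.

    ``sources`` maps category names (subset of :data:`ANNOTATION_PRIORITY`)
    to membership lookups — a container of sequences or a predicate.  The
    ``exist_miRNA_edit`` category is derived from the ``exist_miRNA``
    source (one substitution outside seed positions 2–7) when no explicit
    lookup is supplied.  Unmatched tags become ``unann``; rRNA-class tags
    are flagged excluded from quantification.
    """
    unknown = set(sources) - set(ANNOTATION_PRIORITY)
    if unknown:
        raise ValueError(f"unknown annotation categories: {sorted(unknown)}")

    exist = sources.get("exist_miRNA")
    annotated: list[CleanTag] = []
    for tag in tags:
        category = "unann"
        for cat in ANNOTATION_PRIORITY:
            if cat == "exist_miRNA_edit" and cat not in sources:
                if exist is not None and not callable(exist) and _edit_match(
                    tag.sequence, exist
                ):
                    category = cat
                    break
                continue
            if cat in sources and _matches(tag.sequence, sources[cat]):
                category = cat
                break
        annotated.append(
            replace(tag, category=category, excluded=(category == "rRNA_etc"))
        )
    return annotated


def length_distribution(tags: Sequence[CleanTag]) -> dict[int, int]:
    """Histogram of insert lengths 18..30, weighted by total tag counts."""
    hist = {length: 0 for length in range(MIN_INSERT, MAX_INSERT + 1)}
    for tag in tags:
        n = len(tag.sequence)
        if n in hist:
            hist[n] += tag.total
        else:
            warnings.warn(f"tag of unexpected length {n} ignored", stacklevel=2)
    return hist


def quantify_mirna_tags(tags: Sequence[CleanTag]) -> pd.DataFrame:
    """Count matrix (tag sequence x sample) over miRNA-class tags only."""
    mirna_tags = [t for t in tags if t.category in MIRNA_CATEGORIES and not t.excluded]
    if not mirna_tags:
        return pd.DataFrame()
    samples = sorted({s for t in mirna_tags for s in t.counts})
    data = {t.sequence: [t.counts.get(s, 0) for s in samples] for t in mirna_tags}
    return pd.DataFrame.from_dict(data, orient="index", columns=samples)
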