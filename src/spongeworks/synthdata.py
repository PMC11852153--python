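"""Synthetic study generator with planted, fully recorded ground truth.

Two generators cover the two halves of the pipeline:

* :func:`simulate_reads` emits raw small-RNA reads whose composition over
  the filter categories is known exactly — each read is constructed to
  trip precisely one filter (or none), so the downstream filter report
  can be checked against the truth to the read.

* :func:`simulate_expression` emits negative-binomial count matrices for
  the four RNA classes over a two-group (HF/LF) design with two planted
  signal axes: differential miRNAs whose group means differ by a chosen
  log2 fold change, and sponge triplets (sponge RNA, miRNA, mRNA) in
  which both RNAs track the miRNA's per-sample log-expression with a
  negative slope, making each arm anti-correlated with the miRNA and the
  two arms positively co-expressed.  Regulation acts on the log-mean, so
  ``noise_sd`` directly controls how recoverable the planted structure
  is; at ``noise_sd = 0`` and ``nb_dispersion = 0`` (counts equal to
  their means) the planted correlations are exactly -1 / +1.

:func:`simulate_sequences` adds miRNA and transcript sequences in which
every planted (miRNA, target) arm carries a canonical 8mer seed site, so
the seed-match predictor can run end-to-end on synthetic data.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .smallrna import FILTER_CATEGORIES, MAX_INSERT, MIN_INSERT, ReadRecord
from .targeting import revcomp

__all__ = [
    "SimConfig",
    "SimTruth",
    "ReadSetFixture",
    "SyntheticStudy",
    "DEFAULT_ADAPTER_3P",
    "DEFAULT_ADAPTER_5P",
    "simulate_expression",
    "simulate_sequences",
    "simulate_study",
    "simulate_reads",
    "simulate_null_counts",
    "write_fastq",
]

# Illumina TruSeq small-RNA adapters; any non-degenerate pair works.
DEFAULT_ADAPTER_3P = "TGGAATTCTCGGGTGCCAAGG"
DEFAULT_ADAPTER_5P = "GTTCAGAGTTCTACAGTCCGACGATC"

#: sequence-less mRNA row that keeps the expected library size constant
FILLER_ID = "gene-0000-depth"

#: accepted aliases for read-composition categories
_CATEGORY_ALIASES = {
    "clean": "clean_tags",
    "singleton": "low_frequency",
    "no_3prime_adapter": "adapter3_null",
    "has_5prime_adapter": "adapter5_hit",
    "short_insert": "insert_too_short",
    "long_insert": "insert_too_long",
}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic two-group design.

    Defaults emulate a 4-vs-4 high/low fat-rate comparison: 20 miRNAs,
    200 mRNAs, 50 lncRNAs and 30 circRNAs; 10 differential miRNAs at
    log2FC 2; 10 planted sponge triplets whose regulation slope and
    per-sample miRNA spread are calibrated so that each planted arm has a
    population anti-correlation near -0.9 at ``noise_sd = 0.2``.
    """

    n_samples_per_group: int = 4
    n_mirna: int = 20
    n_mrna: int = 200
    n_lncrna: int = 50
    n_circrna: int = 30
    n_planted_de_mirna: int = 10
    de_log2fc: float = 2.0
    n_planted_triplets: int = 10
    regulation_slope: float = 3.0
    noise_sd: float = 0.2
    nb_dispersion: float = 0.02
    mean_log2_expression_range: tuple[float, float] = (6.0, 10.0)
    mirna_sample_log2_sd: float = 0.7
    transcript_length: int = 150
    mirna_length: int = 22
    size_factors: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_samples_per_group,
            self.n_mirna,
            self.n_mrna,
            self.n_lncrna,
            self.n_circrna,
            self.n_planted_de_mirna,
            self.n_planted_triplets,
        )
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be non-negative")
        if self.n_samples_per_group == 0:
            raise ValueError("need at least one sample per group")
        if self.n_planted_triplets > self.n_mirna:
            raise ValueError("cannot plant more triplets than miRNAs")
        if self.n_planted_de_mirna + self.n_planted_triplets > self.n_mirna:
            raise ValueError(
                "differential and sponge miRNAs are disjoint sets; "
                "their sum cannot exceed n_mirna"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        n_lnc_arms = (self.n_planted_triplets + 1) // 2
        n_circ_arms = self.n_planted_triplets // 2
        if (
            self.n_planted_triplets > self.n_mrna
            or n_lnc_arms > self.n_lncrna
            or n_circ_arms > self.n_circrna
        ):
            raise ValueError("not enough RNAs to host the planted triplets")

    @property
    def n_samples(self) -> int:
        return 2 * self.n_samples_per_group

    def sample_ids(self) -> list[str]:
        n = self.n_samples_per_group
        return [f"HF-{i + 1}" for i in range(n)] + [f"LF-{i + 1}" for i in range(n)]

    def groups(self) -> pd.Series:
        return pd.Series(
            {s: ("HF" if s.startswith("HF") else "LF") for s in self.sample_ids()}
        )


@dataclass
class SimTruth:
    """Answer key for one simulated study."""

    de_mirnas: dict[str, str] = field(default_factory=dict)  # id -> up/down
    triplets: list[tuple[str, str, str]] = field(default_factory=list)
    read_composition: dict[str, int] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "de_mirnas": self.de_mirnas,
            "triplets": [list(t) for t in self.triplets],
            "read_composition": self.read_composition,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    def triplet_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.triplets, columns=["rna_a", "mirna", "rna_b"])


@dataclass
class ReadSetFixture:
    """Raw reads of known composition, ready to feed the filter cascade."""

    reads: dict[str, list[ReadRecord]]
    adapter_3p: str
    adapter_5p: str
    truth: SimTruth
    intended_fate: dict[str, str] = field(default_factory=dict)  # read id -> category

    @property
    def all_reads(self) -> list[ReadRecord]:
        return [r for sample in self.reads.values() for r in sample]


def _log2_means(config: SimConfig, rng: np.random.Generator) -> tuple[dict, SimTruth]:
    """Per-feature, per-sample log2 mean expression plus the truth record."""
    n = config.n_samples
    lo, hi = config.mean_log2_expression_range

    ids = {
        "miRNA": [f"miR-{i + 1:03d}" for i in range(config.n_mirna)],
        "mRNA": [f"gene-{i + 1:04d}" for i in range(config.n_mrna)],
        "lncRNA": [f"lnc-{i + 1:03d}" for i in range(config.n_lncrna)],
        "circRNA": [f"circ-{i + 1:03d}" for i in range(config.n_circrna)],
    }
    means = {
        cls: np.tile(rng.uniform(lo, hi, size=len(ids[cls]))[:, None], (1, n))
        for cls in ids
    }
    truth = SimTruth()

    # axis 1: differential miRNAs, alternating direction, full effect split
    # symmetrically between the groups so the baseline stays the overall mean
    half = np.r_[
        np.full(config.n_samples_per_group, 0.5),
        np.full(config.n_samples_per_group, -0.5),
    ]
    for k in range(config.n_planted_de_mirna):
        direction = "up" if k % 2 == 0 else "down"
        sign = 1.0 if direction == "up" else -1.0
        means["miRNA"][k] += sign * config.de_log2fc * half
        truth.de_mirnas[ids["miRNA"][k]] = direction

    # axis 2: sponge triplets on the next block of miRNAs
    lnc_i = circ_i = 0
    for t in range(config.n_planted_triplets):
        mi = config.n_planted_de_mirna + t
        eta = rng.normal(0.0, config.mirna_sample_log2_sd, size=n)
        means["miRNA"][mi] += eta
        x = means["miRNA"][mi]
        x_centered = x - x.mean()
        if t % 2 == 0:
            a_cls, a_idx = "lncRNA", lnc_i
            lnc_i += 1
        else:
            a_cls, a_idx = "circRNA", circ_i
            circ_i += 1
        for cls, idx in ((a_cls, a_idx), ("mRNA", t)):
            noise = rng.normal(0.0, config.noise_sd, size=n) if config.noise_sd else 0.0
            means[cls][idx] = (
                means[cls][idx].mean()
                - config.regulation_slope * x_centered
                + noise
            )
        truth.triplets.append(
            (ids[a_cls][a_idx], ids["miRNA"][mi], ids["mRNA"][t])
        )

    return {"ids": ids, "means": means}, truth


def _draw_counts(
    log2_means: np.ndarray,
    dispersion: float,
    size_factors: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """NB draws around the given means.

    In the deterministic limit ``dispersion = 0`` the expected counts
    themselves are returned (fractional, not rounded), so planted
    monotone relations survive exactly.
    """
    clipped = np.clip(log2_means, -4.0, 20.0)
    if (clipped != log2_means).any():
        warnings.warn(
            "log2 means clipped to [-4, 20]; reduce regulation_slope or "
            "narrow the mean range",
            stacklevel=3,
        )
    mu = np.power(2.0, clipped) * size_factors[None, :]
    if dispersion == 0.0:
        return mu
    r = 1.0 / dispersion
    p = r / (r + mu)
    return rng.negative_binomial(r, p).astype(np.int64)


def simulate_expression(
    config: SimConfig,
) -> tuple[dict[str, ExpressionMatrix], SimTruth]:
    """Draw per-class count matrices and the planted truth.

    Same config (including seed) reproduces identical output.
    """
    rng = np.random.default_rng(config.seed)
    layout, truth = _log2_means(config, rng)
    groups = config.groups()
    samples = config.sample_ids()
    sf = (
        np.asarray(config.size_factors, dtype=float)
        if config.size_factors is not None
        else np.ones(config.n_samples)
    )
    if sf.size != config.n_samples or (sf <= 0).any():
        raise ValueError("size_factors must be positive, one per sample")

    # Joint construction over the stacked classes.  A depth-filler mRNA
    # absorbs the mass the planted features move around, holding the
    # expected library size exactly constant across samples (equal
    # sequencing depth); TPM is then, in expectation, one global
    # rescaling of the means, so planted monotone structure survives
    # normalisation — exactly so in the deterministic limit.
    order = ("miRNA", "mRNA", "lncRNA", "circRNA")
    stacked = np.vstack([layout["means"][cls] for cls in order])
    linear = np.power(2.0, np.clip(stacked, -4.0, 20.0))
    depth = linear.sum(axis=0)
    filler_mu = 1.05 * depth.max() - depth
    filler_log2 = np.log2(np.maximum(filler_mu, 1.0))[None, :]

    counts = _draw_counts(
        np.vstack([stacked, filler_log2]), config.nb_dispersion, sf, rng
    )
    matrices: dict[str, ExpressionMatrix] = {}
    offset = 0
    for cls in order:
        cls_ids = list(layout["ids"][cls])
        rows = counts[offset : offset + len(cls_ids)]
        offset += len(cls_ids)
        if cls == "mRNA":
            rows = np.vstack([rows, counts[-1]])
            cls_ids = cls_ids + [FILLER_ID]
        values = pd.DataFrame(rows, index=cls_ids, columns=samples)
        classes = pd.Series(cls, index=values.index)
        matrices[cls] = ExpressionMatrix(values, classes, groups, kind="counts")
    return matrices, truth


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def simulate_sequences(
    config: SimConfig,
    truth: SimTruth,
    transcript_ids: Sequence[str],
) -> tuple[dict[str, str], dict[str, str]]:
    """Random miRNA/transcript sequences with planted 8mer sites.

    Each planted (miRNA, target) arm receives one canonical 8mer site
    (reverse complement of miRNA positions 2–8 followed by 'A') at a
    random position of the target; miRNA seed hexamers are kept distinct
    so planted sites are unambiguous.  Chance seed matches elsewhere are
    left in place — they are part of what the screens must reject.
    """
    rng = np.random.default_rng([config.seed, 104729])
    mirna_ids = [f"miR-{i + 1:03d}" for i in range(config.n_mirna)]
    mirnas: dict[str, str] = {}
    seen_cores: set[str] = set()
    for mid in mirna_ids:
        while True:
            seq = _random_seq(rng, config.mirna_length)
            core = seq[1:7]
            if core not in seen_cores:
                seen_cores.add(core)
                mirnas[mid] = seq
                break

    transcripts = {
        tid: _random_seq(rng, config.transcript_length) for tid in transcript_ids
    }
    for rna_a, mirna_id, rna_b in truth.triplets:
        site = revcomp(mirnas[mirna_id][1:8]) + "A"
        for tid in (rna_a, rna_b):
            seq = transcripts[tid]
            pos = int(rng.integers(0, len(seq) - len(site) + 1))
            transcripts[tid] = seq[:pos] + site + seq[pos + len(site):]
    return mirnas, transcripts


@dataclass
class SyntheticStudy:
    """One complete simulated study: matrices, sequences and truth."""

    config: SimConfig
    matrices: dict[str, ExpressionMatrix]
    expression: ExpressionMatrix  # all classes stacked, raw counts
    mirna_seqs: dict[str, str]
    transcript_seqs: dict[str, str]
    truth: SimTruth


def simulate_study(config: SimConfig) -> SyntheticStudy:
    """Expression plus sequences, bundled for end-to-end runs."""
    matrices, truth = simulate_expression(config)
    combined = ExpressionMatrix.concat(
        [matrices[c] for c in ("miRNA", "mRNA", "lncRNA", "circRNA")]
    )
    transcript_ids = [
        fid
        for c in ("mRNA", "lncRNA", "circRNA")
        for fid in matrices[c].values.index
        if fid != FILLER_ID  # the depth filler has no sequence
    ]
    mirnas, transcripts = simulate_sequences(config, truth, transcript_ids)
    return SyntheticStudy(
        config=config,
        matrices=matrices,
        expression=combined,
        mirna_seqs=mirnas,
        transcript_seqs=transcripts,
        truth=truth,
    )


def simulate_null_counts(
    n_features: int,
    n_samples_per_group: int = 4,
    mean_log2_range: tuple[float, float] = (3.0, 7.0),
    dispersion: float = 0.1,
    seed: int = 0,
) -> ExpressionMatrix:
    """NB counts with no group difference at all (type-I error harness)."""
    rng = np.random.default_rng(seed)
    n = 2 * n_samples_per_group
    mu = np.power(
        2.0, rng.uniform(*mean_log2_range, size=n_features)
    )[:, None] * np.ones((1, n))
    if dispersion == 0.0:
        counts = np.rint(mu).astype(np.int64)
    else:
        r = 1.0 / dispersion
        counts = rng.negative_binomial(r, r / (r + mu)).astype(np.int64)
    samples = [f"HF-{i + 1}" for i in range(n_samples_per_group)] + [
        f"LF-{i + 1}" for i in range(n_samples_per_group)
    ]
    values = pd.DataFrame(
        counts, index=[f"f{i + 1:05d}" for i in range(n_features)], columns=samples
    )
    groups = pd.Series({s: s.split("-")[0] for s in samples})
    return ExpressionMatrix(values, pd.Series("miRNA", index=values.index), groups)


# ---------------------------------------------------------------------------
# raw-read fixtures


class _InsertFactory:
    """Generates inserts guaranteed to reach (only) their intended filter."""

    def __init__(self, rng: np.random.Generator, key3: str, key5: str):
        self.rng = rng
        self.key3 = key3
        self.key5 = key5
        self.used: set[str] = set()

    def _ok(self, seq: str, unique: bool) -> bool:
        if self.key3 in seq or self.key5 in seq:
            return False
        if seq and seq.count("A") >= 0.8 * len(seq):
            return False
        if "A" * 10 in seq:
            return False
        if unique and seq in self.used:
            return False
        return True

    def fresh(self, length: int, unique: bool = True) -> str:
        if length == 0:
            return ""
        for _ in range(1000):
            seq = _random_seq(self.rng, length)
            if self._ok(seq, unique):
                if unique:
                    self.used.add(seq)
                return seq
        raise RuntimeError("could not generate a compliant insert")

    def with_key5(self, length: int) -> str:
        for _ in range(1000):
            pad = length - len(self.key5)
            cut = int(self.rng.integers(0, pad + 1))
            seq = (
                _random_seq(self.rng, cut)
                + self.key5
                + _random_seq(self.rng, pad - cut)
            )
            if self.key3 not in seq and seq.count("A") < 0.8 * len(seq) and "A" * 10 not in seq:
                return seq
        raise RuntimeError("could not generate a 5'-adapter insert")


def _canonical_composition(composition: Mapping[str, int]) -> dict[str, int]:
    canon = {c: 0 for c in FILTER_CATEGORIES}
    for raw_key, count in composition.items():
        key = _CATEGORY_ALIASES.get(raw_key, raw_key)
        if key not in canon:
            raise ValueError(f"unknown read category {raw_key!r}")
        if count < 0:
            raise ValueError("composition counts must be non-negative")
        canon[key] += int(count)
    return canon


def simulate_reads(
    config: SimConfig,
    composition: Mapping[str, int],
    adapter_3p: str = DEFAULT_ADAPTER_3P,
    adapter_5p: str = DEFAULT_ADAPTER_5P,
    insert_length_range: tuple[int, int] = (MIN_INSERT, MAX_INSERT),
    read_length: int = 50,
    adapter_match_len: int = 8,
) -> ReadSetFixture:
    """Emit FASTQ-writable reads matching ``composition`` exactly.

    Category names follow the filter report (aliases such as ``clean``,
    ``singleton``, ``short_insert`` are accepted).  Clean reads are built
    as duplicated inserts so they survive the frequency filter, which is
    why a clean count of exactly 1 is rejected.
    """
    canon = _canonical_composition(composition)
    if canon["clean_tags"] == 1:
        raise ValueError("a single clean read cannot survive the frequency filter")
    rng = np.random.default_rng([config.seed, 7919])
    key3 = adapter_3p[:adapter_match_len]
    key5 = adapter_5p[:adapter_match_len]
    factory = _InsertFactory(rng, key3, key5)
    lo, hi = insert_length_range

    good_q = "".join(chr(33 + int(q)) for q in [38] * read_length)

    def _pad(core: str) -> str:
        tail_len = max(0, read_length - len(core))
        return (core + _random_seq(rng, tail_len))[:read_length]

    def _make(category: str, serial: int) -> ReadRecord:
        rid = f"{category}:{serial}"
        if category == "adapter3_null":
            for _ in range(1000):
                seq = _random_seq(rng, read_length)
                if key3 not in seq:
                    break
            return ReadRecord(rid, seq, good_q[: len(seq)])
        if category == "low_quality":
            insert = factory.fresh(int(rng.integers(lo, hi + 1)), unique=False)
            seq = _pad(insert + adapter_3p)
            n_bad = int(0.4 * len(seq))
            qual = "#" * n_bad + good_q[: len(seq) - n_bad]
            return ReadRecord(rid, seq, qual)
        if category == "adapter5_hit":
            insert = factory.with_key5(int(rng.integers(max(lo, 12), hi + 1)))
        elif category == "insert_too_short":
            insert = factory.fresh([0, 10, 17][serial % 3], unique=False)
        elif category == "insert_too_long":
            insert = factory.fresh(int(rng.integers(hi + 1, hi + 11)), unique=False)
        elif category == "polyA":
            insert = "A" * int(rng.integers(lo, hi + 1))
        else:
            raise AssertionError(category)
        seq = _pad(insert + adapter_3p)
        return ReadRecord(rid, seq, good_q[: len(seq)])

    reads: list[ReadRecord] = []
    intended: dict[str, str] = {}

    # clean tags: distinct inserts duplicated to total frequency >= 2
    remaining = canon["clean_tags"]
    serial = 0
    while remaining > 0:
        freq = 3 if remaining == 3 else 2
        insert = factory.fresh(int(rng.integers(lo, hi + 1)))
        for _ in range(freq):
            rid = f"clean_tags:{serial}"
            reads.append(ReadRecord(rid, _pad(insert + adapter_3p), good_q))
            intended[rid] = "clean_tags"
            serial += 1
        remaining -= freq

    # singletons: unique inserts seen exactly once in the whole run
    for serial in range(canon["low_frequency"]):
        rid = f"low_frequency:{serial}"
        insert = factory.fresh(int(rng.integers(lo, hi + 1)))
        reads.append(ReadRecord(rid, _pad(insert + adapter_3p), good_q))
        intended[rid] = "low_frequency"

    for category in (
        "low_quality",
        "adapter3_null",
        "adapter5_hit",
        "insert_too_short",
        "insert_too_long",
        "polyA",
    ):
        for serial in range(canon[category]):
            read = _make(category, serial)
            reads.append(read)
            intended[read.id] = category

    # scatter across the samples of the design
    samples = config.sample_ids()
    per_sample: dict[str, list[ReadRecord]] = {s: [] for s in samples}
    assignment = rng.integers(0, len(samples), size=len(reads))
    for read, si in zip(reads, assignment):
        per_sample[samples[si]].append(read)

    truth = SimTruth(read_composition=canon)
    total = sum(canon.values())
    assert total == len(reads), "composition must sum to the reads emitted"
    return ReadSetFixture(
        reads=per_sample,
        adapter_3p=adapter_3p,
        adapter_5p=adapter_5p,
        truth=truth,
        intended_fate=intended,
    )


def write_fastq(fixture: ReadSetFixture, outdir: str | Path) -> dict[str, Path]:
    """One Sanger-encoded FASTQ per sample; returns the written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for sample, reads in fixture.reads.items():
        path = outdir / f"{sample}.fastq"
        with open(path, "w") as fh:
            for read in reads:
                fh.write(f"@{read.id}\n{read.sequence}\n+\n{read.quality}\n")
        paths[sample] = path
    return paths
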