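"""Seed-match target prediction and the anti-correlation screen.

Canonical site vocabulary (positions are miRNA positions, 5'->3'):

* 6mer     — transcript carries the reverse complement of miRNA 2–7.
* 7mer-m8  — 6mer plus a match to miRNA position 8 immediately 5' of the
  core on the transcript.
* 7mer-A1  — 6mer plus an 'A' on the transcript opposite miRNA position 1
  (an A regardless of the miRNA base, per the canonical definition).
* 8mer     — both extensions.

Predicted (miRNA, RNA) pairs — optionally intersected across several
prediction sources — are then screened for expression anti-correlation:
only pairs with Spearman rho <= -0.6 (inclusive, configurable) across the
pooled samples are kept as candidate sponge arms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import reduce
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

from .corr import average_ranks, pairwise_pearson
from .expression import ExpressionMatrix

__all__ = [
    "TargetSite",
    "NegCorrEdge",
    "SITE_TYPES",
    "DEFAULT_SITE_TYPES",
    "revcomp",
    "find_seed_sites",
    "predict_targets",
    "intersect_predictions",
    "spearman_screen",
]

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")
#: 6mer-only sites are excluded from the default candidate set to keep the
#: predictor conservative (approximating a multi-tool intersection).
DEFAULT_SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _normalize(seq: str) -> str:
    seq = seq.upper().replace("U", "T")
    if set(seq) - set("ACGTN"):
        raise ValueError(f"invalid nucleotide alphabet in {seq[:20]!r}...")
    return seq


def revcomp(seq: str) -> str:
    return _normalize(seq).translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TargetSite:
    """One canonical seed-match site on a transcript.

    ``position`` is the 1-based start of the 6mer seed-core match.
    """

    mirna_id: str
    transcript_id: str
    site_type: Literal["8mer", "7mer-m8", "7mer-A1", "6mer"]
    position: int


@dataclass(frozen=True)
class NegCorrEdge:
    """A predicted miRNA->RNA pair surviving the Spearman screen."""

    mirna_id: str
    rna_id: str
    rna_class: Literal["mRNA", "lncRNA", "circRNA"]
    spearman_rho: float


def find_seed_sites(
    mirna_seq: str,
    transcript_seq: str,
    mirna_id: str = "miRNA",
    transcript_id: str = "transcript",
) -> list[TargetSite]:
    """All canonical seed sites of one miRNA on one transcript."""
    mirna = _normalize(mirna_seq)
    transcript = _normalize(transcript_seq)
    if len(mirna) < 8:
        raise ValueError("miRNA must be at least 8 nt")
    core = revcomp(mirna[1:7])  # reverse complement of seed 2-7
    m8_base = mirna[7].translate(_COMPLEMENT)

    sites: list[TargetSite] = []
    start = transcript.find(core)
    while start >= 0:
        has_m8 = start >= 1 and transcript[start - 1] == m8_base
        a1_pos = start + 6
        has_a1 = a1_pos < len(transcript) and transcript[a1_pos] == "A"
        if has_m8 and has_a1:
            site_type = "8mer"
        elif has_m8:
            site_type = "7mer-m8"
        elif has_a1:
            site_type = "7mer-A1"
        else:
            site_type = "6mer"
        sites.append(TargetSite(mirna_id, transcript_id, site_type, start + 1))
        start = transcript.find(core, start + 1)
    return sites


def predict_targets(
    mirnas: Mapping[str, str],
    transcripts: Mapping[str, str],
    site_types: Sequence[str] = DEFAULT_SITE_TYPES,
) -> tuple[set[tuple[str, str]], dict[tuple[str, str], list[TargetSite]]]:
    """Seed-scan every miRNA against every transcript.

    Returns the candidate (mirna_id, rna_id) pairs having at least one
    site of an accepted type, plus the per-pair site lists.
    """
    bad = set(site_types) - set(SITE_TYPES)
    if bad:
        raise ValueError(f"unknown site types: {sorted(bad)}")
    accepted = set(site_types)
    pairs: set[tuple[str, str]] = set()
    sites: dict[tuple[str, str], list[TargetSite]] = {}
    for mid, mseq in mirnas.items():
        for tid, tseq in transcripts.items():
            found = find_seed_sites(mseq, tseq, mid, tid)
            if found:
                sites[(mid, tid)] = found
            if any(s.site_type in accepted for s in found):
                pairs.add((mid, tid))
    return pairs, sites


def intersect_predictions(
    prediction_sets: Sequence[Iterable[tuple[str, str]]],
) -> set[tuple[str, str]]:
    """Pairs present in every prediction source."""
    if not prediction_sets:
        raise ValueError("need at least one prediction set")
    return reduce(lambda a, b: a & b, (set(s) for s in prediction_sets))


def spearman_screen(
    pairs: Iterable[tuple[str, str]],
    expr: ExpressionMatrix,
    threshold: float = -0.6,
) -> list[NegCorrEdge]:
    """Keep pairs whose Spearman correlation is <= ``threshold``.

    Correlations are computed on the pooled samples of ``expr`` (TPM,
    both groups together), with average ranks for ties.  Pairs involving
    a constant expression vector are skipped with a warning.
    """
    pair_list = sorted(set(pairs))
    if not pair_list:
        return []
    ids = sorted({i for p in pair_list for i in p})
    missing = [i for i in ids if i not in expr.values.index]
    if missing:
        raise KeyError(f"features absent from expression matrix: {missing[:5]}")
    sub = expr.values.loc[ids].to_numpy()
    ranks = np.apply_along_axis(average_ranks, 1, sub)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = pairwise_pearson(ranks, ranks)
    row = {fid: k for k, fid in enumerate(ids)}

    edges: list[NegCorrEdge] = []
    for mid, rid in pair_list:
        r = rho[row[mid], row[rid]]
        if np.isnan(r):
            warnings.warn(
                f"constant expression for ({mid}, {rid}); pair skipped",
                stacklevel=2,
            )
            continue
        if r <= threshold:
            edges.append(
                NegCorrEdge(
                    mirna_id=mid,
                    rna_id=rid,
                    rna_class=str(expr.feature_class[rid]),
                    spearman_rho=float(r),
                )
            )
    return edges
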