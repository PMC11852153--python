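"""Hypergeometric over-representation analysis over GMT gene sets.

Given a query gene list (typically the mRNAs of the assembled ceRNA
network), a collection of gene sets and a background universe, each set
is scored with the upper-tail hypergeometric probability
P[X >= k], X ~ Hypergeom(N, K, n), and p-values are adjusted across all
tested terms by Benjamini–Hochberg.  Collections are supplied as GMT;
nothing is fetched from live databases.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["GeneSetResult", "GeneSet", "read_gmt", "write_gmt", "ora", "results_frame"]


@dataclass(frozen=True)
class GeneSet:
    term_id: str
    term_name: str
    genes: frozenset[str]


@dataclass
class GeneSetResult:
    """One term's over-representation statistics."""

    term_id: str
    term_name: str
    k: int  # query hits in the set
    K: int  # set size within the universe
    n: int  # query size
    N: int  # universe size
    p_value: float
    q_value: float = float("nan")


def read_gmt(path: str | Path) -> list[GeneSet]:
    sets: list[GeneSet] = []
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            sets.append(GeneSet(fields[0], fields[1], frozenset(fields[2:])))
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.term_id, s.term_name, *sorted(s.genes)]) + "\n")


def ora(
    query: Iterable[str],
    collections: Sequence[GeneSet] | Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> list[GeneSetResult]:
    """Over-representation of ``query`` in each gene set.

    Sets are intersected with the universe before testing; the query must
    be a subset of the universe.  Results are BH-adjusted over all tested
    terms and sorted by p-value (ties by term id).
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("empty universe")
    query_set = set(query)
    if not query_set:
        raise ValueError("empty query")
    if not query_set <= universe_set:
        extra = sorted(query_set - universe_set)
        raise ValueError(f"query genes outside the universe: {extra[:5]}")

    if isinstance(collections, Mapping):
        collections = [
            GeneSet(term, term, frozenset(genes)) for term, genes in collections.items()
        ]

    N, n = len(universe_set), len(query_set)
    results: list[GeneSetResult] = []
    for gene_set in collections:
        members = gene_set.genes & universe_set
        K = len(members)
        if K == 0:
            continue
        k = len(query_set & members)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        results.append(
            GeneSetResult(gene_set.term_id, gene_set.term_name, k, K, n, N, min(p, 1.0))
        )
    if results:
        _, q, _, _ = multipletests([r.p_value for r in results], method="fdr_bh")
        for r, qv in zip(results, q):
            r.q_value = float(qv)
    results.sort(key=lambda r: (r.p_value, r.term_id))
    return results


def results_frame(results: Sequence[GeneSetResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "term_id": [r.term_id for r in results],
            "term_name": [r.term_name for r in results],
            "k": [r.k for r in results],
            "K": [r.K for r in results],
            "n": [r.n for r in results],
            "N": [r.N for r in results],
            "p_value": [r.p_value for r in results],
            "q_value": [r.q_value for r in results],
        }
    )
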