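"""File-format glue: FASTQ/FASTA in, prediction lists in, edges out."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio import SeqIO

from .smallrna import ReadRecord
from .targeting import NegCorrEdge

__all__ = [
    "read_fastq",
    "read_fasta",
    "read_prediction_list",
    "write_edges_tsv",
]


def read_fastq(path: str | Path) -> list[ReadRecord]:
    """Load Sanger (Phred+33) FASTQ reads."""
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        reads.append(ReadRecord(rec.id, str(rec.seq).upper(), qual))
    return reads


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_prediction_list(path: str | Path) -> set[tuple[str, str]]:
    """Two-column TSV (mirna_id, rna_id), no header."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    return {(str(a), str(b)) for a, b in zip(df[0], df[1])}


def write_edges_tsv(edges: Sequence[NegCorrEdge], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "mirna": e.mirna_id,
                "rna": e.rna_id,
                "class": e.rna_class,
                "spearman_rho": e.spearman_rho,
            }
            for e in edges
        ]
    ).to_csv(path, sep="\t", index=False)
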