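"""ceRNA pairing, network assembly, export and recovery scoring.

Two RNAs that are both anti-correlated targets of the same miRNA form a
candidate sponge pair; the pair is accepted as a ceRNA triplet when their
own co-expression (Pearson) exceeds the pairing threshold (strictly,
r > 0.7 by default).  Accepted triplets are assembled into a typed graph
— miRNA->target edges carrying Spearman rho, ceRNA-pair edges carrying
Pearson r and the witnessing miRNAs — exportable as SIF/GraphML plus a
node-attribute table for Cytoscape-style visualisation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .corr import pairwise_pearson
from .expression import ExpressionMatrix
from .targeting import NegCorrEdge

__all__ = [
    "CeRNATriplet",
    "CeRNANetwork",
    "RecoveryScore",
    "pair_cernas",
    "assemble_network",
    "export_network",
    "import_network",
    "score_recovery",
]

SPONGE_CLASSES = ("lncRNA", "circRNA")


@dataclass(frozen=True)
class CeRNATriplet:
    """(sponge RNA, miRNA, mRNA) with its three supporting correlations."""

    rna_a: str
    rna_a_class: str
    mirna_id: str
    rna_b: str
    rna_b_class: str
    rho_a: float
    rho_b: float
    pearson_r: float

    def key(self) -> tuple[str, str, str]:
        return (self.rna_a, self.mirna_id, self.rna_b)


def _transform_expression(
    expr: ExpressionMatrix,
    ids: Sequence[str],
    transform: str,
) -> np.ndarray:
    sub = expr.values.loc[list(ids)].to_numpy(dtype=float)
    if transform == "log2p1":
        return np.log2(sub + 1.0)
    if transform == "raw":
        return sub
    raise ValueError(f"unknown transform {transform!r}")


def pair_cernas(
    edges: Sequence[NegCorrEdge],
    expr: ExpressionMatrix,
    threshold: float = 0.7,
    mode: Literal["lncRNA", "circRNA", "both"] = "both",
    transform: str = "log2p1",
) -> list[CeRNATriplet]:
    """Form ceRNA triplets from screened miRNA->target edges.

    For every miRNA, each (mRNA, sponge) pair among its surviving targets
    is tested for positive co-expression; the Pearson correlation is
    computed on log2(TPM + 1) by default (``transform='raw'`` uses the
    TPM values directly) and pairs with r > ``threshold`` (strict) become
    triplets.  ``mode`` restricts the sponge side to lncRNAs, circRNAs,
    or either.
    """
    sponge_classes = SPONGE_CLASSES if mode == "both" else (mode,)
    by_mirna: dict[str, list[NegCorrEdge]] = {}
    for e in edges:
        by_mirna.setdefault(e.mirna_id, []).append(e)

    triplets: list[CeRNATriplet] = []
    for mirna_id in sorted(by_mirna):
        targets = by_mirna[mirna_id]
        mrnas = [e for e in targets if e.rna_class == "mRNA"]
        sponges = [e for e in targets if e.rna_class in sponge_classes]
        if not mrnas or not sponges:
            continue
        m_ids = [e.rna_id for e in mrnas]
        s_ids = [e.rna_id for e in sponges]
        r_mat = pairwise_pearson(
            _transform_expression(expr, s_ids, transform),
            _transform_expression(expr, m_ids, transform),
        )
        for (i, sponge), (j, mrna) in product(enumerate(sponges), enumerate(mrnas)):
            if sponge.rna_id == mrna.rna_id:
                continue
            r = r_mat[i, j]
            if np.isnan(r):
                warnings.warn(
                    f"constant vector for pair ({sponge.rna_id}, {mrna.rna_id}); skipped",
                    stacklevel=2,
                )
                continue
            if r > threshold:
                triplets.append(
                    CeRNATriplet(
                        rna_a=sponge.rna_id,
                        rna_a_class=sponge.rna_class,
                        mirna_id=mirna_id,
                        rna_b=mrna.rna_id,
                        rna_b_class=mrna.rna_class,
                        rho_a=sponge.spearman_rho,
                        rho_b=mrna.spearman_rho,
                        pearson_r=float(r),
                    )
                )
    triplets.sort(key=lambda t: t.key())
    return triplets


@dataclass
class CeRNANetwork:
    """Typed ceRNA graph plus summary counts."""

    graph: nx.Graph

    def summary(self) -> dict[str, int]:
        classes = nx.get_node_attributes(self.graph, "node_class")
        counts = {"miRNA": 0, "mRNA": 0, "lncRNA": 0, "circRNA": 0}
        for cls in classes.values():
            counts[cls] += 1
        return {
            "n_mirna": counts["miRNA"],
            "n_mrna": counts["mRNA"],
            "n_lncrna": counts["lncRNA"],
            "n_circrna": counts["circRNA"],
            "n_interactions": self.graph.number_of_edges(),
            "n_triplets": len(
                {
                    key
                    for _, _, d in self.graph.edges(data=True)
                    if d["kind"] == "cerna_pair"
                    for key in d["triplets"]
                }
            ),
        }

    def triplet_keys(self) -> set[tuple[str, str, str]]:
        keys: set[tuple[str, str, str]] = set()
        for _, _, d in self.graph.edges(data=True):
            if d["kind"] == "cerna_pair":
                keys.update(tuple(k) for k in d["triplets"])
        return keys

    def validate(self) -> None:
        classes = nx.get_node_attributes(self.graph, "node_class")
        for u, v, d in self.graph.edges(data=True):
            if d["kind"] == "mirna_target":
                kinds = {classes[u], classes[v]}
                if "miRNA" not in kinds or kinds == {"miRNA"}:
                    raise AssertionError("mirna_target edge must join miRNA to non-miRNA")
            elif d["kind"] == "cerna_pair":
                witnesses = {k[1] for k in d["triplets"]}
                if not witnesses or any(w not in classes for w in witnesses):
                    raise AssertionError("cerna_pair edge lacks a witnessing miRNA node")


def assemble_network(triplets: Sequence[CeRNATriplet]) -> CeRNANetwork:
    """Deduplicate triplets into a typed graph with provenance."""
    g = nx.Graph()
    for t in triplets:
        if t.rna_a == t.rna_b:
            raise ValueError(f"degenerate triplet {t.key()}")
        if "mRNA" not in (t.rna_a_class, t.rna_b_class):
            raise ValueError(f"triplet {t.key()} has no mRNA arm")
        g.add_node(t.mirna_id, node_class="miRNA")
        g.add_node(t.rna_a, node_class=t.rna_a_class)
        g.add_node(t.rna_b, node_class=t.rna_b_class)
        g.add_edge(t.mirna_id, t.rna_a, kind="mirna_target", rho=t.rho_a)
        g.add_edge(t.mirna_id, t.rna_b, kind="mirna_target", rho=t.rho_b)
        if g.has_edge(t.rna_a, t.rna_b) and g[t.rna_a][t.rna_b]["kind"] == "cerna_pair":
            d = g[t.rna_a][t.rna_b]
            d["triplets"].append(t.key())
            d["r"] = max(d["r"], t.pearson_r)
        else:
            g.add_edge(t.rna_a, t.rna_b, kind="cerna_pair", r=t.pearson_r, triplets=[t.key()])
    net = CeRNANetwork(graph=g)
    net.validate()
    return net


_SIF_RELATION = {"mirna_target": "targets", "cerna_pair": "cerna"}
_SIF_KIND = {v: k for k, v in _SIF_RELATION.items()}


def export_network(
    net: CeRNANetwork,
    outdir: str | Path,
    formats: Sequence[str] = ("sif", "attrs", "graphml"),
    de_direction: Mapping[str, str] | None = None,
    stem: str = "cerna_network",
) -> dict[str, Path]:
    """Write SIF, node attributes and/or GraphML; returns written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    g = net.graph
    if "sif" in formats:
        path = outdir / f"{stem}.sif"
        with open(path, "w") as fh:
            for u, v, d in sorted(g.edges(data=True), key=lambda e: (e[0], e[1])):
                fh.write(f"{u}\t{_SIF_RELATION[d['kind']]}\t{v}\n")
        written["sif"] = path
    if "attrs" in formats:
        path = outdir / f"{stem}.nodes.tsv"
        classes = nx.get_node_attributes(g, "node_class")
        rows = [
            {
                "id": n,
                "class": classes[n],
                "de_direction": (de_direction or {}).get(n, "ns"),
            }
            for n in sorted(g.nodes)
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        written["attrs"] = path
    if "graphml" in formats:
        path = outdir / f"{stem}.graphml"
        h = nx.Graph()
        for n, d in g.nodes(data=True):
            h.add_node(n, **d)
        for u, v, d in g.edges(data=True):
            attrs = {k: v2 for k, v2 in d.items() if k != "triplets"}
            if "triplets" in d:
                attrs["triplets"] = ";".join(",".join(k) for k in d["triplets"])
            h.add_edge(u, v, **attrs)
        nx.write_graphml(h, path)
        written["graphml"] = path
    return written


def import_network(sif_path: str | Path, attrs_path: str | Path) -> CeRNANetwork:
    """Rebuild a network from a SIF file plus its node-attribute table.

    Triplet provenance is re-derived from the graph structure (a ceRNA
    pair is witnessed by every shared miRNA neighbour), so round-tripping
    preserves isomorphism and edge types.
    """
    attrs = pd.read_csv(attrs_path, sep="\t").set_index("id")
    g = nx.Graph()
    for node, row in attrs.iterrows():
        g.add_node(str(node), node_class=row["class"])
    pairs = []
    with open(sif_path) as fh:
        for line in fh:
            u, rel, v = line.rstrip("\n").split("\t")
            kind = _SIF_KIND[rel]
            if kind == "cerna_pair":
                pairs.append((u, v))
            g.add_edge(u, v, kind=kind)
    classes = nx.get_node_attributes(g, "node_class")
    for u, v in pairs:
        shared = [
            n
            for n in set(g.neighbors(u)) & set(g.neighbors(v))
            if classes[n] == "miRNA"
        ]
        a, b = (u, v) if classes[u] != "mRNA" else (v, u)
        g[u][v]["triplets"] = [(a, m, b) for m in sorted(shared)]
    return CeRNANetwork(graph=g)


@dataclass
class RecoveryScore:
    precision: float
    recall: float
    arm_precision: float
    arm_recall: float
    n_true: int
    n_found: int


def _arm_set(triplets: Iterable[tuple[str, str, str]]) -> set[tuple[str, str]]:
    arms = set()
    for a, m, b in triplets:
        arms.add((m, a))
        arms.add((m, b))
    return arms


def score_recovery(
    found: CeRNANetwork | Sequence[CeRNATriplet],
    true_triplets: Sequence[tuple[str, str, str]],
) -> RecoveryScore:
    """Triplet- and arm-level precision/recall against planted truth.

    Precision over an empty discovery set is undefined and reported as
    NaN with a warning.
    """
    if isinstance(found, CeRNANetwork):
        found_keys = found.triplet_keys()
    else:
        found_keys = {t.key() for t in found}
    truth = {tuple(t) for t in true_triplets}

    def _pr(found_s: set, truth_s: set) -> tuple[float, float]:
        tp = len(found_s & truth_s)
        if not found_s:
            warnings.warn("empty discovery set: precision undefined (NaN)", stacklevel=3)
            precision = float("nan")
        else:
            precision = tp / len(found_s)
        recall = tp / len(truth_s) if truth_s else float("nan")
        return precision, recall

    p, r = _pr(found_keys, truth)
    ap, ar = _pr(_arm_set(found_keys), _arm_set(truth))
    return RecoveryScore(
        precision=p,
        recall=r,
        arm_precision=ap,
        arm_recall=ar,
        n_true=len(truth),
        n_found=len(found_keys),
    )
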