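"""ceRNA pairing vs enumeration oracle, assembly invariants, export."""

import numpy as np
import pandas as pd
import pytest

from spongeworks.expression import ExpressionMatrix
from spongeworks.network import (
    CeRNATriplet,
    assemble_network,
    export_network,
    import_network,
    pair_cernas,
    score_recovery,
)
from spongeworks.targeting import NegCorrEdge


def expr_from(rows: dict, classes: dict):
    df = pd.DataFrame({k: np.asarray(v, dtype=float) for k, v in rows.items()}).T
    df.columns = [f"s{i}" for i in range(df.shape[1])]
    colsums = df.sum(axis=0)
    df.loc["fill"] = colsums.max() * 1.5 - colsums
    df = df * (1e6 / df.sum(axis=0))
    cls = pd.Series({**classes, "fill": "mRNA"})
    groups = pd.Series({c: "HF" for c in df.columns})
    return ExpressionMatrix(df, cls, groups, kind="tpm")


def brute_force_triplets(edges, expr, threshold, transform="log2p1"):
    """Triple loop over every (sponge, miRNA, mRNA) combination, Pearson
    via numpy.corrcoef — independent of the package kernels."""
    found = set()
    classes = expr.feature_class
    vals = expr.values
    for e1 in edges:
        for e2 in edges:
            if e1.mirna_id != e2.mirna_id:
                continue
            if classes[e1.rna_id] not in ("lncRNA", "circRNA"):
                continue
            if classes[e2.rna_id] != "mRNA":
                continue
            if e1.rna_id == e2.rna_id:
                continue
            a = vals.loc[e1.rna_id].to_numpy()
            b = vals.loc[e2.rna_id].to_numpy()
            if transform == "log2p1":
                a, b = np.log2(a + 1), np.log2(b + 1)
            if np.std(a) == 0 or np.std(b) == 0:
                continue
            if np.corrcoef(a, b)[0, 1] > threshold:
                found.add((e1.rna_id, e1.mirna_id, e2.rna_id))
    return found


class TestPairCernas:
    def test_perfect_coexpression_forms_triplet(self):
        expr = expr_from(
            {"m1": [8, 7, 6, 5, 4, 3, 2, 1], "g1": np.arange(1.0, 9), "l1": np.arange(2.0, 18, 2)},
            {"m1": "miRNA", "g1": "mRNA", "l1": "lncRNA"},
        )
        edges = [
            NegCorrEdge("m1", "g1", "mRNA", -1.0),
            NegCorrEdge("m1", "l1", "lncRNA", -1.0),
        ]
        triplets = pair_cernas(edges, expr)
        assert [(t.rna_a, t.mirna_id, t.rna_b) for t in triplets] == [("l1", "m1", "g1")]

    def test_boundary_r_exactly_at_threshold_dropped(self):
        expr = expr_from(
            {"m1": [8, 7, 6, 5, 4, 3, 2, 1], "g1": np.arange(1.0, 9), "l1": np.arange(2.0, 18, 2)},
            {"m1": "miRNA", "g1": "mRNA", "l1": "lncRNA"},
        )
        edges = [
            NegCorrEdge("m1", "g1", "mRNA", -1.0),
            NegCorrEdge("m1", "l1", "lncRNA", -1.0),
        ]
        # their (log-scale) correlation r* becomes the threshold: strict >
        r_star = pair_cernas(edges, expr, threshold=-1.0)[0].pearson_r
        assert pair_cernas(edges, expr, threshold=r_star) == []

    def test_mode_restricts_sponge_class(self):
        expr = expr_from(
            {
                "m1": [8, 7, 6, 5, 4, 3, 2, 1],
                "g1": np.arange(1.0, 9),
                "l1": np.arange(2.0, 18, 2),
                "c1": np.arange(3.0, 27, 3),
            },
            {"m1": "miRNA", "g1": "mRNA", "l1": "lncRNA", "c1": "circRNA"},
        )
        edges = [
            NegCorrEdge("m1", "g1", "mRNA", -1.0),
            NegCorrEdge("m1", "l1", "lncRNA", -1.0),
            NegCorrEdge("m1", "c1", "circRNA", -1.0),
        ]
        lnc = pair_cernas(edges, expr, mode="lncRNA")
        assert {t.rna_a for t in lnc} == {"l1"}
        both = pair_cernas(edges, expr, mode="both")
        assert {t.rna_a for t in both} == {"l1", "c1"}

    def test_matches_enumeration_oracle_on_random_instances(self, rng):
        classes = (
            {f"m{i}": "miRNA" for i in range(6)}
            | {f"g{i}": "mRNA" for i in range(10)}
            | {f"l{i}": "lncRNA" for i in range(5)}
            | {f"c{i}": "circRNA" for i in range(5)}
        )
        ids = list(classes)
        for trial in range(50):
            rows = {fid: rng.integers(1, 1000, size=8) for fid in ids}
            expr = expr_from(rows, classes)
            edges = []
            for mid in [f"m{i}" for i in range(6)]:
                for rid in rng.choice(
                    [i for i in ids if not i.startswith("m")], size=8, replace=False
                ):
                    edges.append(
                        NegCorrEdge(mid, str(rid), classes[str(rid)], -0.7)
                    )
            threshold = float(rng.uniform(-0.5, 0.9))
            got = {t.key() for t in pair_cernas(edges, expr, threshold=threshold)}
            assert got == brute_force_triplets(edges, expr, threshold), trial


def demo_triplets():
    return [
        CeRNATriplet("l1", "lncRNA", "m1", "g1", "mRNA", -0.9, -0.8, 0.95),
        CeRNATriplet("l1", "lncRNA", "m2", "g1", "mRNA", -0.7, -0.75, 0.95),
        CeRNATriplet("c1", "circRNA", "m1", "g1", "mRNA", -0.9, -0.8, 0.85),
    ]


class TestAssembleExport:
    def test_empty_network(self):
        net = assemble_network([])
        assert net.summary() == {
            "n_mirna": 0,
            "n_mrna": 0,
            "n_lncrna": 0,
            "n_circrna": 0,
            "n_interactions": 0,
            "n_triplets": 0,
        }

    def test_nodes_and_edges_deduplicated(self):
        net = assemble_network(demo_triplets())
        s = net.summary()
        assert s["n_mirna"] == 2 and s["n_mrna"] == 1
        assert s["n_lncrna"] == 1 and s["n_circrna"] == 1
        # l1-g1 cerna edge shared by two miRNAs appears once
        assert s["n_interactions"] == 7
        assert s["n_triplets"] == 3

    def test_single_triplet_sif_has_three_lines(self, tmp_path):
        net = assemble_network(demo_triplets()[:1])
        written = export_network(net, tmp_path)
        lines = written["sif"].read_text().strip().split("\n")
        assert len(lines) == 3
        relations = sorted(line.split("\t")[1] for line in lines)
        assert relations == ["cerna", "targets", "targets"]

    def test_roundtrip_isomorphic(self, tmp_path):
        import networkx as nx

        net = assemble_network(demo_triplets())
        written = export_network(net, tmp_path)
        back = import_network(written["sif"], written["attrs"])
        assert nx.is_isomorphic(net.graph, back.graph)
        assert set(back.graph.nodes) == set(net.graph.nodes)
        assert back.triplet_keys() == net.triplet_keys()

    def test_node_classes_partition_nodes(self, tmp_path):
        net = assemble_network(demo_triplets())
        written = export_network(net, tmp_path)
        attrs = pd.read_csv(written["attrs"], sep="\t")
        assert sorted(attrs["id"]) == sorted(net.graph.nodes)
        assert attrs["class"].isin(["miRNA", "mRNA", "lncRNA", "circRNA"]).all()

    def test_degenerate_triplet_rejected(self):
        bad = CeRNATriplet("g1", "mRNA", "m1", "g1", "mRNA", -0.9, -0.9, 0.9)
        with pytest.raises(ValueError, match="degenerate"):
            assemble_network([bad])

    def test_graphml_written(self, tmp_path):
        written = export_network(assemble_network(demo_triplets()), tmp_path)
        assert written["graphml"].stat().st_size > 0


class TestRecovery:
    def test_perfect_recovery(self):
        truth = [("l1", "m1", "g1")]
        found = [CeRNATriplet("l1", "lncRNA", "m1", "g1", "mRNA", -1, -1, 1)]
        score = score_recovery(found, truth)
        assert score.precision == 1.0 and score.recall == 1.0
        assert score.arm_precision == 1.0 and score.arm_recall == 1.0

    def test_empty_discovery_nan_precision(self):
        with pytest.warns(UserWarning, match="precision undefined"):
            score = score_recovery([], [("l1", "m1", "g1")])
        assert np.isnan(score.precision)
        assert score.recall == 0.0

    def test_recall_nonincreasing_in_noise(self):
        from spongeworks.pipeline import discover_triplets
        from spongeworks.synthdata import SimConfig, simulate_study

        mean_recall = []
        for noise in (0.1, 0.5, 1.0):
            recalls = []
            for seed in range(8):
                study = simulate_study(SimConfig(seed=seed, noise_sd=noise))
                _, _, score = discover_triplets(study)
                recalls.append(score.recall)
            mean_recall.append(np.mean(recalls))
        assert mean_recall[0] >= mean_recall[1] >= mean_recall[2]
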