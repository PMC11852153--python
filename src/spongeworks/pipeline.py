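"""End-to-end orchestration: simulate -> filter -> ... -> enrichment.

The pipeline is driven by one plain-text (TOML) configuration carrying
the thresholds of the discovery chain (|log2FC| >= 1, p <= 0.05,
Spearman <= -0.6, Pearson > 0.7), a seed, and the synthetic study
conditions.  Every stage writes its artifact under the output directory
and is recorded — with SHA-256 hashes and summary counts — in a run
manifest, so a rerun with the same config and seed reproduces identical
manifests.

:func:`discover_triplets` is the library-level harness used by the
pipeline's network stage and by validation studies: predictions ->
anti-correlation screen -> ceRNA pairing -> recovery scoring.
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
import warnings
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Any, Sequence

import pandas as pd

from . import __version__
from .enrichment import GeneSet, ora, results_frame, write_gmt
from .expression import (
    de_records_frame,
    differential_test,
    screen_de,
    tpm_normalize,
)
from .network import (
    CeRNATriplet,
    assemble_network,
    export_network,
    pair_cernas,
    score_recovery,
)
from .smallrna import annotate_tags, collapse_tags, filter_reads, quantify_mirna_tags
from .synthdata import (
    SimConfig,
    SyntheticStudy,
    simulate_reads,
    simulate_study,
    write_fastq,
)
from .targeting import DEFAULT_SITE_TYPES, intersect_predictions, predict_targets, spearman_screen

__all__ = [
    "ConfigError",
    "StageError",
    "RunConfig",
    "RunManifest",
    "discover_triplets",
    "run",
]

log = logging.getLogger("spongeworks")

STAGES = (
    "filter",
    "annotate",
    "quantify",
    "de",
    "targets",
    "screen",
    "network",
    "enrichment",
)

DEFAULT_READ_COMPOSITION = {
    "clean_tags": 400,
    "low_frequency": 40,
    "low_quality": 30,
    "adapter3_null": 40,
    "adapter5_hit": 10,
    "insert_too_short": 60,
    "polyA": 10,
}


class ConfigError(ValueError):
    """Invalid run configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Validated run settings (see ``RunConfig.from_toml`` for the schema)."""

    outdir: Path
    seed: int = 0
    lfc_threshold: float = 1.0
    p_threshold: float = 0.05
    spearman_threshold: float = -0.6
    pearson_threshold: float = 0.7
    de_gating: bool = True
    pair_mode: str = "both"
    pearson_transform: str = "log2p1"
    site_types: tuple[str, ...] = DEFAULT_SITE_TYPES
    sim: SimConfig = field(default_factory=SimConfig)
    read_composition: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_READ_COMPOSITION)
    )
    prediction_lists: tuple[Path, ...] = ()

    def __post_init__(self) -> None:
        if not -1.0 <= self.spearman_threshold <= 0.0:
            raise ConfigError("spearman threshold must lie in [-1, 0]")
        if not 0.0 <= self.pearson_threshold <= 1.0:
            raise ConfigError("pearson threshold must lie in [0, 1]")
        if self.lfc_threshold < 0 or not 0 <= self.p_threshold <= 1:
            raise ConfigError("invalid DE thresholds")

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        """Schema: [run] outdir, seed; [thresholds] lfc, p, spearman,
        pearson; [network] de_gating, mode, transform; [simulate] any
        SimConfig field; [reads] category = count."""
        try:
            raw = tomllib.loads(Path(path).read_text())
        except (OSError, tomllib.TOMLDecodeError) as exc:
            raise ConfigError(str(exc)) from exc
        run_tbl = raw.get("run", {})
        if "outdir" not in run_tbl:
            raise ConfigError("[run] outdir is required")
        thr = raw.get("thresholds", {})
        net = raw.get("network", {})
        sim_tbl = dict(raw.get("simulate", {}))
        sim_tbl.setdefault("seed", run_tbl.get("seed", 0))
        valid_sim = {f.name for f in dc_fields(SimConfig)}
        bad = set(sim_tbl) - valid_sim
        if bad:
            raise ConfigError(f"unknown [simulate] keys: {sorted(bad)}")
        if "mean_log2_expression_range" in sim_tbl:
            sim_tbl["mean_log2_expression_range"] = tuple(
                sim_tbl["mean_log2_expression_range"]
            )
        try:
            sim = SimConfig(**sim_tbl)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"bad [simulate] table: {exc}") from exc
        return cls(
            outdir=Path(run_tbl["outdir"]),
            seed=int(run_tbl.get("seed", 0)),
            lfc_threshold=float(thr.get("lfc", 1.0)),
            p_threshold=float(thr.get("p", 0.05)),
            spearman_threshold=float(thr.get("spearman", -0.6)),
            pearson_threshold=float(thr.get("pearson", 0.7)),
            de_gating=bool(net.get("de_gating", True)),
            pair_mode=str(net.get("mode", "both")),
            pearson_transform=str(net.get("transform", "log2p1")),
            sim=sim,
            read_composition=dict(raw.get("reads", DEFAULT_READ_COMPOSITION)),
            prediction_lists=tuple(
                Path(p) for p in raw.get("targets", {}).get("prediction_lists", [])
            ),
        )

    def echo(self) -> dict[str, Any]:
        return {
            "outdir": str(self.outdir),
            "seed": self.seed,
            "thresholds": {
                "lfc": self.lfc_threshold,
                "p": self.p_threshold,
                "spearman": self.spearman_threshold,
                "pearson": self.pearson_threshold,
            },
            "network": {
                "de_gating": self.de_gating,
                "mode": self.pair_mode,
                "transform": self.pearson_transform,
            },
            "simulate": {
                f.name: getattr(self.sim, f.name) for f in dc_fields(SimConfig)
            },
            "reads": self.read_composition,
        }


@dataclass
class RunManifest:
    config: dict[str, Any]
    version: str
    stages: list[dict[str, Any]] = field(default_factory=list)

    def add_stage(self, name: str, artifacts: Sequence[Path], counts: dict[str, Any]) -> None:
        self.stages.append(
            {
                "stage": name,
                "artifacts": [
                    {"path": str(p), "sha256": _sha256(p)} for p in artifacts
                ],
                "counts": counts,
            }
        )
        log.info("stage %-10s %s", name, counts)

    def counts(self, stage: str) -> dict[str, Any]:
        for s in self.stages:
            if s["stage"] == stage:
                return s["counts"]
        raise KeyError(stage)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"version": self.version, "config": self.config, "stages": self.stages},
                indent=2,
                default=str,
            )
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def discover_triplets(
    study: SyntheticStudy,
    spearman_threshold: float = -0.6,
    pearson_threshold: float = 0.7,
    site_types: Sequence[str] = DEFAULT_SITE_TYPES,
    de_gating: bool = False,
    pair_mode: str = "both",
    transform: str = "log2p1",
    extra_predictions: Sequence[set[tuple[str, str]]] = (),
):
    """Run prediction -> screens -> pairing on a synthetic study.

    Returns ``(edges, triplets, score)`` where ``score`` compares the
    recovered triplets with the planted truth.  DE gating is off by
    default here: the harness measures the correlation screens' own
    operating characteristics against planted truth.
    """
    tpm = tpm_normalize(study.expression)
    pairs, _ = predict_targets(study.mirna_seqs, study.transcript_seqs, site_types)
    if extra_predictions:
        pairs = intersect_predictions([pairs, *extra_predictions])
    if de_gating:
        records = differential_test(study.expression)
        screen = screen_de(records)
        sig = set(screen.significant)
        pairs = {(m, r) for (m, r) in pairs if m in sig and r in sig}
    edges = spearman_screen(pairs, tpm, threshold=spearman_threshold)
    triplets = pair_cernas(
        edges, tpm, threshold=pearson_threshold, mode=pair_mode, transform=transform
    )
    score = score_recovery(triplets, study.truth.triplets)
    return edges, triplets, score


def _annotation_sources(tag_sequences: Sequence[str]) -> dict[str, set[str]]:
    """Deterministic stand-in lookup tables over the observed tags.

    Real runs would consult rRNA/tRNA collections, miRBase and genome
    annotation; here the clean tags are spread round-robin over the
    categories so the priority logic is exercised end to end.
    """
    cats = ("exist_miRNA", "known_miRNA", "rRNA_etc", "exon", "repeat", "intron")
    sources: dict[str, set[str]] = {c: set() for c in cats}
    for i, seq in enumerate(sorted(tag_sequences)):
        if i % 3 == 2:  # every third tag stays unannotated
            continue
        sources[cats[i % len(cats)]].add(seq)
    return sources


def run(config: RunConfig) -> RunManifest:
    """Execute the full chain; returns the manifest (also written to disk).

    Stage artifacts land under ``config.outdir``; a failing stage aborts
    with :class:`StageError` naming the stage, leaving any partial
    artifact renamed with a ``.partial`` suffix.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.echo(), version=__version__)

    state: dict[str, Any] = {}

    def _stage(name: str, fn) -> None:
        produced: list[Path] = []
        try:
            artifacts, counts = fn(produced)
        except Exception as exc:  # noqa: BLE001 - named-stage abort contract
            for p in produced:
                if p.exists():
                    p.rename(p.with_suffix(p.suffix + ".partial"))
            raise StageError(name, exc) from exc
        manifest.add_stage(name, artifacts, counts)

    # input preparation (not a pipeline stage): synthetic study + raw reads
    study = simulate_study(config.sim)
    fixture = simulate_reads(config.sim, config.read_composition)
    write_fastq(fixture, outdir / "fastq")
    state["study"] = study

    def filter_stage(produced):
        inserts, report = filter_reads(
            fixture.reads, fixture.adapter_3p, fixture.adapter_5p
        )
        tags, report = collapse_tags(inserts, report)
        state["tags"] = tags
        path = outdir / "filter_report.tsv"
        produced.append(path)
        report.to_tsv(path)
        return [path], {c: report.counts[c] for c in report.counts} | {
            "total": report.total
        }

    def annotate_stage(produced):
        sources = _annotation_sources([t.sequence for t in state["tags"]])
        tags = annotate_tags(state["tags"], sources)
        state["tags"] = tags
        path = outdir / "clean_tags.tsv"
        produced.append(path)
        samples = sorted({s for t in tags for s in t.counts})
        pd.DataFrame(
            [
                {
                    "sequence": t.sequence,
                    "category": t.category,
                    "excluded": t.excluded,
                    **{s: t.counts.get(s, 0) for s in samples},
                }
                for t in tags
            ]
        ).to_csv(path, sep="\t", index=False)
        by_cat: dict[str, int] = {}
        for t in tags:
            by_cat[t.category] = by_cat.get(t.category, 0) + 1
        return [path], by_cat

    def quantify_stage(produced):
        tag_counts = quantify_mirna_tags(state["tags"])
        tag_path = outdir / "mirna_tag_counts.tsv"
        produced.append(tag_path)
        tag_counts.to_csv(tag_path, sep="\t", index_label="sequence")
        counts_path = outdir / "expression_counts.tsv"
        produced.append(counts_path)
        study.expression.to_tsv(counts_path)
        tpm = tpm_normalize(study.expression)
        tpm_path = outdir / "expression_tpm.tsv"
        produced.append(tpm_path)
        tpm.to_tsv(tpm_path)
        state["tpm"] = tpm
        return [tag_path, counts_path, tpm_path], {
            "n_mirna_tags": int(tag_counts.shape[0]),
            "n_features": int(study.expression.values.shape[0]),
            "n_samples": int(study.expression.values.shape[1]),
        }

    def de_stage(produced):
        records = differential_test(study.expression)
        screen = screen_de(records, config.lfc_threshold, config.p_threshold)
        state["de"] = screen
        path = outdir / "differential.tsv"
        produced.append(path)
        de_records_frame(records, study.expression.feature_class).to_csv(path, sep="\t")
        return [path], {
            "n_tested": len(records),
            "n_up": len(screen.up),
            "n_down": len(screen.down),
        }

    def targets_stage(produced):
        pairs, _ = predict_targets(
            study.mirna_seqs, study.transcript_seqs, config.site_types
        )
        sets: list[set[tuple[str, str]]] = [pairs]
        for list_path in config.prediction_lists:
            df = pd.read_csv(list_path, sep="\t", header=None)
            sets.append({(str(a), str(b)) for a, b in zip(df[0], df[1])})
        pairs = intersect_predictions(sets)
        state["pairs"] = pairs
        path = outdir / "predicted_targets.tsv"
        produced.append(path)
        pd.DataFrame(sorted(pairs), columns=["mirna", "rna"]).to_csv(
            path, sep="\t", index=False
        )
        return [path], {"n_pairs": len(pairs), "n_sources": len(sets)}

    def screen_stage(produced):
        pairs = state["pairs"]
        if config.de_gating:
            sig = set(state["de"].significant)
            pairs = {(m, r) for (m, r) in pairs if m in sig and r in sig}
        edges = spearman_screen(pairs, state["tpm"], config.spearman_threshold)
        state["edges"] = edges
        path = outdir / "negcorr_edges.tsv"
        produced.append(path)
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
        return [path], {"n_candidate_pairs": len(pairs), "n_edges": len(edges)}

    def network_stage(produced):
        triplets: list[CeRNATriplet] = pair_cernas(
            state["edges"],
            state["tpm"],
            threshold=config.pearson_threshold,
            mode=config.pair_mode,
            transform=config.pearson_transform,
        )
        net = assemble_network(triplets)
        state["network"] = net
        directions = {
            r.feature_id: r.direction for r in state["de"].records if r.significant
        }
        written = export_network(net, outdir, de_direction=directions)
        produced.extend(written.values())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            score = score_recovery(net, study.truth.triplets)
        def _jsonable(v: float):
            return None if v != v else v  # NaN (undefined) -> null

        summary = net.summary() | {
            "triplet_recall": _jsonable(score.recall),
            "triplet_precision": _jsonable(score.precision),
        }
        summary_path = outdir / "network_summary.json"
        produced.append(summary_path)
        summary_path.write_text(json.dumps(summary, indent=2))
        return [*written.values(), summary_path], summary

    def enrichment_stage(produced):
        mrna_universe = sorted(
            study.expression.feature_class[
                study.expression.feature_class == "mRNA"
            ].index
        )
        rng_sets = _synthetic_gene_sets(study, mrna_universe)
        gmt_path = outdir / "gene_sets.gmt"
        produced.append(gmt_path)
        write_gmt(rng_sets, gmt_path)
        classes = dict(study.expression.feature_class)
        query = sorted(
            n
            for n in state["network"].graph.nodes
            if classes.get(n) == "mRNA"
        )
        path = outdir / "enrichment.tsv"
        produced.append(path)
        if query:
            results = ora(query, rng_sets, mrna_universe)
            results_frame(results).to_csv(path, sep="\t", index=False)
            n_sig = sum(r.q_value <= 0.05 for r in results)
        else:
            results_frame([]).to_csv(path, sep="\t", index=False)
            n_sig = 0
        return [gmt_path, path], {"n_terms": len(rng_sets), "n_query": len(query), "n_q05": n_sig}

    stage_fns = {
        "filter": filter_stage,
        "annotate": annotate_stage,
        "quantify": quantify_stage,
        "de": de_stage,
        "targets": targets_stage,
        "screen": screen_stage,
        "network": network_stage,
        "enrichment": enrichment_stage,
    }
    for name in STAGES:
        _stage(name, stage_fns[name])

    manifest.to_json(outdir / "manifest.json")
    return manifest


def _synthetic_gene_sets(study: SyntheticStudy, universe: Sequence[str]) -> list[GeneSet]:
    """GMT stand-in: one set seeded with the planted target mRNAs plus
    size-matched random sets drawn from the mRNA universe."""
    import numpy as np

    rng = np.random.default_rng([study.config.seed, 65537])
    planted = sorted({b for _, _, b in study.truth.triplets})
    pad = [g for g in universe if g not in planted]
    sets = [
        GeneSet(
            "SET_PLANTED",
            "planted sponge targets",
            frozenset(
                planted
                + list(rng.choice(pad, size=min(10, len(pad)), replace=False))
            ),
        )
    ]
    for i in range(9):
        members = rng.choice(universe, size=min(20, len(universe)), replace=False)
        sets.append(GeneSet(f"SET_{i + 1:02d}", f"random set {i + 1}", frozenset(members)))
    return sets
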