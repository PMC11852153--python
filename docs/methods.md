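# Methods

## The discovery chain

`spongeworks` infers miRNA-centred sponge (ceRNA) triplets
(RNA_a, miRNA, RNA_b) from a two-group expression study. A triplet is
accepted when (i) both RNAs carry a canonical seed site for the miRNA,
(ii) each RNA is anti-correlated with the miRNA across the pooled
samples (Spearman ρ ≤ −0.6, inclusive), and (iii) the two RNAs are
positively co-expressed (Pearson r > 0.7, strict). One arm is always an
mRNA; the other is a lncRNA or circRNA (mRNA–mRNA sponge pairs are
excluded by default, configurable via `pair_mode`). The thresholds are
inclusive/strict exactly as written because they are screening
*definitions*, not estimates: a pair at ρ = −0.6 is in, a pair at
r = 0.7 is out.

Assumptions worth stating explicitly:

* Correlation across n = 8 pooled samples is a very blunt instrument;
  the screens are deliberately simple rank/moment statistics, not
  significance tests. With 8 samples the null probability of
  ρ ≤ −0.6 is a few percent per candidate pair, which is why the
  candidate set is restricted by seed matching (and optionally by the
  differential screen) before any correlation is computed.
* Sponge regulation is modelled as monotone: the screens make no
  attempt to detect threshold or saturation kinetics.

## Read filtering and annotation

Filters run in a fixed order and each read is charged to the *first*
category it fails: `low_quality`, `adapter3_null` (no 3′ adapter — the
insert is the sequence strictly before the first adapter occurrence),
`adapter5_hit` (5′ adapter inside the trimmed insert, a ligation
artefact), `insert_too_short` (< 18 nt, including no insert at all),
`insert_too_long` (> 30 nt), `polyA`, and, after collapsing identical
inserts across samples, `low_frequency` (summed count < 2). The
survivors are clean tags. Category counts partition the input exactly;
this accounting invariant is asserted in code and tested against the
generator's per-read truth.

Numerical/rule choices the upstream literature leaves open, each
configurable:

* **Low quality**: > 20 % of bases below Phred 20, or any `N` call.
* **polyA**: ≥ 80 % adenine or an A-run of ≥ 10.
* **Adapter match**: exact substring of the first 8 adapter bases; real
  trimmers allow mismatches — kept exact for auditability.
* **Quality is judged on the raw read** (before trimming).
* **Frequency ≥ 2 is summed across samples**, not per sample, so a tag
  seen once in each of two samples survives.
* The 18–30 nt window is enforced computationally on both sides,
  mirroring the small-RNA gel cut; over-long inserts get their own
  report bucket rather than being folded into "too short".

Annotation assigns each tag the single highest-priority matching
category: `rRNA_etc > exist_miRNA > exist_miRNA_edit > known_miRNA >
repeat > exon > novel_candidate > intron`, else `unann`; rRNA-class
tags are flagged excluded from quantification. Lookups are abstract
membership tables (sets or predicates) — no genome alignment is
performed, and novel-miRNA hairpin prediction is out of scope (the
`novel_candidate` category exists so the priority order is complete).
`exist_miRNA_edit` means: equal length and exactly one substitution
relative to an `exist_miRNA` reference, outside seed positions 2–7.

## Quantification and the differential screen

TPM is count-proportional per sample (columns scaled to 10⁶); small-RNA
tags carry no length correction. The two-group test is an exact
conditional negative-binomial test: counts are rescaled to the
geometric-mean library depth, a single common dispersion φ is estimated
by pooled method of moments across all features
(φ = mean of (s² − μ)/μ², clipped to ≥ 10⁻⁶), and the group-A total is
compared with its conditional distribution given the overall total
(sum of n i.i.d. NB(μ, φ) is NB(nμ, φ/n)). The two-sided p-value sums
the probability of every outcome no more probable than the observed one
(with a 10⁻¹⁰ log-tolerance for numerically tied outcomes); totals
above 2×10⁶ switch to the Gaussian limit of the conditional
distribution. Fold change is reported on mean TPM with a pseudo-count
of 1 TPM: log₂((TPM̄_A + 1)/(TPM̄_B + 1)). A rank-based alternative
(Mann–Whitney on TPM) sits behind the same interface
(`method="wilcoxon"`).

This is a deliberate simplification of the shrinkage machinery of
dedicated DE packages: at 4-vs-4 with a common dispersion shared by
construction in the simulated data, the pooled-moments estimate is
accurate, and the null type-I error is calibrated (the acceptance run
measures the fraction of p ≤ 0.05 under a 10,000-feature null at
nominal 0.05 within the 99 % binomial band). On real data with strongly
feature-dependent dispersion this test will be miscalibrated; that is a
known limitation, not a target of this package.

The raw p ≤ 0.05 (no multiplicity adjustment) in the significance rule
is intentional: it reproduces the screening rule as practised, with the
screen's permissiveness absorbed downstream by the correlation filters.

## Seed-match target prediction

Canonical site vocabulary on the transcript, 5′→3′: an optional match
to miRNA position 8, the reverse complement of seed positions 2–7 (the
6mer core), and an optional adenine opposite position 1 (an A
regardless of the miRNA base, per the canonical definition):
`8mer = m8 + core + A`, `7mer-m8 = m8 + core`, `7mer-A1 = core + A`,
`6mer = core`. Every reported site is re-verifiable by direct string
comparison, and the implementation is tested against a brute-force
window-enumeration oracle. U/T are interchangeable (sequences are
normalised to DNA internally). 6mer-only pairs are excluded from the
default candidate set: the single in-repo predictor then behaves
conservatively, approximating the stringency of intersecting several
external predictors — whose pair lists can also be imported as
two-column TSVs and intersected explicitly.

## Correlation screens and pairing

Both screens run on TPM over all samples pooled across groups (the
input scale is configurable; pooling maximises the dynamic range the
sponge axis needs at n = 8). Spearman uses average ranks for ties.
The ceRNA Pearson correlation is computed on log₂(TPM + 1) by default
(`transform="raw"` uses TPM directly): count data are approximately
log-normal, and on the raw scale the sample Pearson of strongly
co-expressed features is dominated by the heaviest-expressed samples,
which at n = 8 makes it an erratic statistic. Rank screens are
unaffected by this choice. Constant expression vectors make the
correlation undefined; such pairs are skipped with a warning, never an
exception.

Correlation kernels are implemented as vectorised
centre-and-dot operations (sum-of-squares products before the square
root, so perfectly proportional vectors give exactly ±1); `scipy`'s
scalar routines serve as independent oracles in the tests, to 10⁻¹².

## Network assembly and scoring

Triplets merge into a typed graph: `mirna_target` edges carry the
Spearman ρ, `cerna_pair` edges carry the Pearson r and the full list of
witnessing triplets (provenance). Invariants checked on every assembly:
miRNA–target edges join a miRNA to a non-miRNA; every ceRNA pair edge
is witnessed by at least one shared miRNA in the graph; duplicate
evidence collapses onto one edge (a pair witnessed twice keeps its best
r). Export is SIF + node-attribute TSV + GraphML; re-importing
SIF + attributes reconstructs an isomorphic graph with provenance
re-derived from shared-miRNA structure.

`score_recovery` reports triplet-level and arm-level precision/recall
against planted truth; precision of an empty discovery set is undefined
and returned as NaN with a warning (serialised as `null` in manifests).

By default the pipeline gates network membership on differential
significance (`de_gating = true`), mirroring the practice of building
networks around differential features. The recovery harness
(`discover_triplets`) runs ungated by default because it measures the
operating characteristics of the correlation screens themselves — see
the generator design below for why the two planted axes are disjoint.

## Over-representation analysis

Hypergeometric upper tail P[X ≥ k] with X ~ Hypergeom(N, K, n), sets
intersected with the universe before testing, BH adjustment across all
tested terms. The universe defaults to all features of the queried
class; collections are plain GMT files — nothing is fetched from live
databases, so results are reproducible and version-pinned by input.

## The synthetic-data generator

`SimConfig` defaults define the study conditions: 4 vs 4 samples
(HF/LF), 20 miRNAs, 200 mRNAs, 50 lncRNAs, 30 circRNAs; NB counts with
dispersion 0.02 around log-normal baselines (log₂ means uniform on
[6, 10]); 10 differential miRNAs at log₂FC 2 (alternating direction,
effect split symmetrically between groups); 10 sponge triplets.

Two *disjoint* planted signal axes:

* **Differential axis** (miR-001…010): a pure group-mean shift with no
  extra inter-individual spread, so 4-vs-4 power is governed by count
  noise alone and all planted DE miRNAs are recovered at log₂FC 2.
* **Sponge axis** (miR-011…020): each miRNA receives per-sample
  log₂-normal spread (sd 0.7) — inter-individual variation, the signal
  the correlation screens consume — and both arms of its triplet follow
  `baseline − slope·(x − x̄) + N(0, noise_sd)` on the log₂-mean scale,
  with slope 3 and noise_sd 0.2 by default. Regulation acts on the
  log-mean (not by post-hoc count editing), so `noise_sd` is a direct,
  interpretable recovery knob. The slope/spread/dispersion combination
  was calibrated once so the *population* arm Spearman is ≈ −0.9 at
  noise_sd = 0.2 (measured at n = 1000 samples: −0.907); at n = 8 the
  sample arm correlations average ≈ −0.87 and pooled recovery over 20
  replicates is ~0.94 recall / ~0.91 precision at thresholds
  (−0.6, 0.7).

The axes are disjoint because they need opposite variance structure:
sponge arms need large inter-individual spread, which would destroy
4-vs-4 differential power if layered onto the same miRNAs. A
consequence: with differential gating on, the default synthetic network
is empty — gated runs are a power study, toggled explicitly.

Sequence layer: miRNAs are random 22-mers with pairwise-distinct seed
hexamers; transcripts are random 150-mers (think of them as the
site-bearing 3′-UTR fragment) and every planted arm has one embedded
8mer site. Chance seed matches elsewhere are left in place — rejecting
them is precisely the screens' job, and they set the generator's
realistic floor on precision.

Technical choices for exactness and reproducibility:

* A sequence-less **depth-filler** mRNA row absorbs the mass the
  planted features move around, holding the expected library size
  exactly constant (equal sequencing depth; per-sample size factors
  default to 1 and multiply on top). Without it, TPM's per-sample
  denominator would couple every feature to the planted swings.
* In the deterministic limit `nb_dispersion = 0` the generator returns
  the expected counts themselves (fractional, unrounded): rounding
  creates ties that break the exact ±1 planted correlations. With both
  `noise_sd = 0` and `nb_dispersion = 0`, every planted arm has
  Spearman exactly −1 and every planted pair Pearson exactly +1 (on the
  raw TPM scale, where planted proportionality is exact), and recovery
  is 100 %.
* Log₂ means are clamped to [−4, 20] with a warning — the safety net
  for configurations whose slope/spread would otherwise under/overflow
  the count scale.
* All draws come from one seeded generator in a fixed order; derived
  streams (sequences, read fixtures, gene sets) use fixed sequence-seed
  offsets of the study seed. Identical config ⇒ byte-identical output.

Read fixtures: each requested category is constructed to trip exactly
its intended filter (e.g. a `short_insert` read has a valid 3′ adapter
and an insert of 0/10/17 nt; a `singleton` is a unique insert seen once
in the whole run; clean inserts are duplicated so they survive the
frequency filter — a clean count of exactly 1 is rejected as
unsatisfiable). The generated composition *is* the expected filter
report, which gives the end-to-end bookkeeping oracle.

What the generator does **not** emulate — so what passing tests do not
show: no real genome or sequence homology, no mapping ambiguity, no
GC/length biases, no feature-dependent dispersion, no batch or
library-preparation effects, no compositional competition beyond the
planted swings, and transcript-level (not gene-level) identity. Results
on real data will be correspondingly noisier, and the differential
test's common-dispersion assumption will not hold there.

## Pipeline plumbing

One TOML config drives the run (`[run] outdir/seed`, `[thresholds]`,
`[network]`, `[simulate]`, `[reads]`). Eight stages (filter, annotate,
quantify, de, targets, screen, network, enrichment) each log one
structured line of input/output counts and record their artifacts with
SHA-256 hashes in `manifest.json`; reruns with identical config and
seed reproduce identical manifests. A failing stage aborts with the
stage named (CLI exit codes: 0 ok, 1 config error, 2 stage failure) and
renames its partial outputs with a `.partial` suffix. The annotation
stage on synthetic runs uses deterministic stand-in lookup tables
spread over the observed tags, exercising the priority logic end to end
without pretending to a real reference.

Problem sizes used by the shipped validation runs — 10 read fixtures of
up to ~16k reads, 20 replicate studies of 300 features × 8 samples, one
10,000-feature null for test calibration — were chosen so the full
suite and the acceptance script each complete in seconds while keeping
every Monte-Carlo band comfortably tight.

## Known limitations

* The exact NB test's common dispersion is a simulation-faithful
  simplification; real data need tagwise shrinkage.
* Seed matching ignores thermodynamics, conservation and 3′
  supplementary pairing; site counts are collapsed to one edge per
  pair (best site type kept).
* n = 8 correlation screens cannot distinguish direct sponging from
  shared upstream regulation; the network is a candidate structure,
  not a causal claim.
* ORA ignores gene-set overlap and GO DAG structure.
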