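"""Expression containers, TPM normalisation and the two-group screen.

The differential test is an exact conditional negative-binomial test for a
two-group design at small n: counts are scaled to a common library size,
a common dispersion is estimated across all features by the method of
moments, and the group-A total is compared with its conditional
distribution given the overall total (the sum of probabilities no larger
than that of the observed outcome gives the two-sided p).  Fold changes
are reported on mean TPM with a pseudo-count.

A rank-based alternative (Mann–Whitney on TPM) is provided behind the
same interface for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

__all__ = [
    "ExpressionMatrix",
    "DERecord",
    "DEScreen",
    "tpm_normalize",
    "estimate_common_dispersion",
    "differential_test",
    "screen_de",
    "de_records_frame",
]

FeatureClass = Literal["miRNA", "mRNA", "lncRNA", "circRNA"]

TPM_SCALE = 1e6


@dataclass
class ExpressionMatrix:
    """Features x samples expression values with class and group labels.

    ``values`` is a DataFrame indexed by feature id; ``feature_class``
    maps feature id -> one of miRNA/mRNA/lncRNA/circRNA; ``groups`` maps
    sample id -> group label (e.g. HF/LF).  ``kind`` records whether the
    values are raw counts or TPM.
    """

    values: pd.DataFrame
    feature_class: pd.Series
    groups: pd.Series
    kind: Literal["counts", "tpm"] = "counts"

    def __post_init__(self) -> None:
        self.feature_class = pd.Series(self.feature_class).reindex(self.values.index)
        self.groups = pd.Series(self.groups).reindex(self.values.columns)
        self.validate()

    def validate(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        if self.feature_class.isna().any():
            raise ValueError("every feature needs a class label")
        if self.groups.isna().any():
            raise ValueError("every sample needs a group label")
        if self.kind == "tpm":
            colsums = self.values.sum(axis=0).to_numpy()
            if not np.allclose(colsums, TPM_SCALE, rtol=1e-6):
                raise ValueError("TPM columns must sum to 1e6")

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def class_subset(self, feature_class: str) -> "ExpressionMatrix":
        keep = self.feature_class[self.feature_class == feature_class].index
        return ExpressionMatrix(
            self.values.loc[keep],
            self.feature_class.loc[keep],
            self.groups,
            self.kind,
        )

    def group_samples(self, group: str) -> list[str]:
        return list(self.groups[self.groups == group].index)

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.insert(0, "class", self.feature_class)
        out.to_csv(path, sep="\t", index_label="feature_id")

    @classmethod
    def from_tsv(cls, path, groups: Mapping[str, str], kind="counts") -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col="feature_id")
        classes = df.pop("class")
        return cls(df, classes, pd.Series(dict(groups)), kind)

    @staticmethod
    def concat(matrices: Sequence["ExpressionMatrix"]) -> "ExpressionMatrix":
        values = pd.concat([m.values for m in matrices], axis=0)
        classes = pd.concat([m.feature_class for m in matrices], axis=0)
        return ExpressionMatrix(values, classes, matrices[0].groups, matrices[0].kind)


def tpm_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each sample column to sum to one million.

    Small-RNA tags carry no length correction, so TPM here is simply
    count-proportional per sample.
    """
    if m.kind != "counts":
        raise ValueError("tpm_normalize expects a counts matrix")
    colsums = m.values.sum(axis=0)
    if (colsums == 0).any():
        bad = list(colsums.index[colsums == 0])
        raise ValueError(f"all-zero sample column(s): {bad}")
    tpm = m.values.div(colsums, axis=1) * TPM_SCALE
    return ExpressionMatrix(tpm, m.feature_class, m.groups, kind="tpm")


@dataclass
class DERecord:
    """Differential result for one feature (group A over group B)."""

    feature_id: str
    log2fc: float
    p_value: float
    significant: bool = False
    direction: Literal["up", "down", "ns"] = "ns"


@dataclass
class DEScreen:
    records: list[DERecord]
    up: list[str] = field(default_factory=list)
    down: list[str] = field(default_factory=list)

    @property
    def significant(self) -> list[str]:
        return self.up + self.down


def _scale_to_common_depth(counts: np.ndarray) -> np.ndarray:
    """Rescale each sample to the geometric-mean depth and round.

    The exact conditional test assumes exchangeable per-sample totals;
    this mirrors the equal-library pseudo-count device of NB exact-test
    practice without a full TMM step.
    """
    depths = counts.sum(axis=0).astype(float)
    if (depths == 0).any():
        raise ValueError("sample with zero total counts")
    target = np.exp(np.mean(np.log(depths)))
    return np.rint(counts * (target / depths)).astype(np.int64)


def estimate_common_dispersion(counts: np.ndarray, group_idx: Sequence[np.ndarray]) -> float:
    """Pooled method-of-moments NB dispersion across all features.

    For each feature the within-group pooled variance s2 and grand mean mu
    give phi = (s2 - mu) / mu^2; the average over informative features
    (mean >= 1) is clipped to a small positive floor.
    """
    counts = counts.astype(float)
    n_total = sum(len(g) for g in group_idx)
    ss = np.zeros(counts.shape[0])
    for g in group_idx:
        sub = counts[:, g]
        ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    df = n_total - len(group_idx)
    s2 = ss / max(df, 1)
    mu = counts.mean(axis=1)
    keep = mu >= 1.0
    if not keep.any():
        return 1e-6
    phi = (s2[keep] - mu[keep]) / mu[keep] ** 2
    return float(np.clip(phi.mean(), 1e-6, 100.0))


def _exact_nb_pvalue(y_a: int, y_b: int, n_a: int, n_b: int, phi: float) -> float:
    """Two-sided exact conditional NB p-value for group totals.

    The sum of n iid NB(mu, phi) is NB(n*mu, phi/n); conditional on the
    overall total T the group-A total is compared against its conditional
    pmf, summing the probability of all outcomes at most as probable as
    the observed one.
    """
    total = y_a + y_b
    if total == 0:
        return 1.0
    mu = total / (n_a + n_b)
    r_a, r_b = n_a / phi, n_b / phi
    if total > 2_000_000:
        # Gaussian limit of the conditional distribution for very deep
        # features; the enumeration would be needlessly large there.
        var_a = n_a * mu * (1 + phi * mu)
        var_b = n_b * mu * (1 + phi * mu)
        cond_mean = n_a * mu + (var_a / (var_a + var_b)) * (total - (n_a + n_b) * mu)
        cond_var = var_a * var_b / (var_a + var_b)
        z = abs(y_a - cond_mean) / np.sqrt(cond_var)
        return float(2.0 * stats.norm.sf(z))
    k = np.arange(total + 1)
    logp = stats.nbinom.logpmf(
        k, r_a, r_a / (r_a + n_a * mu)
    ) + stats.nbinom.logpmf(total - k, r_b, r_b / (r_b + n_b * mu))
    logp -= logsumexp(logp)
    obs = logp[y_a]
    # include numerically tied outcomes
    return float(min(1.0, np.exp(logsumexp(logp[logp <= obs + 1e-10]))))


def differential_test(
    m: ExpressionMatrix,
    group_a: str = "HF",
    group_b: str = "LF",
    method: Literal["exact_nb", "wilcoxon"] = "exact_nb",
    pseudo_tpm: float = 1.0,
) -> list[DERecord]:
    """Per-feature two-group test on counts; fold change on mean TPM.

    log2fc = log2((mean TPM_A + c) / (mean TPM_B + c)) with c = 1 TPM.
    """
    if m.kind != "counts":
        raise ValueError("differential_test expects raw counts")
    samples_a = m.group_samples(group_a)
    samples_b = m.group_samples(group_b)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("need at least 2 samples per group")

    counts = m.values[samples_a + samples_b].to_numpy()
    tpm = tpm_normalize(m).values
    mean_a = tpm[samples_a].mean(axis=1).to_numpy()
    mean_b = tpm[samples_b].mean(axis=1).to_numpy()
    log2fc = np.log2((mean_a + pseudo_tpm) / (mean_b + pseudo_tpm))

    if method == "wilcoxon":
        pvals = np.ones(counts.shape[0])
        ta = tpm[samples_a].to_numpy()
        tb = tpm[samples_b].to_numpy()
        for i in range(counts.shape[0]):
            if np.ptp(np.r_[ta[i], tb[i]]) == 0:
                pvals[i] = 1.0
            else:
                pvals[i] = stats.mannwhitneyu(
                    ta[i], tb[i], alternative="two-sided"
                ).pvalue
    elif method == "exact_nb":
        scaled = _scale_to_common_depth(counts)
        idx_a = np.arange(len(samples_a))
        idx_b = np.arange(len(samples_a), len(samples_a) + len(samples_b))
        phi = estimate_common_dispersion(scaled, [idx_a, idx_b])
        ya = scaled[:, idx_a].sum(axis=1)
        yb = scaled[:, idx_b].sum(axis=1)
        pvals = np.array(
            [
                _exact_nb_pvalue(int(a), int(b), len(samples_a), len(samples_b), phi)
                for a, b in zip(ya, yb)
            ]
        )
    else:
        raise ValueError(f"unknown method {method!r}")

    return [
        DERecord(feature_id=fid, log2fc=float(l), p_value=float(p))
        for fid, l, p in zip(m.values.index, log2fc, pvals)
    ]


def screen_de(
    records: Sequence[DERecord],
    lfc_threshold: float = 1.0,
    p_threshold: float = 0.05,
) -> DEScreen:
    """Apply the significance rule |log2FC| >= 1 and p <= 0.05 (inclusive)."""
    screen = DEScreen(records=list(records))
    for rec in screen.records:
        rec.significant = (
            abs(rec.log2fc) >= lfc_threshold and rec.p_value <= p_threshold
        )
        if not rec.significant:
            rec.direction = "ns"
        elif rec.log2fc > 0:
            rec.direction = "up"
            screen.up.append(rec.feature_id)
        else:
            rec.direction = "down"
            screen.down.append(rec.feature_id)
    return screen


def de_records_frame(records: Sequence[DERecord], feature_class: pd.Series | None = None) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in records],
            "log2fc": [r.log2fc for r in records],
            "p_value": [r.p_value for r in records],
            "significant": [r.significant for r in records],
            "direction": [r.direction for r in records],
        }
    ).set_index("feature_id")
    if feature_class is not None:
        df.insert(0, "class", feature_class.reindex(df.index))
    return df
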