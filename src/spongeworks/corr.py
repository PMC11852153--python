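"""Correlation kernels used by the screening stages.

Both screens of the discovery chain run over many (feature, feature) pairs
on the same small set of samples, so the kernels here are written as
vectorised rank/standardise-then-dot operations on numpy arrays rather
than per-pair calls into a stats library.  Spearman uses average ranks for
ties (the convention assumed throughout the screens).
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = [
    "average_ranks",
    "pearson",
    "spearman",
    "standardize_rows",
    "pairwise_pearson",
]


def average_ranks(x: np.ndarray) -> np.ndarray:
    """1-based ranks of ``x`` with ties replaced by their average rank."""
    x = np.asarray(x, dtype=float)
    n = x.size
    order = np.argsort(x, kind="mergesort")
    sx = x[order]
    # run boundaries of tied values in sorted order
    starts = np.flatnonzero(np.r_[True, sx[1:] != sx[:-1]])
    stops = np.r_[starts[1:], n]
    avg = (starts + stops + 1) / 2.0
    ranks = np.empty(n, dtype=float)
    ranks[order] = np.repeat(avg, stops - starts)
    return ranks


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson product-moment correlation; NaN for a constant vector."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = xc @ xc
    syy = yc @ yc
    if sxx == 0.0 or syy == 0.0:
        return float("nan")
    # product before sqrt: exact +/-1 for perfectly proportional vectors
    return float(np.clip((xc @ yc) / np.sqrt(sxx * syy), -1.0, 1.0))


def spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation (average ranks for ties)."""
    return pearson(average_ranks(x), average_ranks(y))


def standardize_rows(m: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center each row; return (centered, sum-of-squares, constant_mask).

    Constant rows are flagged so callers can skip the (undefined)
    correlations they would produce.
    """
    m = np.asarray(m, dtype=float)
    centered = m - m.mean(axis=1, keepdims=True)
    ss = (centered * centered).sum(axis=1)
    return centered, ss, ss == 0.0


def pairwise_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlations between every row of ``a`` and every row of ``b``.

    Rows are observations over the same samples (columns).  Constant rows
    yield NaN with a warning, mirroring the scalar kernels.
    """
    ca_m, ssa, ca = standardize_rows(np.atleast_2d(a))
    cb_m, ssb, cb = standardize_rows(np.atleast_2d(b))
    if ca.any() or cb.any():
        warnings.warn(
            "constant expression vector(s): correlations undefined, set to NaN",
            stacklevel=2,
        )
    denom = np.sqrt(np.outer(ssa, ssb))
    denom[denom == 0.0] = 1.0
    r = np.clip((ca_m @ cb_m.T) / denom, -1.0, 1.0)
    r[ca, :] = np.nan
    r[:, cb] = np.nan
    return r
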