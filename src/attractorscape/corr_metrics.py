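"""Temporal correlation metrics: Pearson, Spearman, biweight midcorrelation
and a mutual-information-based correlation.

All four metrics compare the transcriptome at time t_i with the t_0
transcriptome over genes.  The mutual information estimator is
histogram-based on rank-transformed data with K equal-frequency bins and a
permutation-derived systematic-error correction: the discretisation biases
raw MI upward, so the minimum raw MI over random permutations of one vector
is subtracted (clipped at zero).  MI is reported in nats and mapped to a
[0, 1] correlation scale via MI_c = sqrt(1 - exp(-2 MI)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MIEstimate",
    "CorrelationSeries",
    "corr",
    "bicor",
    "rank_bins",
    "estimate_mi",
    "mi_correlation",
    "temporal_series",
]


@dataclass(frozen=True)
class MIEstimate:
    """Histogram MI with permutation bias correction (all values in nats)."""

    raw_mi: float
    epsilon: float
    corrected_mi: float
    bins: int
    n_permutations: int
    seed: int | None


@dataclass
class CorrelationSeries:
    """One correlation value per time point per replicate vs the t0 sample."""

    metric: str
    reference_time: float
    values: pd.DataFrame  # index = time_min, columns = replicate


def _check_pair(x, y, min_n: int = 3):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    return x, y


def bicor(x, y) -> float:
    """Biweight midcorrelation: a median/MAD-weighted robust correlation.

    Each vector is centred on its median; observations further than 9 MAD
    from the median get zero weight, nearer ones a Tukey biweight
    (1 - u^2)^2.  The correlation is the inner product of the weight-
    normalised vectors.
    """
    x, y = _check_pair(x, y)
    tilde = []
    for p in (x, y):
        med = np.median(p)
        mad = np.median(np.abs(p - med))
        if mad == 0:
            raise ZeroDivisionError("bicor undefined: MAD is zero")
        u = (p - med) / (9.0 * mad)
        w = (1.0 - u**2) ** 2 * (1.0 - np.abs(u) > 0)
        num = (p - med) * w
        denom = np.sqrt(np.sum(num**2))
        if denom == 0:
            raise ZeroDivisionError("bicor undefined: all weights zero")
        tilde.append(num / denom)
    return float(np.dot(tilde[0], tilde[1]))


def corr(x, y, method: str = "pearson") -> float:
    """Correlation between two vectors: 'pearson', 'spearman' or 'bicor'."""
    x, y = _check_pair(x, y)
    if method == "pearson":
        if np.std(x) == 0 or np.std(y) == 0:
            raise ZeroDivisionError("pearson undefined for a constant vector")
        return float(np.corrcoef(x, y)[0, 1])
    if method == "spearman":
        if np.std(x) == 0 or np.std(y) == 0:
            raise ZeroDivisionError("spearman undefined for a constant vector")
        return float(stats.spearmanr(x, y).statistic)
    if method == "bicor":
        return bicor(x, y)
    raise ValueError(f"unknown method {method!r}")


def rank_bins(x, k: int) -> np.ndarray:
    """Equal-frequency discretisation of a vector via its (average) ranks.

    Returns integer bin labels in [0, k).  With n divisible by k and no
    ties, every bin holds exactly n/k observations.
    """
    x = np.asarray(x, dtype=float)
    r = stats.rankdata(x, method="average")
    b = np.floor((r - 0.5) * k / x.size).astype(np.intp)
    return np.clip(b, 0, k - 1)


def _mi_from_bins(bx: np.ndarray, by: np.ndarray, k: int) -> float:
    """Plug-in MI of two pre-binned vectors, in nats."""
    n = bx.size
    joint = np.bincount(bx * k + by, minlength=k * k).astype(float) / n
    px = np.bincount(bx, minlength=k).astype(float) / n
    py = np.bincount(by, minlength=k).astype(float) / n
    nz = joint > 0
    h_joint = float(np.sum(joint[nz] * np.log(joint[nz])))
    h_x = float(np.sum(px[px > 0] * np.log(px[px > 0])))
    h_y = float(np.sum(py[py > 0] * np.log(py[py > 0])))
    return h_joint - h_x - h_y


def estimate_mi(x, y, k: int = 10, n_permutations: int = 100,
                seed: int | None = 0, epsilon_rule: str = "min") -> MIEstimate:
    """Histogram MI on rank-transformed data with permutation bias correction.

    Parameters
    ----------
    k : number of equal-frequency bins (default 10).
    n_permutations : random permutations of `y` used to estimate the
        discretisation bias epsilon.
    epsilon_rule : 'min' (default) takes the minimum permuted MI as the
        systematic error; 'mean' is a more conservative alternative.
    """
    x, y = _check_pair(x, y, min_n=2)
    if x.size < k:
        import warnings

        warnings.warn(f"n={x.size} < {k} bins: proceeding with occupied bins only")
    bx = rank_bins(x, k)
    by = rank_bins(y, k)
    raw = _mi_from_bins(bx, by, k)
    rng = np.random.default_rng(seed)
    # permute against sorted copies so epsilon depends only on the bin
    # histograms, not on the order the observations arrived in
    bx_sorted = np.sort(bx)
    by_sorted = np.sort(by)
    perms = np.empty(n_permutations)
    for i in range(n_permutations):
        perms[i] = _mi_from_bins(bx_sorted, rng.permutation(by_sorted), k)
    if epsilon_rule == "min":
        eps = float(perms.min())
    elif epsilon_rule == "mean":
        eps = float(perms.mean())
    else:
        raise ValueError("epsilon_rule must be 'min' or 'mean'")
    corrected = max(raw - eps, 0.0)
    return MIEstimate(raw_mi=raw, epsilon=eps, corrected_mi=corrected,
                      bins=k, n_permutations=n_permutations, seed=seed)


def mi_correlation(mi: MIEstimate | float) -> float:
    """Map an MI value (nats) to a correlation scale: sqrt(1 - e^(-2 MI))."""
    value = mi.corrected_mi if isinstance(mi, MIEstimate) else float(mi)
    if value < 0:
        raise ValueError("MI must be non-negative")
    return float(np.sqrt(1.0 - np.exp(-2.0 * value)))


def temporal_series(expr, metric: str, k: int = 10, n_permutations: int = 100,
                    seed: int | None = 0) -> CorrelationSeries:
    """Transcriptome-wide correlation of each time point with t=0, per replicate.

    `metric` is one of 'pearson', 'spearman', 'bicor', 'mi_c'.  For 'mi_c'
    the t0-vs-t0 value is its self-correlation maximum rather than exactly 1.
    """
    times = expr.time_points
    if 0.0 not in [float(t) for t in times]:
        raise ValueError("expression matrix has no t=0 sample")
    out = {}
    for rep in expr.replicates:
        cols = expr.replicate_columns(rep)
        t0_col = expr.sample_for(0.0, rep)
        x0 = expr.values[t0_col].to_numpy(dtype=float)
        vals = []
        for c in cols:
            xi = expr.values[c].to_numpy(dtype=float)
            if metric == "mi_c":
                est = estimate_mi(x0, xi, k=k, n_permutations=n_permutations,
                                  seed=seed)
                vals.append(mi_correlation(est))
            else:
                vals.append(corr(x0, xi, method=metric))
        out[rep] = pd.Series(vals, index=expr.design.loc[cols, "time_min"].to_numpy())
    return CorrelationSeries(metric=metric, reference_time=0.0,
                             values=pd.DataFrame(out))
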