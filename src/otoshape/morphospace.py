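"""Morphospace construction: covariance PCA, broken-stick retention and
allometric size correction.

The wavelet feature matrix is decomposed by PCA on the variance–covariance
matrix (no per-column rescaling: coefficients share units, and their relative
amplitudes are the signal).  Components are retained while their variance
fraction exceeds the broken-stick null expectation.  Allometry is removed by
subtracting the common (pooled) within-group regression slope of each score on
otolith size — a standardization that zeroes within-group size trends while
leaving between-group mean differences intact, which is what a downstream
classifier needs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "MorphospaceModel",
    "SizeAdjustedScores",
    "pca_covariance",
    "broken_stick_retain",
    "broken_stick_fractions",
    "size_correlation",
    "allometric_residuals",
]


@dataclass
class MorphospaceModel:
    eigenvalues: np.ndarray  # non-increasing variances
    loadings: np.ndarray  # (p, p) orthonormal columns
    scores: np.ndarray  # (N, p) centered data projected on loadings
    mean: np.ndarray  # (p,) column means removed before projection
    variance_fraction: np.ndarray
    retained: int


@dataclass
class SizeAdjustedScores:
    scores: np.ndarray  # (N, k) size-adjusted component scores
    slopes: np.ndarray  # (k,) pooled within-group slopes removed
    group_labels: np.ndarray
    grand_mean_size: float


def pca_covariance(features: np.ndarray, retain: str = "broken-stick") -> MorphospaceModel:
    """PCA on the variance–covariance matrix of mean-centered features.

    Eigenvectors carry a deterministic sign: the largest-magnitude element of
    each loading column is positive.  ``retained`` is the broken-stick count
    computed over the positive (effective-rank) eigenvalues.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("features must be an (N, p) matrix with N >= 3")
    if not np.all(np.isfinite(X)):
        raise ValueError("features contain non-finite values")
    mean = X.mean(axis=0)
    Xc = X - mean
    cov = (Xc.T @ Xc) / (X.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    total = evals.sum()
    if total <= 0:
        raise ValueError("constant feature matrix: zero covariance")
    # deterministic sign: largest-|.| element of each loading positive
    flip = evecs[np.argmax(np.abs(evecs), axis=0), np.arange(evecs.shape[1])] < 0
    evecs[:, flip] *= -1.0
    scores = Xc @ evecs
    positive = evals > 1e-12 * evals[0]
    retained = broken_stick_retain(evals[positive]) if retain == "broken-stick" else int(positive.sum())
    return MorphospaceModel(
        eigenvalues=evals,
        loadings=evecs,
        scores=scores,
        mean=mean,
        variance_fraction=evals / total,
        retained=retained,
    )


def broken_stick_fractions(p: int) -> np.ndarray:
    """Broken-stick null expectation b_i = (1/p) * sum_{j=i..p} 1/j."""
    inv = 1.0 / np.arange(1, p + 1)
    return np.cumsum(inv[::-1])[::-1] / p


def broken_stick_retain(eigenvalues: np.ndarray, consecutive: bool = True) -> int:
    """Number of leading components whose variance fraction beats the broken stick.

    By default the count is the leading consecutive run above expectation
    (stops at the first failure); ``consecutive=False`` counts every component
    above its expectation instead.
    """
    ev = np.asarray(eigenvalues, dtype=float)
    if ev.ndim != 1 or ev.size == 0:
        raise ValueError("eigenvalues must be a non-empty 1-D array")
    if np.any(ev < 0) or not np.all(np.isfinite(ev)):
        raise ValueError("eigenvalues must be finite and nonnegative")
    total = ev.sum()
    if total <= 0:
        raise ValueError("all eigenvalues are zero")
    frac = ev / total
    above = frac > broken_stick_fractions(ev.size)
    if not consecutive:
        return int(above.sum())
    run = 0
    for a in above:
        if not a:
            break
        run += 1
    return run


def size_correlation(scores: np.ndarray, sizes: np.ndarray):
    """Pearson r (and two-sided p from the t transform) of each score vs size."""
    S = np.atleast_2d(np.asarray(scores, dtype=float))
    if S.shape[0] == 1:
        S = S.T
    x = np.asarray(sizes, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if S.shape[0] != n:
        raise ValueError("scores and sizes disagree in length")
    if np.std(x) == 0:
        raise ValueError("size vector has zero variance")
    xc = x - x.mean()
    Sc = S - S.mean(axis=0)
    sxx = float(xc @ xc)
    syy = (Sc**2).sum(axis=0)
    # scores constant up to float noise count as zero-variance (r = 0)
    score_scale = np.maximum(np.abs(S).max(axis=0), 1.0)
    zero_var = np.sqrt(syy) <= 1e-9 * score_scale
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ Sc) / np.sqrt(sxx * syy)
    r = np.where(zero_var, 0.0, r)
    r = np.clip(r, -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2))
    p = np.where(np.abs(r) == 1.0, 0.0, 2.0 * stats.t.sf(np.abs(t), df))
    return r, p


def allometric_residuals(scores, sizes, groups) -> SizeAdjustedScores:
    """Remove the common within-group size slope from each component score.

    For component y with size x, the pooled within-group slope is
    b = sum_g Sxy(g) / sum_g Sxx(g); the adjusted score is
    y' = y - b * (x - grand mean of x).  Subtracting the grand-mean-anchored
    trend (rather than per-group residuals) preserves between-group mean
    differences.
    """
    S = np.atleast_2d(np.asarray(scores, dtype=float))
    if S.shape[0] == 1:
        S = S.T
    x = np.asarray(sizes, dtype=float)
    g = np.asarray(groups)
    n = x.size
    if S.shape[0] != n or g.size != n:
        raise ValueError("scores, sizes and groups disagree in length")
    sxx_total = 0.0
    sxy_total = np.zeros(S.shape[1])
    for name in np.unique(g):
        idx = g == name
        if idx.sum() < 2:
            raise ValueError(f"group {name!r} has fewer than 2 members")
        xg = x[idx] - x[idx].mean()
        sxx_total += float(xg @ xg)
        sxy_total += xg @ (S[idx] - S[idx].mean(axis=0))
    if sxx_total == 0:
        raise ValueError("no within-group size variation; cannot estimate slopes")
    b = sxy_total / sxx_total
    grand = float(x.mean())
    adjusted = S - np.outer(x - grand, b)
    return SizeAdjustedScores(scores=adjusted, slopes=b, group_labels=g, grand_mean_size=grand)
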