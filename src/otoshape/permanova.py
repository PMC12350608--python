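"""PERMANOVA on Manhattan distances, implemented from the sums-of-squares
partition.

For N points in ``a`` groups with pairwise distances d_ij:

    SS_total  = (1/N) * sum_{i<j} d_ij^2
    SS_within = sum_g (1/n_g) * sum_{i<j in g} d_ij^2
    SS_among  = SS_total - SS_within
    pseudo-F  = (SS_among / (a-1)) / (SS_within / (N-a))

The p-value comes from unrestricted random permutations of the group labels,
with the observed statistic counted among the null set (so p >= 1/(n_perm+1))
and ties counted as exceedances.  Small designs can be tested exactly by
enumerating every distinct label arrangement.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sympy.utilities.iterables import multiset_permutations

__all__ = [
    "DistanceMatrix",
    "PermanovaResult",
    "manhattan_distances",
    "permanova_global",
    "permanova_pairwise",
]


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative distance matrix with a zero diagonal."""

    values: np.ndarray
    metric: str = "manhattan"

    def __post_init__(self) -> None:
        D = np.asarray(self.values, dtype=float)
        if D.ndim != 2 or D.shape[0] != D.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.all(np.isfinite(D)):
            raise ValueError("distance matrix contains non-finite entries")
        if np.any(D < 0) or not np.allclose(D, D.T) or np.any(np.diag(D) != 0):
            raise ValueError("not a valid distance matrix")
        self.values = D

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class PermanovaResult:
    pseudo_F: float
    p_value: float
    df_among: int
    df_within: int
    ss_among: float
    ss_within: float
    ss_total: float
    n_permutations: int
    seed: int | None
    method: str = "permutation"
    note: str | None = None


def manhattan_distances(X: np.ndarray) -> DistanceMatrix:
    """Pairwise Manhattan (city-block) distances between rows of X."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be an (N, k) matrix")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite entries")
    return DistanceMatrix(squareform(pdist(X, metric="cityblock")))


def _codes_and_counts(groups) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(groups)
    _, codes = np.unique(labels, return_inverse=True)
    counts = np.bincount(codes)
    return codes, counts


def _ss_within(D2: np.ndarray, codes: np.ndarray, counts: np.ndarray) -> float:
    ssw = 0.0
    for g, n_g in enumerate(counts):
        idx = codes == g
        ssw += D2[np.ix_(idx, idx)].sum() / (2.0 * n_g)
    return ssw


def _ss_within_many(D2: np.ndarray, code_matrix: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """SS_within for each row of codes in ``code_matrix`` (m, N), vectorized."""
    out = np.zeros(code_matrix.shape[0])
    for g, n_g in enumerate(counts):
        M = (code_matrix == g).astype(float)
        out += ((M @ D2) * M).sum(axis=1) / (2.0 * n_g)
    return out


def _pseudo_f(ss_among: np.ndarray, ss_within: np.ndarray, df_among: int, df_within: int):
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(
            ss_within > 0,
            (ss_among / df_among) / (ss_within / df_within),
            np.inf,
        )


def permanova_global(
    D: DistanceMatrix,
    groups,
    n_perm: int = 9999,
    seed: int | None = None,
    method: str = "permutation",
) -> PermanovaResult:
    """One-way PERMANOVA of the grouping factor on a distance matrix.

    ``method='permutation'`` draws ``n_perm`` unrestricted label shuffles and
    reports p = (#{F* >= F} + 1) / (n_perm + 1).  ``method='exact'``
    enumerates every distinct arrangement of the label multiset and reports
    the exact proportion with F* >= F (the observed arrangement included).
    """
    if isinstance(D, np.ndarray):
        D = DistanceMatrix(D, metric="unspecified")
    codes, counts = _codes_and_counts(groups)
    N = D.n
    if codes.size != N:
        raise ValueError("groups must have one label per distance-matrix row")
    a = counts.size
    if a < 2:
        raise ValueError("need at least 2 groups")
    if np.any(counts < 2):
        raise ValueError("every group needs at least 2 members")
    D2 = D.values**2
    ss_total = D2.sum() / (2.0 * N)
    ss_within = _ss_within(D2, codes, counts)
    ss_among = ss_total - ss_within
    df_among, df_within = a - 1, N - a
    f_obs = float(_pseudo_f(np.asarray(ss_among), np.asarray(ss_within), df_among, df_within))
    thresh = f_obs - 1e-12 * max(1.0, abs(f_obs)) if np.isfinite(f_obs) else np.inf

    if method == "exact":
        exceed = 0
        total = 0
        for perm in multiset_permutations(codes.tolist()):
            ssw = _ss_within(D2, np.asarray(perm), counts)
            f_star = float(_pseudo_f(np.asarray(ss_total - ssw), np.asarray(ssw), df_among, df_within))
            total += 1
            if f_star >= thresh:
                exceed += 1
        return PermanovaResult(
            pseudo_F=f_obs,
            p_value=exceed / total,
            df_among=df_among,
            df_within=df_within,
            ss_among=float(ss_among),
            ss_within=float(ss_within),
            ss_total=float(ss_total),
            n_permutations=total,
            seed=None,
            method="exact",
        )
    if method != "permutation":
        raise ValueError(f"unknown method {method!r}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    exceed = 0
    chunk = 1024
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        perms = rng.permuted(np.tile(codes, (m, 1)), axis=1)
        ssw = _ss_within_many(D2, perms, counts)
        f_star = _pseudo_f(ss_total - ssw, ssw, df_among, df_within)
        exceed += int(np.sum(f_star >= thresh))
        done += m
    return PermanovaResult(
        pseudo_F=f_obs,
        p_value=(exceed + 1) / (n_perm + 1),
        df_among=df_among,
        df_within=df_within,
        ss_among=float(ss_among),
        ss_within=float(ss_within),
        ss_total=float(ss_total),
        n_permutations=n_perm,
        seed=seed,
        method="permutation",
    )


def permanova_pairwise(
    D: DistanceMatrix,
    groups,
    n_perm: int = 9999,
    correction: str = "bonferroni",
    seed: int | None = None,
) -> pd.DataFrame:
    """All pairwise PERMANOVAs with Bonferroni-adjusted p-values.

    Each pair is tested on its own submatrix with fresh permutations (seeds
    fanned out from ``seed``); adjusted p = min(1, raw p * number of pairs).
    """
    if isinstance(D, np.ndarray):
        D = DistanceMatrix(D, metric="unspecified")
    labels = np.asarray(groups)
    names = list(dict.fromkeys(labels.tolist()))
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    pairs = list(combinations(names, 2))
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(pairs))
    rows = []
    for (g1, g2), child in zip(pairs, children):
        idx = np.flatnonzero((labels == g1) | (labels == g2))
        sub = DistanceMatrix(D.values[np.ix_(idx, idx)], metric=D.metric)
        res = permanova_global(
            sub, labels[idx], n_perm=n_perm, seed=int(child.generate_state(1)[0] % 2**31)
        )
        rows.append((g1, g2, res.pseudo_F, res.p_value))
    df = pd.DataFrame(rows, columns=["group1", "group2", "pseudo_F", "p_value"])
    if correction == "bonferroni":
        df["p_adjusted"] = np.minimum(1.0, df["p_value"] * len(pairs))
    elif correction is None or correction == "none":
        df["p_adjusted"] = df["p_value"]
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return df
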