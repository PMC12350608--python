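"""Morphotype discovery: Ward hierarchical clustering, tree cutting and
composition summaries.

Clustering uses the classic 'ward.D' criterion — the Lance–Williams ward
update applied to the input Euclidean dissimilarities as-is, without squaring
them first (the variant distinct from ward.D2, which operates on squared
distances).  Morphotype labels are arbitrary cluster identities; grouping them
into biological classes (upper/lower rostrum, antirostrum development) is done
through user-supplied maps since identities permute across runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree as _scipy_cut_tree
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import silhouette_score

from .permanova import DistanceMatrix, PermanovaResult, manhattan_distances, permanova_global

__all__ = [
    "Dendrogram",
    "MorphotypeTable",
    "ward_cluster",
    "cut_tree",
    "morphotype_composition",
    "morphotype_separation_test",
    "silhouette_profile",
]


@dataclass
class Dendrogram:
    """Agglomeration history in scipy linkage layout.

    ``merges`` is (N-1, 4): the two cluster ids joined (originals 0..N-1,
    merged clusters N, N+1, ...), the merge height, and the new cluster size.
    """

    merges: np.ndarray
    linkage: str = "ward.D"
    n_leaves: int = 0

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]


@dataclass
class MorphotypeTable:
    assignments: np.ndarray  # morphotype id (1..k) per individual
    proportions: pd.DataFrame  # morphotype x population, columns sum to 1
    rostrum: pd.DataFrame | None = None  # class x population aggregation
    antirostrum: pd.DataFrame | None = None


def ward_cluster(X: np.ndarray) -> Dendrogram:
    """Agglomerative ward.D clustering of the rows of X.

    Euclidean inter-point distances enter the Lance–Williams ward recurrence
    unsquared: on merging clusters i, j (sizes n_i, n_j),

        d(ij, k) = [(n_i + n_k) d(i,k) + (n_j + n_k) d(j,k) - n_k d(i,j)]
                   / (n_i + n_j + n_k).

    The closest active pair merges at each step; exact ties break toward the
    lexicographically smallest pair of cluster indices.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("X must be an (N, k) matrix with N >= 2")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    N = X.shape[0]
    d = squareform(pdist(X))
    np.fill_diagonal(d, np.inf)
    size = np.ones(N)
    cluster_id = np.arange(N)
    active = np.ones(N, dtype=bool)
    merges = np.empty((N - 1, 4))
    for step in range(N - 1):
        # argmin over active pairs; flat argmin returns the first (row-major)
        # minimum, i.e. the lexicographically smallest slot pair
        masked = np.where(np.outer(active, active), d, np.inf)
        flat = int(np.argmin(masked))
        i, j = divmod(flat, N)
        if i > j:
            i, j = j, i
        h = d[i, j]
        id_i, id_j = cluster_id[i], cluster_id[j]
        lo, hi = (id_i, id_j) if id_i < id_j else (id_j, id_i)
        merges[step] = (lo, hi, h, size[i] + size[j])
        # Lance-Williams ward update into slot i
        k_mask = active.copy()
        k_mask[[i, j]] = False
        nk = size[k_mask]
        d_new = ((size[i] + nk) * d[i, k_mask] + (size[j] + nk) * d[j, k_mask]
                 - nk * h) / (size[i] + size[j] + nk)
        d[i, k_mask] = d_new
        d[k_mask, i] = d_new
        size[i] += size[j]
        active[j] = False
        d[j, :] = np.inf
        d[:, j] = np.inf
        cluster_id[i] = N + step
    return Dendrogram(merges=merges, linkage="ward.D", n_leaves=N)


def cut_tree(dendrogram: Dendrogram, k: int) -> np.ndarray:
    """Cut a dendrogram into k clusters by undoing the last k-1 merges.

    Clusters are labeled 1..k in order of first appearance along the input.
    """
    N = dendrogram.n_leaves
    if not 1 <= k <= N:
        raise ValueError(f"k must be in 1..{N}, got {k}")
    raw = _scipy_cut_tree(dendrogram.merges, n_clusters=k).ravel()
    relabel: dict[int, int] = {}
    out = np.empty(N, dtype=int)
    for idx, lab in enumerate(raw):
        if lab not in relabel:
            relabel[lab] = len(relabel) + 1
        out[idx] = relabel[lab]
    return out


def morphotype_composition(
    assignments,
    populations,
    rostrum_map: dict | None = None,
    antirostrum_map: dict | None = None,
) -> MorphotypeTable:
    """Cross-tabulate morphotype fractions per population.

    Optional maps aggregate morphotypes into rostrum (upper/lower) or
    antirostrum (less/well developed) classes; every observed morphotype must
    be mapped or an error is raised.
    """
    a = np.asarray(assignments)
    p = np.asarray(populations)
    if a.size != p.size:
        raise ValueError("assignments and populations disagree in length")
    tab = pd.crosstab(pd.Series(a, name="morphotype"), pd.Series(p, name="population"))
    props = tab / tab.sum(axis=0)

    def _aggregate(mapping: dict) -> pd.DataFrame:
        missing = [m for m in tab.index if m not in mapping]
        if missing:
            raise ValueError(f"morphotypes without a class mapping: {missing}")
        return props.groupby([mapping[m] for m in props.index]).sum()

    return MorphotypeTable(
        assignments=a,
        proportions=props,
        rostrum=_aggregate(rostrum_map) if rostrum_map is not None else None,
        antirostrum=_aggregate(antirostrum_map) if antirostrum_map is not None else None,
    )


def morphotype_separation_test(
    X: np.ndarray, assignments, n_perm: int = 9999, seed: int | None = None
) -> PermanovaResult:
    """PERMANOVA of cluster labels on the clustered data (circular by design).

    The labels were derived from the very matrix being tested, which inflates
    significance; the result carries an explicit warning note and this
    function warns at call time.
    """
    warnings.warn(
        "testing cluster-derived labels on the data they came from inflates "
        "significance; interpret p as descriptive only",
        stacklevel=2,
    )
    res = permanova_global(manhattan_distances(X), assignments, n_perm=n_perm, seed=seed)
    res.note = "circular: labels derived from the tested data"
    return res


def silhouette_profile(X: np.ndarray, k_min: int = 2, k_max: int = 10) -> dict[int, float]:
    """Mean silhouette width of ward.D partitions for k in [k_min, k_max]."""
    X = np.asarray(X, dtype=float)
    dend = ward_cluster(X)
    out = {}
    for k in range(k_min, min(k_max, X.shape[0] - 1) + 1):
        labels = cut_tree(dend, k)
        if np.unique(labels).size < 2:
            continue
        out[k] = float(silhouette_score(X, labels))
    return out
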