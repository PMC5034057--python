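"""Sample and gene clustering: Ward trees with bootstrap support, k-means
response clusters, and template-based semantic labelling.

Sample relationships are summarised by agglomerative clustering of
log-expression profiles under Manhattan distance with Ward's linkage, with
node support estimated as the plain bootstrap probability (BP): the percent
of gene resamples in which a node's exact leaf set recurs. Hypoxia-regulated
genes are partitioned into k response clusters by k-means on z-scored
per-condition mean profiles, and the arbitrary k-means labels are mapped onto
the canonical response-cluster semantics by Hungarian matching of centroids
against effect templates.

Ward's linkage on a non-Euclidean (Manhattan) dissimilarity is geometrically
improper but is the established convention of the clustering tools this
mirrors; the Lance-Williams Ward update is applied to the squared input
distances and merge heights reported on the original distance scale (the
"Ward.D2" convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans

__all__ = [
    "DistanceMatrix",
    "Dendrogram",
    "GeneClusterAssignment",
    "manhattan_distances",
    "ward_agglomerate",
    "bootstrap_support",
    "standardize_rows",
    "kmeans_assign",
    "label_clusters_by_template",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distances with a zero diagonal."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError(f"distance matrix shape {v.shape} does not match {n} ids")
        if np.any(v < 0):
            raise ValueError("distances must be non-negative")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.ids)


@dataclass(frozen=True)
class Dendrogram:
    """Binary merge tree in scipy linkage convention.

    ``merges`` has one row per internal node: (child a, child b, merge height,
    leaf count), where children < n are leaves (indices into ``leaf_ids``) and
    children >= n refer to earlier merge rows. ``bp`` optionally carries the
    bootstrap probability (percent) of each internal node.
    """

    leaf_ids: tuple[str, ...]
    merges: np.ndarray
    bp: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.leaf_ids)
        m = np.asarray(self.merges, dtype=float)
        if m.shape != (n - 1, 4):
            raise ValueError(f"expected {n - 1} merges for {n} leaves, got {m.shape}")
        if self.bp is not None:
            b = np.asarray(self.bp, dtype=float)
            if b.shape != (n - 1,):
                raise ValueError("bp must have one value per internal node")
            if np.any((b < 0) | (b > 100)):
                raise ValueError("bp values must lie in [0, 100]")
            object.__setattr__(self, "bp", b)
        object.__setattr__(self, "merges", m)

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def node_leafsets(self) -> list[frozenset[str]]:
        """Leaf-id set of each internal node, in merge order."""
        n = self.n_leaves
        members: list[frozenset[str]] = [frozenset([lid]) for lid in self.leaf_ids]
        out = []
        for a, b, _h, _c in self.merges:
            merged = members[int(a)] | members[int(b)]
            members.append(merged)
            out.append(merged)
        return out

    def has_clade(self, leaves: set[str] | frozenset[str]) -> bool:
        return frozenset(leaves) in set(self.node_leafsets())

    def support_for(self, leaves: set[str] | frozenset[str]) -> float:
        """BP of the internal node with exactly this leaf set."""
        if self.bp is None:
            raise ValueError("dendrogram carries no bootstrap support")
        target = frozenset(leaves)
        for node, support in zip(self.node_leafsets(), self.bp):
            if node == target:
                return float(support)
        raise KeyError(f"no internal node with leaf set {sorted(target)}")


def manhattan_distances(profiles: pd.DataFrame, axis: str = "rows") -> DistanceMatrix:
    """Pairwise L1 distances between rows or columns of a profile matrix."""
    if axis not in ("rows", "columns"):
        raise ValueError("axis must be 'rows' or 'columns'")
    x = profiles.to_numpy(dtype=float)
    ids = profiles.index if axis == "rows" else profiles.columns
    if axis == "columns":
        x = x.T
    if np.any(np.isnan(x)):
        raise ValueError("profiles contain NaN")
    return DistanceMatrix(tuple(str(i) for i in ids), squareform(pdist(x, metric="cityblock")))


def ward_agglomerate(dist: DistanceMatrix) -> Dendrogram:
    """Agglomerate by Ward's criterion (Lance-Williams on squared distances).

    Deterministic: exact ties are broken by the earliest pair in index order.
    Merge heights are the square roots of the minimised Ward criterion, i.e.
    on the scale of the input distances.
    """
    n = len(dist)
    if n < 2:
        raise ValueError("need at least 2 items to cluster")
    d2 = dist.values.astype(float) ** 2
    size = np.ones(n)
    labels = list(range(n))  # scipy-style cluster labels for active rows
    active = d2.copy()
    np.fill_diagonal(active, np.inf)
    merges = np.empty((n - 1, 4))
    next_label = n
    for step in range(n - 1):
        m = active.shape[0]
        iu = np.triu_indices(m, 1)
        flat = active[iu]
        j = int(np.argmin(flat))  # first minimum in row-major upper-triangular
        a, b = int(iu[0][j]), int(iu[1][j])  # a < b
        height = float(np.sqrt(flat[j]))
        sa, sb = size[a], size[b]
        # Lance-Williams Ward update for squared distances to every other cluster
        keep = np.array([k for k in range(m) if k not in (a, b)], dtype=int)
        if keep.size:
            sk = size[keep]
            new_row = ((sa + sk) * active[a, keep] + (sb + sk) * active[b, keep]
                       - sk * active[a, b]) / (sa + sb + sk)
        merges[step] = (labels[a], labels[b], height, sa + sb)
        # collapse b into a, relabel a as the new cluster
        if keep.size:
            sub = active[np.ix_(keep, keep)]
            m2 = keep.size + 1
            nxt = np.full((m2, m2), np.inf)
            nxt[:-1, :-1] = sub
            nxt[-1, :-1] = new_row
            nxt[:-1, -1] = new_row
            active = nxt
            size = np.concatenate([size[keep], [sa + sb]])
            labels = [labels[k] for k in keep] + [next_label]
        else:
            active = np.full((1, 1), np.inf)
            size = np.array([sa + sb])
            labels = [next_label]
        next_label += 1
    return Dendrogram(dist.ids, merges)


def bootstrap_support(
    expr: pd.DataFrame, n_boot: int = 1000, seed: int = 0
) -> Dendrogram:
    """Sample dendrogram with bootstrap probabilities on internal nodes.

    Columns of ``expr`` (samples) are clustered on the full gene set; then
    genes (rows) are resampled with replacement ``n_boot`` times and the
    samples re-clustered each time. BP(node) is the percent of resamples in
    which the node's exact leaf set recurs as a cluster.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if expr.shape[0] < 2 or expr.shape[1] < 2:
        raise ValueError("need at least 2 genes and 2 samples")
    base = ward_agglomerate(manhattan_distances(expr, axis="columns"))
    targets = base.node_leafsets()
    counts = np.zeros(len(targets))
    x = expr.to_numpy(dtype=float)
    ids = base.leaf_ids
    rng = np.random.default_rng(seed)
    g = x.shape[0]
    for _ in range(n_boot):
        xb = x[rng.integers(0, g, size=g)]
        db = DistanceMatrix(ids, squareform(pdist(xb.T, metric="cityblock")))
        clades = set(ward_agglomerate(db).node_leafsets())
        for i, t in enumerate(targets):
            if t in clades:
                counts[i] += 1
    return Dendrogram(ids, base.merges, bp=100.0 * counts / n_boot)


def standardize_rows(expr: pd.DataFrame) -> pd.DataFrame:
    """Z-score each row (population SD); constant rows map to all zeros."""
    x = expr.to_numpy(dtype=float)
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)  # population SD
    constant = (sd == 0).ravel()
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant row(s) standardised to zeros",
            stacklevel=2,
        )
    z = np.where(sd > 0, (x - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return pd.DataFrame(z, index=expr.index, columns=expr.columns)


@dataclass(frozen=True)
class GeneClusterAssignment:
    """k-means partition of gene response profiles.

    ``labels`` maps gene id to cluster id 1..k; ``centroids`` is k x
    profile-dimension (index 1..k); ``semantic_labels`` optionally maps each
    k-means cluster id onto a canonical response-cluster number.
    """

    labels: pd.Series
    centroids: pd.DataFrame
    inertia: float
    semantic_labels: dict[int, int] | None = None

    @property
    def k(self) -> int:
        return len(self.centroids)

    def members(self, cluster: int) -> list[str]:
        return self.labels.index[self.labels == cluster].tolist()


def kmeans_assign(
    profiles: pd.DataFrame, k: int = 4, seed: int = 0, n_init: int = 25
) -> GeneClusterAssignment:
    """Best-of-``n_init`` k-means++ / Lloyd partition, deterministic under seed."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if profiles.empty:
        raise ValueError("empty profile matrix")
    if k > len(profiles):
        raise ValueError(f"k={k} exceeds the number of genes ({len(profiles)})")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, random_state=seed,
                algorithm="lloyd")
    labels = km.fit_predict(profiles.to_numpy(dtype=float))
    return GeneClusterAssignment(
        labels=pd.Series(labels + 1, index=profiles.index, name="cluster"),
        centroids=pd.DataFrame(
            km.cluster_centers_,
            index=pd.RangeIndex(1, k + 1, name="cluster"),
            columns=profiles.columns,
        ),
        inertia=float(km.inertia_),
    )


def label_clusters_by_template(
    centroids: pd.DataFrame, templates: pd.DataFrame
) -> dict[int, int]:
    """Match k-means centroids one-to-one onto template rows.

    Maximises total cosine similarity (Hungarian assignment). Returns a map
    from centroid cluster id to template row label. Requires as many centroids
    as template rows and matching profile dimensions.
    """
    if centroids.shape != (len(templates), templates.shape[1]):
        raise ValueError(
            f"centroid matrix {centroids.shape} does not match templates {templates.shape}"
        )
    c = centroids.to_numpy(dtype=float)
    t = templates.to_numpy(dtype=float)

    def unit(rows: np.ndarray) -> np.ndarray:
        norms = np.linalg.norm(rows, axis=1, keepdims=True)
        return np.where(norms > 0, rows / np.where(norms > 0, norms, 1.0), 0.0)

    sim = unit(c) @ unit(t).T
    rows, cols = linear_sum_assignment(-sim)
    return {
        int(centroids.index[r]): int(templates.index[c_]) for r, c_ in zip(rows, cols)
    }
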