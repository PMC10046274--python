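"""The three clustering methods: Ward hierarchical, Taylor–Butina, UMAP + agglomerative.

Ward hierarchical clustering is implemented directly from the Lance–Williams
recurrence on squared distances:

    d(k, i+j)^2 = [ (n_i+n_k) d(i,k)^2 + (n_j+n_k) d(j,k)^2 - n_k d(i,j)^2 ]
                  / (n_i + n_j + n_k)

with two singletons merging at their input distance.  Taylor–Butina
exclusion-sphere clustering repeatedly promotes the unassigned molecule with
the most unassigned neighbors (Tanimoto >= cutoff) to centroid and absorbs
those neighbors; molecules left without unassigned neighbors become
singletons even if they had neighbors ("false singletons").  The UMAP route
embeds fingerprints in a low-dimensional space (delegated to umap-learn;
re-implementing the embedding optimizer is out of scope) and applies Ward
agglomeration on the Euclidean embedding distances, cut to an exact cluster
count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .mol_io import FingerprintSet
from .similarity import CondensedDistanceMatrix, pair_count


@dataclass
class LinkageTree:
    """Ordered merge list of an agglomerative clustering.

    Each merge is (left node, right node, height, merged size); leaves are
    nodes 0..n_leaves-1 and the merge at position m creates node n_leaves+m
    (the scipy linkage convention).  Ward heights are non-decreasing.
    """

    merges: np.ndarray  # (n_leaves-1, 4) float: left, right, height, size
    n_leaves: int

    def __post_init__(self) -> None:
        self.merges = np.asarray(self.merges, dtype=np.float64).reshape(-1, 4)
        if self.merges.shape[0] != self.n_leaves - 1:
            raise ValidationError("a binary merge tree over n leaves has exactly n-1 merges")
        heights = self.merges[:, 2]
        if heights.size and np.any(np.diff(heights) < -1e-9):
            raise ValidationError("merge heights must be non-decreasing (Ward monotonicity)")

    def to_scipy(self) -> np.ndarray:
        """The merge table as a scipy ``linkage`` Z matrix."""
        return self.merges.copy()


@dataclass
class ClusterAssignment:
    """Per-molecule integer cluster labels plus method metadata."""

    ids: list[str]
    labels: np.ndarray
    method: str
    params: dict = field(default_factory=dict)
    butina_role: list[str] | None = None  # per-molecule centroid/member/singleton

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.shape != (len(self.ids),):
            raise ValidationError("labels must have one entry per molecule")
        if self.labels.size:
            k = self.labels.max() + 1
            if self.labels.min() < 0 or len(np.unique(self.labels)) != k:
                raise ValidationError("labels must cover 0..k-1 with no empty cluster")
        if (self.butina_role is not None) != (self.method == "butina"):
            raise ValidationError("butina_role must be present exactly for the butina method")

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0


@dataclass
class UmapConfig:
    """Hyperparameters of the embedding + agglomerative clustering route.

    ``n_neighbors`` balances local against global structure, ``min_dist``
    controls how tightly the embedding packs points, ``metric`` is the
    distance applied to the binary fingerprint rows (jaccard = 1 - Tanimoto),
    and ``n_clusters`` is the agglomerative cut applied to the embedding.
    """

    n_neighbors: int = 100
    min_dist: float = 0.0
    n_components: int = 2
    metric: str = "jaccard"
    n_clusters: int = 7
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_neighbors < 2:
            raise ValidationError("n_neighbors must be >= 2")
        if not 0.0 <= self.min_dist < 1.0:
            raise ValidationError("min_dist must lie in [0, 1)")
        if self.n_components < 1:
            raise ValidationError("n_components must be >= 1")
        if self.n_clusters < 1:
            raise ValidationError("n_clusters must be >= 1")


def _as_condensed_values(d: CondensedDistanceMatrix | np.ndarray) -> tuple[np.ndarray, int, list[str] | None]:
    if isinstance(d, CondensedDistanceMatrix):
        return np.asarray(d.values, dtype=np.float64), d.n, list(d.ids)
    values = np.asarray(d, dtype=np.float64)
    # invert m = n(n-1)/2
    n = int(round((1 + np.sqrt(1 + 8 * values.size)) / 2))
    if pair_count(n) != values.size:
        raise ValidationError("array length is not a valid condensed-matrix size")
    return values, n, None


def ward_linkage(d: CondensedDistanceMatrix | np.ndarray) -> LinkageTree:
    """Greedy Ward agglomeration of a condensed distance matrix.

    At each step the pair of clusters at minimal (Ward-updated) distance is
    merged; distances to the merged cluster follow the Lance–Williams Ward
    recurrence on squared distances.  Ties resolve to the lexicographically
    smallest cluster pair.  Heights are checked to be non-decreasing.
    """
    values, n, _ = _as_condensed_values(d)
    if n < 2:
        raise ValidationError("ward linkage requires at least 2 molecules")

    from scipy.spatial.distance import squareform

    D2 = squareform(values) ** 2
    np.fill_diagonal(D2, np.inf)
    active = np.ones(n, dtype=bool)
    sizes = np.ones(n, dtype=np.float64)
    node_id = np.arange(n, dtype=np.int64)  # current tree-node id living in each slot
    merges = np.empty((n - 1, 4), dtype=np.float64)

    work = D2.copy()
    for step in range(n - 1):
        # first (row-major) occurrence of the minimum = lexicographically
        # smallest pair, giving a deterministic tie-break
        flat = np.argmin(work)
        i, j = divmod(int(flat), n)
        if i > j:
            i, j = j, i
        h2 = work[i, j]
        height = float(np.sqrt(max(h2, 0.0)))
        ni, nj = sizes[i], sizes[j]
        merges[step] = (node_id[i], node_id[j], height, ni + nj)

        # Lance-Williams Ward update of distances to the merged cluster (slot i)
        others = active.copy()
        others[i] = others[j] = False
        nk = sizes[others]
        dik2 = work[i, others]
        djk2 = work[j, others]
        work[i, others] = ((ni + nk) * dik2 + (nj + nk) * djk2 - nk * h2) / (ni + nj + nk)
        work[others, i] = work[i, others]
        # retire slot j
        active[j] = False
        work[j, :] = np.inf
        work[:, j] = np.inf
        work[i, i] = np.inf
        sizes[i] = ni + nj
        node_id[i] = n + step

    heights = merges[:, 2]
    if np.any(np.diff(heights) < -1e-9):  # Ward monotonicity safety check
        raise AssertionError("Ward merge heights decreased; numerical failure")
    # clamp tiny negative drifts so the tree invariant holds exactly
    merges[:, 2] = np.maximum.accumulate(heights)
    return LinkageTree(merges=merges, n_leaves=n)


def _labels_from_merge_prefix(tree: LinkageTree, n_merges: int) -> np.ndarray:
    """Flat labels after applying the first ``n_merges`` merges, numbered by first leaf."""
    n = tree.n_leaves
    parent = np.arange(n + n_merges, dtype=np.int64)

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for m in range(n_merges):
        left, right = int(tree.merges[m, 0]), int(tree.merges[m, 1])
        new = n + m
        parent[find(left)] = new
        parent[find(right)] = new

    labels = np.empty(n, dtype=np.int64)
    seen: dict[int, int] = {}
    for leaf in range(n):  # label clusters in order of first leaf appearance
        root = find(leaf)
        if root not in seen:
            seen[root] = len(seen)
        labels[leaf] = seen[root]
    return labels


def cut_tree(tree: LinkageTree, height_cutoff: float,
             ids: Sequence[str] | None = None) -> ClusterAssignment:
    """Flat clustering from all merges at height <= cutoff (cophenetic criterion)."""
    if height_cutoff <= 0:
        raise ValidationError("height_cutoff must be positive")
    n_merges = int(np.searchsorted(tree.merges[:, 2], height_cutoff, side="right"))
    labels = _labels_from_merge_prefix(tree, n_merges)
    return ClusterAssignment(
        ids=list(ids) if ids is not None else [str(i) for i in range(tree.n_leaves)],
        labels=labels,
        method="ward",
        params={"height_cutoff": height_cutoff},
    )


def cut_tree_k(tree: LinkageTree, n_clusters: int,
               ids: Sequence[str] | None = None, method: str = "ward") -> ClusterAssignment:
    """Flat clustering with exactly ``n_clusters`` clusters (drop the last k-1 merges)."""
    n = tree.n_leaves
    if not 1 <= n_clusters <= n:
        raise ValidationError("n_clusters must lie in [1, n]")
    labels = _labels_from_merge_prefix(tree, n - n_clusters)
    return ClusterAssignment(
        ids=list(ids) if ids is not None else [str(i) for i in range(n)],
        labels=labels,
        method=method,
        params={"n_clusters": n_clusters},
    )


def butina_cluster(d: CondensedDistanceMatrix, similarity_cutoff: float) -> ClusterAssignment:
    """Taylor–Butina exclusion-sphere clustering at a Tanimoto similarity cutoff.

    j is a neighbor of i iff tanimoto(i, j) >= cutoff.  Each round promotes
    the unassigned molecule with the most unassigned neighbors (ties: lowest
    molecule index) to centroid of a new cluster and assigns it together with
    all its unassigned neighbors; neighbor counts are recomputed against the
    remaining unassigned molecules each round.  Molecules ending up alone are
    singletons — possibly "false" singletons whose neighbors were attracted
    by a better centroid.  Every member's similarity to its centroid is >=
    cutoff by construction.
    """
    if not 0.0 < similarity_cutoff <= 1.0:
        raise ValidationError("similarity_cutoff must lie in (0, 1]")
    n = d.n
    sim = 1.0 - d.square()
    neighbors = sim >= similarity_cutoff
    np.fill_diagonal(neighbors, False)

    labels = np.full(n, -1, dtype=np.int64)
    roles = ["singleton"] * n
    unassigned = np.ones(n, dtype=bool)
    next_label = 0
    while unassigned.any():
        counts = (neighbors & unassigned[None, :]).sum(axis=1)
        counts[~unassigned] = -1
        centroid = int(np.argmax(counts))  # first max = lowest index on ties
        members = np.flatnonzero(neighbors[centroid] & unassigned)
        labels[centroid] = next_label
        unassigned[centroid] = False
        if members.size:
            roles[centroid] = "centroid"
            labels[members] = next_label
            unassigned[members] = False
            for m in members:
                roles[m] = "member"
        next_label += 1

    return ClusterAssignment(
        ids=list(d.ids),
        labels=labels,
        method="butina",
        params={"similarity_cutoff": similarity_cutoff},
        butina_role=roles,
    )


def umap_embed(fps: FingerprintSet, cfg: UmapConfig) -> np.ndarray:
    """Low-dimensional embedding of the fingerprint rows (delegated to umap-learn).

    The configured metric (jaccard by default, i.e. 1 - Tanimoto) is applied
    to the binary rows; a fixed seed makes repeated calls reproducible on a
    fixed environment.
    """
    if fps.n <= cfg.n_neighbors:
        raise ValidationError(
            f"embedding undefined: n ({fps.n}) must exceed n_neighbors ({cfg.n_neighbors})"
        )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        from umap import UMAP

        reducer = UMAP(
            n_neighbors=cfg.n_neighbors,
            min_dist=cfg.min_dist,
            n_components=cfg.n_components,
            metric=cfg.metric,
            random_state=cfg.seed,
        )
        embedding = reducer.fit_transform(fps.bits.astype(np.float32))
    return np.asarray(embedding, dtype=np.float64)


def agglomerative_on_embedding(
    embedding: np.ndarray, n_clusters: int, ids: Sequence[str] | None = None
) -> ClusterAssignment:
    """Ward agglomeration of embedding rows under Euclidean distance, cut to k clusters."""
    embedding = np.asarray(embedding, dtype=np.float64)
    n = embedding.shape[0]
    if n_clusters > n:
        raise ValidationError("n_clusters cannot exceed the number of points")
    from scipy.spatial.distance import pdist

    tree = ward_linkage(pdist(embedding))
    out = cut_tree_k(tree, n_clusters, ids=ids, method="umap_agglomerative")
    out.params["n_clusters"] = n_clusters
    return out
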