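"""Two-step hyperparameter tuning for the embedding + agglomerative route.

Step one fixes the cluster count and grid-searches the embedding
hyperparameters (n_neighbors, min_dist), scoring each combination with the
three clustering-quality indices on the embedding coordinates; the winner is
the combination that is best on the most indices (highest silhouette,
highest Calinski–Harabasz, lowest Davies–Bouldin), ties broken by smallest
n_neighbors then smallest min_dist.  Step two freezes those hyperparameters
and narrows the cluster count with the elbow method: one embedding is reused
across the whole k range, scored by distortion (sum of squared distances of
each observation to its assigned cluster centroid) or by the mean
silhouette.  Knee detection on distortion curves is a Kneedle-style
normalized-difference rule; silhouette curves return the argmax k.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .mol_io import FingerprintSet
from .clustering import UmapConfig, agglomerative_on_embedding, umap_embed, ward_linkage, cut_tree_k
from .quality import calinski_harabasz, davies_bouldin, silhouette_mean


@dataclass
class GridSearchRow:
    n_neighbors: int
    min_dist: float
    silhouette: float
    calinski_harabasz: float
    davies_bouldin: float
    failed: bool = False


@dataclass
class GridSearchResult:
    """Scored embedding-hyperparameter grid and the majority-of-metrics winner."""

    rows: list[GridSearchRow]
    winner: tuple[int, float]
    wins_per_combination: dict[tuple[int, float], int]


@dataclass
class ElbowCurve:
    """Cluster-count scan: scores over k_values under one scoring rule."""

    k_values: np.ndarray
    scores: np.ndarray
    scoring: str  # distortion | silhouette

    def __post_init__(self) -> None:
        self.k_values = np.asarray(self.k_values, dtype=np.int64)
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.k_values.size != self.scores.size:
            raise ValidationError("k_values and scores must have equal length")
        if self.k_values.size and np.any(np.diff(self.k_values) <= 0):
            raise ValidationError("k_values must be strictly increasing")
        if self.scoring not in ("distortion", "silhouette"):
            raise ValidationError(f"unknown scoring {self.scoring!r}")


def grid_search_umap(
    fps: FingerprintSet,
    neighbor_values: list[int],
    min_dist_values: list[float],
    fixed_k: int,
    seed: int = 42,
    base_config: UmapConfig | None = None,
    embedder=umap_embed,
) -> GridSearchResult:
    """Grid search over (n_neighbors, min_dist) at a fixed cluster count.

    Each cell embeds the fingerprints, clusters the embedding into
    ``fixed_k`` clusters and scores with all three indices on the embedding
    coordinates.  Cells where the embedding fails are flagged and excluded
    from the contest.  ``embedder`` is injectable for testing.
    """
    if not neighbor_values or not min_dist_values:
        raise ValidationError("neighbor and min_dist grids must be non-empty")
    if fixed_k < 2:
        raise ValidationError("fixed_k must be >= 2")
    base = base_config or UmapConfig()
    rows: list[GridSearchRow] = []
    for nn in neighbor_values:
        for md in min_dist_values:
            cfg = UmapConfig(
                n_neighbors=nn,
                min_dist=md,
                n_components=base.n_components,
                metric=base.metric,
                n_clusters=fixed_k,
                seed=seed,
            )
            try:
                emb = embedder(fps, cfg)
                labels = agglomerative_on_embedding(emb, fixed_k, ids=fps.ids).labels
                sil, _ = silhouette_mean(emb, labels)
                ch, _ = calinski_harabasz(emb, labels)
                db, _ = davies_bouldin(emb, labels)
                rows.append(GridSearchRow(nn, md, sil, ch, db))
            except Exception:
                rows.append(GridSearchRow(nn, md, math.nan, math.nan, math.nan, failed=True))

    ok = [r for r in rows if not r.failed]
    if not ok:
        raise ValidationError("every grid cell failed; no winner")
    wins: dict[tuple[int, float], int] = {(r.n_neighbors, r.min_dist): 0 for r in rows}
    for attr, best in (("silhouette", max), ("calinski_harabasz", max), ("davies_bouldin", min)):
        target = best(getattr(r, attr) for r in ok)
        for r in ok:
            if getattr(r, attr) == target:
                wins[(r.n_neighbors, r.min_dist)] += 1
    top = max(wins.values())
    winner = min(
        (cell for cell, w in wins.items() if w == top),
        key=lambda cell: (cell[0], cell[1]),
    )
    return GridSearchResult(rows=rows, winner=winner, wins_per_combination=wins)


def _distortion(x: np.ndarray, labels: np.ndarray) -> float:
    """Sum of squared distances of each observation to its cluster centroid."""
    total = 0.0
    for q in np.unique(labels):
        pts = x[labels == q]
        total += float(((pts - pts.mean(axis=0)) ** 2).sum())
    return total


def elbow_curve(
    points: np.ndarray,
    k_range: list[int] | range,
    scoring: str = "distortion",
    ids: list[str] | None = None,
) -> ElbowCurve:
    """Score agglomerative clusterings of ``points`` over a range of cluster counts.

    One Ward tree is built once and cut at every k (the clusterings are
    nested refinements, so distortion is non-increasing in k).  ``points``
    are the clustering feature space: an embedding matrix, or fingerprint
    rows cast to reals.
    """
    points = np.asarray(points, dtype=np.float64)
    n = points.shape[0]
    ks = sorted(set(int(k) for k in k_range))
    if not ks or ks[0] < 1 or ks[-1] > n - 1:
        raise ValidationError("k_range must lie within [1, n-1]")
    if scoring == "silhouette" and ks[0] < 2:
        raise ValidationError("silhouette scoring requires k >= 2")
    from scipy.spatial.distance import pdist

    tree = ward_linkage(pdist(points))
    scores = []
    for k in ks:
        labels = cut_tree_k(tree, k).labels
        if scoring == "distortion":
            scores.append(_distortion(points, labels))
        elif scoring == "silhouette":
            sil, _ = silhouette_mean(points, labels)
            scores.append(sil)
        else:
            raise ValidationError(f"unknown scoring {scoring!r}")
    curve = ElbowCurve(k_values=np.array(ks), scores=np.array(scores), scoring=scoring)
    if scoring == "distortion" and np.any(np.diff(curve.scores) > 1e-9):
        raise AssertionError("distortion increased with k on nested clusterings")
    return curve


def detect_knee(curve: ElbowCurve, sensitivity: float = 1.0) -> int | None:
    """The elbow of a score-versus-k curve, or None when no elbow exists.

    Distortion curves use a Kneedle-style rule: x and y are rescaled to
    [0, 1], the decreasing curve is flipped, and the knee is the k
    maximizing the difference between the rescaled curve and the diagonal.
    When that maximum falls below ``sensitivity`` times the mean x-spacing
    the curve is effectively straight and no elbow is declared.  Silhouette
    curves return the k with the highest score.
    """
    if curve.scoring == "silhouette":
        return int(curve.k_values[int(np.argmax(curve.scores))])
    if curve.k_values.size < 3:
        raise ValidationError("knee detection needs at least 3 points")
    x = curve.k_values.astype(np.float64)
    y = curve.scores
    if np.ptp(y) == 0:
        return None
    xn = (x - x.min()) / np.ptp(x)
    yn = (y - y.min()) / np.ptp(y)
    diff = (1.0 - yn) - xn  # flipped decreasing curve minus the diagonal
    threshold = sensitivity * np.mean(np.diff(xn))
    best = int(np.argmax(diff))
    if diff[best] < threshold:
        return None
    return int(curve.k_values[best])
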