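"""Clustering evaluation: silhouette, Calinski–Harabasz, Davies–Bouldin,
the average inter/intra-cluster Tanimoto similarity matrix, and cluster-size
summaries.

All three indices are implemented directly from their definitions (see
docs/methods.md for the formulas) rather than delegated, so their terms
(per-molecule a_i/b_i, dispersion traces, per-cluster scatters) are exposed
for inspection.  Degenerate situations are explicit: k = 1 is a validation
error, zero within-dispersion or coincident centroids yield +infinity
sentinels with a warning, and a singleton cluster contributes silhouette 0
by convention.

Metric feature space: for Ward/Butina clusterings of fingerprints the
indices are computed on the binary fingerprint matrix under Euclidean
geometry; for embedding-based clusterings, on the embedding coordinates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .mol_io import FingerprintSet
from .similarity import _block_similarity

logger = logging.getLogger(__name__)

SIZE_PERCENTILES = (10, 17, 20, 25, 50, 75)


@dataclass
class SilhouetteTerms:
    """Per-molecule silhouette ingredients: a_i, b_i and SC(i)."""

    a: np.ndarray
    b: np.ndarray
    sc: np.ndarray


@dataclass
class DispersionDecomposition:
    """Within/between dispersion traces of a clustering and the CH score."""

    k: int
    n: int
    tr_w: float
    tr_b: float
    ch: float


@dataclass
class DaviesBouldinTerms:
    """Per-cluster scatters s_i, centroid distances d_ij, ratios R_ij, and the score."""

    s: np.ndarray
    d_centroid: np.ndarray
    r: np.ndarray
    db: float


@dataclass
class QualityReport:
    """The three validity indices plus a cluster-size summary for one clustering."""

    silhouette: float
    calinski_harabasz: float
    davies_bouldin: float
    n_clusters: int
    size_summary: dict[str, float] = field(default_factory=dict)


def _validate_labels(labels: np.ndarray) -> tuple[np.ndarray, int]:
    labels = np.asarray(labels, dtype=np.int64)
    if labels.ndim != 1 or labels.size == 0:
        raise ValidationError("labels must be a non-empty 1-D array")
    uniq = np.unique(labels)
    if labels.min() < 0 or not np.array_equal(uniq, np.arange(uniq.size)):
        raise ValidationError("labels must cover 0..k-1 with no empty cluster")
    return labels, int(uniq.size)


def _distance_matrix(x: np.ndarray, precomputed: bool) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if precomputed:
        if x.ndim != 2 or x.shape[0] != x.shape[1]:
            raise ValidationError("precomputed distances must form a square matrix")
        return x
    from scipy.spatial.distance import pdist, squareform

    return squareform(pdist(x))


def silhouette_mean(
    x: np.ndarray, labels: np.ndarray, precomputed: bool = False
) -> tuple[float, SilhouetteTerms]:
    """Mean silhouette coefficient SC(i) = (b_i - a_i) / max(a_i, b_i).

    a_i is the mean distance of molecule i to the other members of its own
    cluster; b_i the smallest mean distance to the molecules of any other
    cluster.  Singleton-cluster molecules contribute SC = 0 (a_i is
    undefined for a one-member cluster).  ``x`` is a feature matrix (rows =
    molecules, Euclidean geometry) or, with ``precomputed=True``, a square
    distance matrix.
    """
    labels, k = _validate_labels(labels)
    if k < 2:
        raise ValidationError("silhouette requires at least 2 clusters")
    d = _distance_matrix(x, precomputed)
    n = d.shape[0]
    if n != labels.size:
        raise ValidationError("labels must match the number of molecules")

    sizes = np.bincount(labels, minlength=k).astype(np.float64)
    # mean distance of each molecule to every cluster: n x k
    sums = np.zeros((n, k))
    for q in range(k):
        sums[:, q] = d[:, labels == q].sum(axis=1)
    own = labels
    a = np.zeros(n)
    nontriv = sizes[own] > 1
    a[nontriv] = sums[np.arange(n), own][nontriv] / (sizes[own][nontriv] - 1)
    mean_other = sums / sizes[None, :]
    mean_other[np.arange(n), own] = np.inf
    b = mean_other.min(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        sc = np.where(np.maximum(a, b) > 0, (b - a) / np.maximum(a, b), 0.0)
    sc[~nontriv] = 0.0  # singleton convention
    return float(sc.mean()), SilhouetteTerms(a=a, b=b, sc=sc)


def calinski_harabasz(x: np.ndarray, labels: np.ndarray) -> tuple[float, DispersionDecomposition]:
    """Calinski–Harabasz score: (tr B_k / tr W_k) * (n - k) / (k - 1).

    W_k sums squared deviations of points from their cluster centers, B_k
    the size-weighted squared deviations of cluster centers from the grand
    center.  Zero within-dispersion yields a +infinity sentinel.
    """
    labels, k = _validate_labels(labels)
    x = np.asarray(x, dtype=np.float64)
    n = x.shape[0]
    if n != labels.size:
        raise ValidationError("labels must match the number of points")
    if k < 2:
        raise ValidationError("Calinski-Harabasz is undefined for k < 2 (k - 1 = 0)")
    if k >= n + 1:
        raise ValidationError("need k <= n")
    grand = x.mean(axis=0)
    tr_w = 0.0
    tr_b = 0.0
    for q in range(k):
        pts = x[labels == q]
        center = pts.mean(axis=0)
        tr_w += float(((pts - center) ** 2).sum())
        tr_b += pts.shape[0] * float(((center - grand) ** 2).sum())
    if tr_w == 0.0:
        logger.warning("zero within-cluster dispersion; Calinski-Harabasz reported as +inf")
        ch = math.inf
    else:
        ch = (tr_b / tr_w) * (n - k) / (k - 1)
    return ch, DispersionDecomposition(k=k, n=n, tr_w=tr_w, tr_b=tr_b, ch=ch)


def davies_bouldin(x: np.ndarray, labels: np.ndarray) -> tuple[float, DaviesBouldinTerms]:
    """Davies–Bouldin score: mean over clusters of max_{j!=i} (s_i + s_j) / d_ij.

    s_i is the mean distance of cluster i's members to its centroid; d_ij the
    distance between centroids.  Coincident centroids with positive scatter
    yield a +infinity sentinel; the minimum score is zero.
    """
    labels, k = _validate_labels(labels)
    x = np.asarray(x, dtype=np.float64)
    if x.shape[0] != labels.size:
        raise ValidationError("labels must match the number of points")
    if k < 2:
        raise ValidationError("Davies-Bouldin requires at least 2 clusters")
    centroids = np.vstack([x[labels == q].mean(axis=0) for q in range(k)])
    s = np.array(
        [np.linalg.norm(x[labels == q] - centroids[q], axis=1).mean() for q in range(k)]
    )
    diff = centroids[:, None, :] - centroids[None, :, :]
    d_centroid = np.sqrt((diff**2).sum(axis=2))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (s[:, None] + s[None, :]) / d_centroid
    np.fill_diagonal(r, -np.inf)
    coincident = (d_centroid == 0) & (s[:, None] + s[None, :] > 0)
    np.fill_diagonal(coincident, False)
    if coincident.any():
        logger.warning("coincident centroids with positive scatter; Davies-Bouldin is +inf")
        r[coincident] = math.inf
    else:
        r[np.isnan(r)] = 0.0  # d_ij = 0 with zero scatter
    db = float(np.max(r, axis=1).mean())
    return db, DaviesBouldinTerms(s=s, d_centroid=d_centroid, r=r, db=db)


@dataclass
class AverageSimilarityMatrix:
    """k x k mean Tanimoto similarities between (and within) clusters.

    Diagonal entry (i, i) averages over unordered distinct within-cluster
    pairs — similarity of a molecule with itself is never included — and is
    NaN for singleton clusters, whose within-cluster average is undefined.
    The matrix is symmetric; rendering it lower-triangular is display-only.
    """

    matrix: np.ndarray
    sizes: np.ndarray

    def diagonal_dominant(self) -> bool:
        """True when every defined diagonal entry exceeds all off-diagonal entries
        of its row — the signature of well-separated clusters."""
        k = self.matrix.shape[0]
        for i in range(k):
            if math.isnan(self.matrix[i, i]):
                continue
            off = np.delete(self.matrix[i], i)
            off = off[~np.isnan(off)]
            if off.size and self.matrix[i, i] <= off.max():
                return False
        return True


def average_similarity_matrix(fps: FingerprintSet, labels: np.ndarray) -> AverageSimilarityMatrix:
    """Mean Tanimoto similarity between molecules of cluster i and cluster j.

    Off-diagonal entries average over all cross pairs; the diagonal averages
    over distinct within-cluster pairs (NaN for singletons).
    """
    labels, k = _validate_labels(labels)
    if labels.size != fps.n:
        raise ValidationError("labels must match the fingerprint set")
    pop = fps.bits.sum(axis=1).astype(np.float64)
    sim = _block_similarity(fps.bits, fps.bits, pop, pop)
    out = np.full((k, k), np.nan)
    sizes = np.bincount(labels, minlength=k)
    members = [np.flatnonzero(labels == q) for q in range(k)]
    for i in range(k):
        for j in range(i, k):
            block = sim[np.ix_(members[i], members[j])]
            if i == j:
                if sizes[i] < 2:
                    continue  # singleton: within-cluster average undefined
                iu = np.triu_indices(sizes[i], k=1)
                out[i, i] = block[iu].mean()
            else:
                out[i, j] = out[j, i] = block.mean()
    return AverageSimilarityMatrix(matrix=out, sizes=sizes)


def cluster_size_summary(labels: np.ndarray) -> dict[str, float]:
    """Descriptive statistics of cluster sizes: mean, std, min, selected percentiles, max.

    Percentiles use linear interpolation between order statistics; std is the
    sample standard deviation (ddof=1, 0 for a single cluster)."""
    labels, k = _validate_labels(labels)
    sizes = np.bincount(labels, minlength=k).astype(np.float64)
    out = {
        "n_clusters": float(k),
        "mean": float(sizes.mean()),
        "std": float(sizes.std(ddof=1)) if k > 1 else 0.0,
        "min": float(sizes.min()),
    }
    for p in SIZE_PERCENTILES:
        out[f"p{p}"] = float(np.percentile(sizes, p))
    out["max"] = float(sizes.max())
    return out


def quality_report(
    fps_or_points: FingerprintSet | np.ndarray,
    labels: np.ndarray,
    metric_space: str = "fingerprints",
) -> QualityReport:
    """All three indices plus the size summary for one clustering.

    ``metric_space='fingerprints'`` scores on the binary fingerprint matrix
    under Euclidean geometry (the Ward/Butina route); pass an embedding
    matrix with ``metric_space='embedding'`` to score on embedding
    coordinates.
    """
    if metric_space == "fingerprints":
        if not isinstance(fps_or_points, FingerprintSet):
            raise ValidationError("metric_space='fingerprints' requires a FingerprintSet")
        x = fps_or_points.bits.astype(np.float64)
    elif metric_space == "embedding":
        x = np.asarray(fps_or_points, dtype=np.float64)
    else:
        raise ValidationError(f"unknown metric space {metric_space!r}")
    sil, _ = silhouette_mean(x, labels)
    ch, _ = calinski_harabasz(x, labels)
    db, _ = davies_bouldin(x, labels)
    labels_arr, k = _validate_labels(np.asarray(labels))
    return QualityReport(
        silhouette=sil,
        calinski_harabasz=ch,
        davies_bouldin=db,
        n_clusters=k,
        size_summary=cluster_size_summary(labels_arr),
    )
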