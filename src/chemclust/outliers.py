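"""Nearest-neighbor outlier definition, filter, and the cutoff-scan experiment.

A molecule is an outlier at similarity cutoff ``c`` when the Tanimoto
similarity to its most similar other molecule is <= c: it is different from
every molecule in the set at that level.  The filter is a single pass over
the nearest-neighbor profile computed on the FULL set; similarities are not
iteratively recomputed after removals.

The cutoff scan re-clusters the retained molecules at each cutoff with a
baseline Ward clustering and reports the three clustering-quality indices,
producing rows shaped like a cutoff-comparison table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .mol_io import FingerprintSet
from .similarity import NearestNeighborProfile, nearest_neighbor_profile, pairwise_distances


@dataclass
class OutlierReport:
    """Partition of the molecule set at one similarity cutoff."""

    cutoff: float
    outlier_ids: list[str]
    retained_ids: list[str]

    @property
    def n_removed(self) -> int:
        return len(self.outlier_ids)


@dataclass
class CutoffScanRow:
    """One row of the outlier-cutoff scan: filter size plus baseline clustering quality.

    Metric fields are NaN when the retained set was not clusterable
    (fewer than 2 molecules or fewer than 2 clusters)."""

    cutoff: float
    n_removed: int
    n_clusters: int
    silhouette: float
    calinski_harabasz: float
    davies_bouldin: float

    @property
    def clusterable(self) -> bool:
        return not math.isnan(self.silhouette)


def flag_outliers(profile: NearestNeighborProfile, cutoff: float) -> OutlierReport:
    """Partition molecules into outliers (nn_sim <= cutoff) and retained (> cutoff)."""
    if not 0.0 <= cutoff <= 1.0:
        raise ValidationError("cutoff must lie in [0, 1]")
    if len(profile.ids) == 0:
        raise ValidationError("profile is empty")
    is_out = profile.nn_sim <= cutoff
    return OutlierReport(
        cutoff=cutoff,
        outlier_ids=[m for m, o in zip(profile.ids, is_out) if o],
        retained_ids=[m for m, o in zip(profile.ids, is_out) if not o],
    )


def histogram_gap_cutoff(nn_sim: np.ndarray) -> float:
    """Similarity cutoff at the widest gap of the nearest-neighbor histogram.

    Picks the midpoint of the largest spacing between consecutive sorted
    nn_sim values — the natural threshold when outliers and cluster members
    form two separated similarity modes.
    """
    vals = np.sort(np.asarray(nn_sim, dtype=np.float64))
    if vals.size < 2:
        raise ValidationError("need at least 2 nearest-neighbor similarities")
    gaps = np.diff(vals)
    k = int(np.argmax(gaps))
    return float((vals[k] + vals[k + 1]) / 2.0)


def scan_outlier_cutoffs(
    fps: FingerprintSet,
    cutoffs: Sequence[float],
    ward_height_cutoff: float,
    metric_space: str = "fingerprints",
) -> list[CutoffScanRow]:
    """For each cutoff: filter, re-cluster the retained set with baseline Ward, score.

    ``ward_height_cutoff`` is the dendrogram height at which the baseline Ward
    tree is cut.  Cutoffs must be sorted ascending; rows where the retained
    set is not clusterable carry NaN metrics instead of fabricated numbers.
    """
    from .clustering import ward_linkage, cut_tree
    from .quality import quality_report

    cutoffs = list(cutoffs)
    if cutoffs != sorted(cutoffs):
        raise ValidationError("cutoffs must be sorted ascending")
    if not cutoffs:
        return []
    profile = nearest_neighbor_profile(fps)
    id_to_row = {m: i for i, m in enumerate(fps.ids)}
    rows: list[CutoffScanRow] = []
    for cutoff in cutoffs:
        report = flag_outliers(profile, cutoff)
        keep = [id_to_row[m] for m in report.retained_ids]
        if len(keep) < 2:
            rows.append(CutoffScanRow(cutoff, report.n_removed, len(keep),
                                      math.nan, math.nan, math.nan))
            continue
        sub = fps.subset(keep)
        tree = ward_linkage(pairwise_distances(sub))
        assignment = cut_tree(tree, ward_height_cutoff)
        k = int(assignment.labels.max()) + 1
        if k < 2:
            rows.append(CutoffScanRow(cutoff, report.n_removed, k, math.nan, math.nan, math.nan))
            continue
        rep = quality_report(sub, assignment.labels, metric_space=metric_space)
        rows.append(
            CutoffScanRow(
                cutoff=cutoff,
                n_removed=report.n_removed,
                n_clusters=k,
                silhouette=rep.silhouette,
                calinski_harabasz=rep.calinski_harabasz,
                davies_bouldin=rep.davies_bouldin,
            )
        )
    return rows
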