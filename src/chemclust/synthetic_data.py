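"""Synthetic fingerprint sets with planted clusters and injected outliers.

The generator emulates sparse 1024-bit binary fingerprints: each planted
cluster has a centroid whose bits are on independently with density ``p``,
and every member is the centroid perturbed by per-bit flip noise (an on-bit
is cleared with probability ``eps_off``, an off-bit is set with probability
``eps_on``).  Outliers are independent random fingerprints at a chosen bit
density, so their nearest-neighbor Tanimoto similarity sits far below that
of cluster members.  ``labels_true`` records the planted cluster of every
molecule; injected outliers carry the sentinel label -1.

The default ("nci60-like") noise preset was calibrated once by simulation
so that the pre-filter nearest-neighbor similarity median of a clean planted
set falls near 0.6, matching the similarity profile of a large screening
panel before outlier filtering; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .mol_io import FingerprintSet

#: Sentinel value of ``labels_true`` marking an injected outlier molecule.
OUTLIER_LABEL = -1

#: Sentinel for molecules without a planted label (input set had none).
UNLABELED = -2


@dataclass
class SyntheticSpec:
    """Parameters of a planted-cluster fingerprint set.

    Defaults are the "nci60-like" preset: 4 clusters of 100 molecules over
    1024 bits at centroid density 0.05, with bit-flip noise calibrated so
    the nearest-neighbor similarity median lands near 0.6, plus 20 random
    outliers at the same bit density.
    """

    n_clusters: int = 4
    members_per_cluster: int = 100
    n_bits: int = 1024
    density: float = 0.05
    eps_off: float = 0.19
    eps_on: float = 0.010
    n_outliers: int = 20
    outlier_density: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 1:
            raise ValidationError("n_clusters must be >= 1")
        if self.members_per_cluster < 1:
            raise ValidationError("members_per_cluster must be >= 1")
        if self.n_bits < 1:
            raise ValidationError("n_bits must be >= 1")
        if not 0.0 < self.density < 1.0:
            raise ValidationError("centroid density must lie in (0, 1)")
        if not (0.0 <= self.eps_off <= 1.0 and 0.0 <= self.eps_on <= 1.0):
            raise ValidationError("noise rates must lie in [0, 1]")
        if self.n_outliers < 0:
            raise ValidationError("n_outliers must be >= 0")
        if not 0.0 < self.outlier_density < 1.0:
            raise ValidationError("outlier density must lie in (0, 1)")


def perturb_centroid(centroid: np.ndarray, eps_off: float, eps_on: float,
                     rng: np.random.Generator) -> np.ndarray:
    """One member fingerprint: clear on-bits w.p. eps_off, set off-bits w.p. eps_on."""
    u = rng.random(centroid.shape)
    on = centroid.astype(bool)
    member = np.where(on, u >= eps_off, u < eps_on)
    return member.astype(np.uint8)


def generate_planted_fingerprints(spec: SyntheticSpec) -> FingerprintSet:
    """Planted-cluster fingerprint set (WITHOUT outliers; see inject_outliers).

    K independent centroids are drawn bit-wise Bernoulli(density); each of
    the ``members_per_cluster`` members perturbs its centroid with the
    (eps_off, eps_on) flip noise.  Deterministic given the seed.
    """
    rng = np.random.default_rng(spec.seed)
    ids: list[str] = []
    rows: list[np.ndarray] = []
    labels: list[int] = []
    for q in range(spec.n_clusters):
        centroid = (rng.random(spec.n_bits) < spec.density).astype(np.uint8)
        for m in range(spec.members_per_cluster):
            rows.append(perturb_centroid(centroid, spec.eps_off, spec.eps_on, rng))
            ids.append(f"c{q}_m{m}")
            labels.append(q)
    return FingerprintSet(
        ids=ids,
        bits=np.vstack(rows),
        radius=0,  # synthetic bits carry no chemistry radius
        labels_true=np.array(labels, dtype=np.int64),
    )


def inject_outliers(
    fps: FingerprintSet, n_outliers: int, outlier_density: float, seed: int
) -> FingerprintSet:
    """Append independent random fingerprints flagged with the outlier sentinel.

    Each outlier bit is on with probability ``outlier_density``.  Molecules
    of the input set keep their planted labels (or get the UNLABELED
    sentinel when the input carried none); outliers get OUTLIER_LABEL.
    """
    if n_outliers < 0:
        raise ValidationError("n_outliers must be >= 0")
    if n_outliers == 0:
        return fps
    rng = np.random.default_rng(seed)
    extra = (rng.random((n_outliers, fps.n_bits)) < outlier_density).astype(np.uint8)
    base_labels = (
        fps.labels_true
        if fps.labels_true is not None
        else np.full(fps.n, UNLABELED, dtype=np.int64)
    )
    return FingerprintSet(
        ids=list(fps.ids) + [f"out{i}" for i in range(n_outliers)],
        bits=np.vstack([fps.bits, extra]),
        radius=fps.radius,
        labels_true=np.concatenate([base_labels, np.full(n_outliers, OUTLIER_LABEL)]),
    )


def generate_with_outliers(spec: SyntheticSpec) -> FingerprintSet:
    """Planted clusters plus the spec's outliers in one call (seed-split internally)."""
    clean = generate_planted_fingerprints(spec)
    # derive a distinct stream for the outlier rows from the same spec seed
    return inject_outliers(clean, spec.n_outliers, spec.outlier_density, seed=spec.seed + 1_000_003)
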