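"""Pairwise Tanimoto similarity, condensed distance matrices, NN profiles.

Tanimoto similarity of two binary fingerprints is |a AND b| / |a OR b|
(1 - Jaccard distance).  Distances are stored condensed: the upper triangle
of the symmetric pairwise matrix flattened in lexicographic pair order,
length n(n-1)/2 — the same layout as ``scipy.spatial.distance.pdist``.

Both full pairwise computation and the nearest-neighbor profile work on
row blocks so the peak extra memory is O(block * n); the nearest-neighbor
profile never materializes the condensed matrix at all, since only the n
per-molecule maxima are retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError
from .mol_io import FingerprintSet

logger = logging.getLogger(__name__)

_DEFAULT_BLOCK = 512


def pair_count(n: int) -> int:
    """Number of unordered molecule pairs, n(n-1)/2."""
    if n < 0:
        raise ValidationError("n must be non-negative")
    return n * (n - 1) // 2


@dataclass
class CondensedDistanceMatrix:
    """Upper-triangle vector of pairwise Tanimoto distances (1 - similarity).

    ``values[k]`` holds the distance of pair (i, j), i < j, with pairs in
    lexicographic order; entries lie in [0, 1].
    """

    values: np.ndarray
    n: int
    ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        expected = pair_count(self.n)
        if self.values.shape != (expected,):
            raise ValidationError(
                f"condensed vector length {self.values.shape} does not match n={self.n} "
                f"(expected {expected})"
            )
        if len(self.ids) != self.n:
            raise ValidationError("ids length must equal n")
        if self.values.size and (self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12):
            raise ValidationError("distances must lie in [0, 1]")

    def square(self) -> np.ndarray:
        """Full symmetric n x n distance matrix (zero diagonal)."""
        from scipy.spatial.distance import squareform

        return squareform(self.values.astype(np.float64))


@dataclass
class NearestNeighborProfile:
    """Per-molecule similarity to its closest other molecule.

    ``nn_sim[i]`` is the maximum Tanimoto similarity of molecule i to any
    other molecule, and ``nn_id[i]`` names that neighbor (ties broken by
    lowest molecule index).
    """

    ids: list[str]
    nn_sim: np.ndarray
    nn_id: list[str]

    def __post_init__(self) -> None:
        self.nn_sim = np.asarray(self.nn_sim, dtype=np.float64)
        if not (len(self.ids) == len(self.nn_sim) == len(self.nn_id)):
            raise ValidationError("ids, nn_sim and nn_id must have equal lengths")
        if len(self.ids) < 2:
            raise ValidationError("nearest-neighbor profile requires n >= 2")
        if self.nn_sim.size and (self.nn_sim.min() < 0 or self.nn_sim.max() > 1):
            raise ValidationError("nn_sim entries must lie in [0, 1]")
        for own, other in zip(self.ids, self.nn_id):
            if own == other:
                raise ValidationError("a molecule cannot be its own nearest neighbor")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"id": self.ids, "nn_id": self.nn_id, "nn_sim": self.nn_sim})


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto similarity |a AND b| / |a OR b| of two equal-length bit vectors.

    The all-zero pair (empty union) is defined as 0.0: an empty fingerprint
    shares no substructure with anything, so it is maximally dissimilar.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("bit vectors must be 1-D and of equal length")
    inter = int(np.count_nonzero(np.logical_and(a, b)))
    union = int(np.count_nonzero(np.logical_or(a, b)))
    if union == 0:
        logger.debug("tanimoto of two all-zero fingerprints defined as 0.0")
        return 0.0
    return inter / union


def _block_similarity(block: np.ndarray, all_bits: np.ndarray, popcounts: np.ndarray,
                      block_pop: np.ndarray) -> np.ndarray:
    """Tanimoto similarity of every row in `block` against every row in `all_bits`."""
    inter = block.astype(np.float64) @ all_bits.T.astype(np.float64)
    union = block_pop[:, None] + popcounts[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / union, 0.0)
    return sim


def pairwise_distances(
    fps: FingerprintSet, block_size: int = _DEFAULT_BLOCK, dtype: np.dtype | type = np.float64
) -> CondensedDistanceMatrix:
    """Condensed matrix of Tanimoto distances (1 - similarity) for all pairs.

    Computed in row blocks of ``block_size`` so the peak additional memory is
    O(block_size * n); the condensed result is the only full-size allocation.
    ``dtype`` may be set to ``np.float32`` to halve storage on large sets.
    """
    n = fps.n
    if n < 2:
        raise ValidationError("pairwise distances require at least 2 molecules")
    bits = fps.bits
    popcounts = bits.sum(axis=1).astype(np.float64)
    out = np.empty(pair_count(n), dtype=dtype)
    for start in range(0, n - 1, block_size):
        stop = min(start + block_size, n - 1)
        sim = _block_similarity(bits[start:stop], bits, popcounts, popcounts[start:stop])
        for local, i in enumerate(range(start, stop)):
            # condensed offset of pair (i, i+1)
            off = pair_count(n) - pair_count(n - i)
            out[off : off + n - i - 1] = (1.0 - sim[local, i + 1 :]).astype(dtype)
    return CondensedDistanceMatrix(values=out, n=n, ids=list(fps.ids))


def nearest_neighbor_profile(fps: FingerprintSet, block_size: int = _DEFAULT_BLOCK) -> NearestNeighborProfile:
    """Similarity of each molecule to its closest other molecule.

    Streams row blocks against the full matrix without ever materializing the
    condensed distances; ties on the maximum similarity resolve to the lowest
    molecule index.
    """
    n = fps.n
    if n < 2:
        raise ValidationError("nearest-neighbor profile requires at least 2 molecules")
    bits = fps.bits
    popcounts = bits.sum(axis=1).astype(np.float64)
    nn_sim = np.full(n, -1.0)
    nn_idx = np.zeros(n, dtype=np.intp)
    for start in range(0, n, block_size):
        stop = min(start + block_size, n)
        sim = _block_similarity(bits[start:stop], bits, popcounts, popcounts[start:stop])
        rows = np.arange(start, stop)
        sim[np.arange(stop - start), rows] = -np.inf  # exclude self
        # np.argmax returns the first (lowest-index) maximum
        idx = np.argmax(sim, axis=1)
        nn_idx[start:stop] = idx
        nn_sim[start:stop] = sim[np.arange(stop - start), idx]
    nn_sim = np.clip(nn_sim, 0.0, 1.0)
    return NearestNeighborProfile(
        ids=list(fps.ids),
        nn_sim=nn_sim,
        nn_id=[fps.ids[j] for j in nn_idx],
    )


def write_condensed(d: CondensedDistanceMatrix, path: str | Path) -> None:
    """Persist a condensed matrix as a flat binary file + a text sidecar.

    The sidecar ``<path>.meta`` records n, the dtype and the molecule ids.
    """
    path = Path(path)
    d.values.tofile(path)
    with Path(str(path) + ".meta").open("w") as fh:
        fh.write(f"n={d.n}\ndtype={d.values.dtype.name}\n")
        for mol_id in d.ids:
            fh.write(mol_id + "\n")


def read_condensed(path: str | Path) -> CondensedDistanceMatrix:
    path = Path(path)
    meta_path = Path(str(path) + ".meta")
    if not meta_path.exists():
        raise FormatError(f"missing sidecar {meta_path}")
    lines = meta_path.read_text().splitlines()
    try:
        n = int(lines[0].split("=", 1)[1])
        dtype = np.dtype(lines[1].split("=", 1)[1])
    except (IndexError, ValueError, TypeError) as exc:
        raise FormatError(f"corrupted sidecar {meta_path}") from exc
    ids = lines[2 : 2 + n]
    values = np.fromfile(path, dtype=dtype)
    return CondensedDistanceMatrix(values=values, n=n, ids=ids)
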