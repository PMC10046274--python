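"""Molecule tables and Morgan fingerprints.

Reads molecule tables (CSV with ``id,smiles`` columns, or .smi files),
computes hashed circular (Morgan) fingerprints through RDKit, and persists
fingerprint sets as a plain TSV format: a header line carrying the bit width
and radius, then one row per molecule of ``id<TAB>hex-encoded bitstring``.
The TSV format is diff-able and independent of the chemistry toolkit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError, EnvironmentError_

logger = logging.getLogger(__name__)

_HEADER_PREFIX = "#chemclust-fingerprints"


@dataclass(frozen=True)
class MoleculeRecord:
    """A single molecule: an opaque identifier (e.g. an NSC number) plus SMILES."""

    id: str
    smiles: str


@dataclass
class FingerprintSet:
    """Ordered molecule identifiers plus an n x L binary fingerprint matrix.

    Parameters
    ----------
    ids
        Molecule identifiers, one per fingerprint row; must be unique.
    bits
        n x L matrix of 0/1 values (uint8).  L is the fingerprint length,
        1024 bits by default.
    radius
        Morgan radius used to generate the fingerprints (metadata only).
    labels_true
        Optional planted-cluster label per molecule; populated only by the
        synthetic-data generator (outliers carry a sentinel label of -1).
    """

    ids: list[str]
    bits: np.ndarray
    radius: int = 2
    labels_true: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.bits.ndim != 2:
            raise ValidationError("bits must be a 2-D matrix")
        if self.bits.shape[0] != len(self.ids):
            raise ValidationError(
                f"row count of bits ({self.bits.shape[0]}) must equal number of ids ({len(self.ids)})"
            )
        if self.bits.shape[1] <= 0:
            raise ValidationError("fingerprint length must be positive")
        if self.bits.size and not np.isin(self.bits, (0, 1)).all():
            raise ValidationError("every fingerprint entry must be 0 or 1")
        if len(set(self.ids)) != len(self.ids):
            raise ValidationError("molecule ids must be unique")
        if self.labels_true is not None:
            self.labels_true = np.asarray(self.labels_true, dtype=np.int64)
            if self.labels_true.shape != (len(self.ids),):
                raise ValidationError("labels_true must have one entry per molecule")

    @property
    def n(self) -> int:
        return self.bits.shape[0]

    @property
    def n_bits(self) -> int:
        return self.bits.shape[1]

    def subset(self, indices: Sequence[int]) -> "FingerprintSet":
        """A new set keeping only the given row positions, in the given order."""
        idx = np.asarray(indices, dtype=np.intp)
        return FingerprintSet(
            ids=[self.ids[i] for i in idx],
            bits=self.bits[idx],
            radius=self.radius,
            labels_true=None if self.labels_true is None else self.labels_true[idx],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FingerprintSet):
            return NotImplemented
        same_labels = (
            (self.labels_true is None and other.labels_true is None)
            or (
                self.labels_true is not None
                and other.labels_true is not None
                and np.array_equal(self.labels_true, other.labels_true)
            )
        )
        return (
            self.ids == other.ids
            and self.radius == other.radius
            and np.array_equal(self.bits, other.bits)
            and same_labels
        )


def read_molecule_table(path: str | Path, format: str | None = None) -> list[MoleculeRecord]:
    """Read a molecule table from CSV (columns ``id,smiles``) or .smi.

    .smi rows are whitespace-delimited ``SMILES [id]``; when the id column is
    absent a positional identifier ``mol<row>`` is assigned.  Records are
    returned in file order; duplicate identifiers and empty files are
    rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "smi" if path.suffix.lower() == ".smi" else "csv"
    if format not in ("csv", "smi"):
        raise ValidationError(f"unknown molecule table format: {format!r}")

    records: list[MoleculeRecord] = []
    if format == "csv":
        df = pd.read_csv(path, dtype=str)
        missing = {"id", "smiles"} - set(df.columns)
        if missing:
            raise FormatError(f"molecule CSV is missing columns: {sorted(missing)}")
        for row in df.itertuples(index=False):
            records.append(MoleculeRecord(id=str(row.id), smiles=str(row.smiles)))
    else:
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            smiles = parts[0]
            mol_id = parts[1] if len(parts) > 1 else f"mol{lineno}"
            records.append(MoleculeRecord(id=mol_id, smiles=smiles))

    if not records:
        raise ValidationError(f"no molecules found in {path}")
    seen: set[str] = set()
    for rec in records:
        if not rec.smiles or rec.smiles == "nan":
            raise ValidationError(f"empty SMILES for molecule {rec.id!r}")
        if rec.id in seen:
            raise ValidationError(f"duplicate molecule id: {rec.id!r}")
        seen.add(rec.id)
    return records


def compute_fingerprints(
    records: Sequence[MoleculeRecord], radius: int = 2, n_bits: int = 1024
) -> FingerprintSet:
    """Compute hashed circular-substructure (Morgan) fingerprints.

    Each parseable molecule contributes one binary row; unparseable SMILES
    are skipped with a logged warning (their count is reported via the log).
    Raises if no molecule parses at all.
    """
    if radius < 0:
        raise ValidationError("radius must be >= 0")
    if n_bits <= 0:
        raise ValidationError("n_bits must be positive")
    try:
        from rdkit import Chem
        from rdkit import RDLogger
        from rdkit.Chem import rdFingerprintGenerator
    except ImportError as exc:  # pragma: no cover - environment-dependent
        raise EnvironmentError_("RDKit is required to compute Morgan fingerprints") from exc

    RDLogger.DisableLog("rdApp.error")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    ids: list[str] = []
    rows: list[np.ndarray] = []
    n_skipped = 0
    for rec in records:
        mol = Chem.MolFromSmiles(rec.smiles)
        if mol is None:
            n_skipped += 1
            logger.warning("skipping unparseable SMILES for molecule %r", rec.id)
            continue
        fp = gen.GetFingerprint(mol)
        arr = np.zeros(n_bits, dtype=np.uint8)
        arr[list(fp.GetOnBits())] = 1
        ids.append(rec.id)
        rows.append(arr)
    if n_skipped:
        logger.warning("skipped %d of %d molecules with unparseable SMILES", n_skipped, len(records))
    if not rows:
        raise ValidationError("no molecule could be parsed; fingerprint set would be empty")
    return FingerprintSet(ids=ids, bits=np.vstack(rows), radius=radius)


def write_fingerprints(fps: FingerprintSet, path: str | Path) -> None:
    """Persist a fingerprint set as TSV: header line, then id + hex bitstring."""
    path = Path(path)
    n_bytes = (fps.n_bits + 7) // 8
    with path.open("w") as fh:
        fh.write(f"{_HEADER_PREFIX}\tn_bits={fps.n_bits}\tradius={fps.radius}\n")
        for i, mol_id in enumerate(fps.ids):
            packed = np.packbits(fps.bits[i])
            fh.write(f"{mol_id}\t{packed.tobytes()[:n_bytes].hex()}\n")


def read_fingerprints(path: str | Path) -> FingerprintSet:
    """Read a fingerprint TSV written by :func:`write_fingerprints`."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith(_HEADER_PREFIX):
            raise FormatError(f"{path} is not a chemclust fingerprint file (bad header)")
        meta = dict(item.split("=", 1) for item in header.split("\t")[1:])
        try:
            n_bits = int(meta["n_bits"])
            radius = int(meta["radius"])
        except (KeyError, ValueError) as exc:
            raise FormatError(f"corrupted fingerprint header in {path}") from exc
        n_hex = 2 * ((n_bits + 7) // 8)
        ids: list[str] = []
        rows: list[np.ndarray] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            try:
                mol_id, hexbits = line.split("\t")
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: expected two tab-separated fields") from exc
            if len(hexbits) != n_hex:
                raise FormatError(
                    f"{path}:{lineno}: bit width mismatch (got {len(hexbits)} hex chars, header implies {n_hex})"
                )
            unpacked = np.unpackbits(np.frombuffer(bytes.fromhex(hexbits), dtype=np.uint8))[:n_bits]
            ids.append(mol_id)
            rows.append(unpacked)
    bits = np.vstack(rows) if rows else np.zeros((0, n_bits), dtype=np.uint8)
    return FingerprintSet(ids=ids, bits=bits, radius=radius)
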