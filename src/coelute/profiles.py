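"""Elution-profile matrices for co-fractionation mass spectrometry.

An experiment separates a native extract into an ordered series of
chromatographic fractions; each protein's quantitation across those fractions
is its *elution profile*. Two quantitation kinds are supported: MS2 spectral
counts (non-negative integers) and MS1 precursor intensities (non-negative
reals). Protein identifiers are gene-level throughout.

Fraction coordinates are 0-based and contiguous; column order in files is
elution order. Missing cells in input files are an error, never implicit
zeros: "not detected" must be an explicit 0.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "QuantKind",
    "NormMode",
    "ProfileMatrix",
    "PsmCountRecord",
    "ProfileFormatError",
    "ProfileValidationError",
    "ContractError",
    "read_profile_matrix",
    "write_profile_matrix",
    "assemble_from_psm_table",
    "filter_ms1_by_ms2",
    "min_evidence_filter",
    "normalize_row",
]


class ProfileFormatError(ValueError):
    """Malformed profile file (ragged rows, duplicate ids, missing cells)."""


class ProfileValidationError(ValueError):
    """Values violate a matrix invariant (negative, non-integer MS2)."""


class ContractError(ValueError):
    """An operation was called outside its contract."""


class QuantKind(str, enum.Enum):
    MS2_COUNTS = "MS2_COUNTS"
    MS1_INTENSITY = "MS1_INTENSITY"


class NormMode(str, enum.Enum):
    UNIT_SUM = "UNIT_SUM"
    UNIT_L2 = "UNIT_L2"


@dataclass(frozen=True)
class ProfileMatrix:
    """One experiment's proteins × fractions quantitation table.

    ``values`` has shape ``(len(protein_ids), n_fractions)``; row order is
    the protein order. MS2 matrices hold whole numbers, MS1 matrices
    non-negative floats.
    """

    experiment_id: str
    species: str
    quant_kind: QuantKind
    protein_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2:
            raise ProfileValidationError("values must be a 2-D grid")
        if vals.shape[0] != len(self.protein_ids):
            raise ProfileValidationError(
                f"{vals.shape[0]} rows for {len(self.protein_ids)} protein ids"
            )
        if len(set(self.protein_ids)) != len(self.protein_ids):
            seen: set[str] = set()
            for pid in self.protein_ids:
                if pid in seen:
                    raise ProfileFormatError(f"duplicate protein id {pid!r}")
                seen.add(pid)
        if vals.size and not np.all(np.isfinite(vals)):
            raise ProfileValidationError("non-finite value in profile matrix")
        if vals.size and vals.min() < 0:
            raise ProfileValidationError("negative value in profile matrix")
        if self.quant_kind is QuantKind.MS2_COUNTS and vals.size:
            if not np.allclose(vals, np.round(vals)):
                raise ProfileValidationError("MS2 spectral counts must be whole numbers")
        vals.setflags(write=False)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "protein_ids", tuple(self.protein_ids))

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    @property
    def n_fractions(self) -> int:
        return self.values.shape[1]

    def row(self, protein_id: str) -> np.ndarray:
        return self.values[self.protein_ids.index(protein_id)]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ProfileMatrix):
            return NotImplemented
        return (
            self.experiment_id == other.experiment_id
            and self.species == other.species
            and self.quant_kind == other.quant_kind
            and self.protein_ids == other.protein_ids
            and self.values.shape == other.values.shape
            and np.array_equal(self.values, other.values)
        )


@dataclass(frozen=True)
class PsmCountRecord:
    """One (protein, fraction) spectral-count observation from upstream search."""

    protein_id: str
    fraction_index: int
    count: int

    def __post_init__(self) -> None:
        if self.fraction_index < 0:
            raise ProfileValidationError("fraction_index must be >= 0")
        if self.count < 0:
            raise ProfileValidationError("count must be >= 0")


def read_profile_matrix(
    path,
    quant_kind: QuantKind,
    experiment_id: str,
    species: str,
) -> ProfileMatrix:
    """Read a wide profile TSV: header row, first column protein id, then
    one column per fraction in elution order.

    Ragged rows and empty cells are format errors reported with their line
    number; values are validated against the matrix invariants.
    """
    quant_kind = QuantKind(quant_kind)
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    lines = [ln for ln in lines if ln != ""]
    if not lines:
        raise ProfileFormatError(f"{path}: empty file (header row required)")
    header = lines[0].split("\t")
    n_fractions = len(header) - 1
    if n_fractions < 1:
        raise ProfileFormatError(f"{path}: header must name at least one fraction")
    ids: list[str] = []
    seen: set[str] = set()
    rows: list[list[float]] = []
    for lineno, ln in enumerate(lines[1:], start=2):
        cells = ln.split("\t")
        if len(cells) != n_fractions + 1:
            raise ProfileFormatError(
                f"{path}: line {lineno}: expected {n_fractions + 1} columns, got {len(cells)}"
            )
        pid = cells[0]
        if not pid:
            raise ProfileFormatError(f"{path}: line {lineno}: empty protein id")
        if pid in seen:
            raise ProfileFormatError(f"{path}: duplicate protein id {pid!r} (line {lineno})")
        seen.add(pid)
        row: list[float] = []
        for col, cell in enumerate(cells[1:], start=2):
            if cell == "":
                raise ProfileFormatError(
                    f"{path}: line {lineno}: missing value in column {col} "
                    "(explicit 0 required for non-detection)"
                )
            try:
                row.append(float(cell))
            except ValueError as exc:
                raise ProfileFormatError(
                    f"{path}: line {lineno}: non-numeric value {cell!r}"
                ) from exc
        ids.append(pid)
        rows.append(row)
    values = np.asarray(rows, dtype=float) if rows else np.zeros((0, n_fractions))
    return ProfileMatrix(experiment_id, species, quant_kind, tuple(ids), values)


def write_profile_matrix(matrix: ProfileMatrix, path) -> None:
    """Write the wide TSV form read back by :func:`read_profile_matrix`.

    MS2 counts are written as integers; MS1 intensities with full float
    precision so that write → read round-trips exactly.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("protein\t" + "\t".join(f"f{i + 1}" for i in range(matrix.n_fractions)) + "\n")
        is_counts = matrix.quant_kind is QuantKind.MS2_COUNTS
        for pid, row in zip(matrix.protein_ids, matrix.values):
            if is_counts:
                cells = [str(int(round(v))) for v in row]
            else:
                cells = [repr(float(v)) for v in row]
            fh.write(pid + "\t" + "\t".join(cells) + "\n")


def assemble_from_psm_table(
    records: Iterable[PsmCountRecord],
    n_fractions: int,
    experiment_id: str,
    species: str,
) -> ProfileMatrix:
    """Aggregate long-form PSM counts into an MS2 profile matrix.

    Counts for identical (protein, fraction) pairs are summed; cells with no
    record are 0. Protein rows are sorted lexicographically so the result is
    independent of record order.
    """
    records = list(records)
    for rec in records:
        if rec.fraction_index >= n_fractions:
            raise IndexError(
                f"fraction_index {rec.fraction_index} out of range for "
                f"{n_fractions} fractions (protein {rec.protein_id!r})"
            )
    ids = sorted({rec.protein_id for rec in records})
    index = {pid: i for i, pid in enumerate(ids)}
    values = np.zeros((len(ids), n_fractions), dtype=float)
    for rec in records:
        values[index[rec.protein_id], rec.fraction_index] += rec.count
    return ProfileMatrix(experiment_id, species, QuantKind.MS2_COUNTS, tuple(ids), values)


def filter_ms1_by_ms2(ms1: ProfileMatrix, ms2: ProfileMatrix) -> ProfileMatrix:
    """Restrict MS1 quantitation to proteins identified by MS2 in the same sample.

    A protein counts as identified when its MS2 row has at least one nonzero
    spectral count — an all-zero MS2 row carries no identification evidence.
    MS1 row order is preserved.
    """
    if ms1.experiment_id != ms2.experiment_id:
        raise ContractError(
            f"experiment mismatch: MS1 {ms1.experiment_id!r} vs MS2 {ms2.experiment_id!r}"
        )
    identified = {
        pid for pid, row in zip(ms2.protein_ids, ms2.values) if np.any(row > 0)
    }
    keep = [i for i, pid in enumerate(ms1.protein_ids) if pid in identified]
    return replace(
        ms1,
        protein_ids=tuple(ms1.protein_ids[i] for i in keep),
        values=ms1.values[keep] if keep else np.zeros((0, ms1.n_fractions)),
    )


def min_evidence_filter(matrix: ProfileMatrix, min_nonzero_fractions: int = 0) -> ProfileMatrix:
    """Drop proteins detected in fewer than ``min_nonzero_fractions`` fractions.

    Default 0 keeps everything: pre-scoring filtering is an explicit choice,
    not a silent default. Each drop is logged.
    """
    if min_nonzero_fractions < 0:
        raise ContractError("min_nonzero_fractions must be >= 0")
    if min_nonzero_fractions == 0:
        return matrix
    nonzero = (matrix.values > 0).sum(axis=1)
    keep = [i for i in range(matrix.n_proteins) if nonzero[i] >= min_nonzero_fractions]
    dropped = matrix.n_proteins - len(keep)
    if dropped:
        logger.info(
            "min_evidence_filter(%s): dropped %d/%d proteins below %d nonzero fractions",
            matrix.experiment_id, dropped, matrix.n_proteins, min_nonzero_fractions,
        )
    return replace(
        matrix,
        protein_ids=tuple(matrix.protein_ids[i] for i in keep),
        values=matrix.values[keep] if keep else np.zeros((0, matrix.n_fractions)),
    )


def normalize_row(x: Sequence[float], mode: NormMode) -> tuple[np.ndarray, bool]:
    """Normalize a fraction vector to unit sum or unit L2 norm.

    Returns ``(vector, degenerate)``; an all-zero input is returned unchanged
    with ``degenerate=True``.
    """
    mode = NormMode(mode)
    vec = np.asarray(x, dtype=float)
    if vec.ndim != 1 or vec.size < 1:
        raise ContractError("normalize_row expects a 1-D vector with >= 1 entry")
    if vec.size and vec.min() < 0:
        raise ProfileValidationError("negative entry in fraction vector")
    if mode is NormMode.UNIT_SUM:
        denom = vec.sum()
    else:
        denom = float(np.linalg.norm(vec))
    if denom == 0:
        return vec.copy(), True
    return vec / denom, False
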