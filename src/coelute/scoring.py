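"""Pairwise co-elution scores.

Four correlation-type features are computed for each protein pair within one
fractionation experiment, following standard CF-MS practice:

1. **Pearson correlation with added Poisson noise** (MS2). Each of R
   replicates resamples every count as ``Poisson(count + p)`` with a small
   pseudocount ``p``; the score is the mean Pearson correlation over
   replicates. The pseudocount breaks the spurious perfect correlations that
   sparse spectral-count profiles otherwise produce.
2. **Weighted cross-correlation** (MS2). Pearson correlations of the two
   profiles at lags −K..K, combined with weights ``w_k = 1/(1+|k|)`` so that
   lag 0 dominates; tolerant of small elution shifts between co-complex
   members.
3. **Co-apex score** (MS2). ``1/(1 + |apex(x) − apex(y)|)`` where the apex is
   the earliest fraction attaining the profile maximum; 1.0 means the two
   proteins peak in the same fraction.
4. **Euclidean similarity** (MS1). One minus the scaled Euclidean distance
   between the unit-sum-normalized intensity profiles; scale-invariant so
   stoichiometry, not abundance, is compared.

Scores 1–3 come from MS2 spectral counts, score 4 from MS1 intensities
(missing when a protein lacks MS1 quantitation). Noise replication uses a
per-pair RNG substream derived from ``(seed, canonical pair id)``, with the
lexicographically smaller protein always consuming the first block of draws,
so the score is exactly symmetric in its arguments and bit-reproducible.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .profiles import ContractError, NormMode, ProfileMatrix, normalize_row

logger = logging.getLogger(__name__)

__all__ = [
    "ScoreParams",
    "PairScoreRecord",
    "pearson_plain",
    "pearson_poisson_noise",
    "weighted_cross_correlation",
    "co_apex",
    "euclidean_similarity",
    "score_experiment",
    "write_pair_scores",
    "read_pair_scores",
    "FEATURE_NAMES",
]

#: Feature columns of a pair-score record, in file order.
FEATURE_NAMES = ("pcc_noise", "wcc", "coapex", "euclid_sim")

_SQRT2 = float(np.sqrt(2.0))


@dataclass(frozen=True)
class ScoreParams:
    """Free parameters of the four co-elution scores.

    noise_reps
        Number of Poisson resampling replicates R (0 disables noise).
    noise_pseudocount
        Pseudocount p added to every count before resampling.
    max_lag
        Largest |lag| K of the weighted cross-correlation; must satisfy
        ``K < n_fractions - 2`` so every lag leaves >= 3 aligned fractions.
    rng_seed
        Seed of the deterministic noise stream.
    min_overlap
        Minimum number of fractions where both profiles are nonzero for a
        pair to be scored at all.
    """

    noise_reps: int = 100
    noise_pseudocount: float = 1.0
    max_lag: int = 2
    rng_seed: int = 0
    min_overlap: int = 1

    def __post_init__(self) -> None:
        if self.noise_reps < 0:
            raise ContractError("noise_reps must be >= 0")
        if self.noise_pseudocount < 0:
            raise ContractError("noise_pseudocount must be >= 0")
        if self.max_lag < 0:
            raise ContractError("max_lag must be >= 0")
        if self.min_overlap < 0:
            raise ContractError("min_overlap must be >= 0")


@dataclass(frozen=True)
class PairScoreRecord:
    """The four co-elution features for one protein pair in one experiment.

    ``protein_a < protein_b`` lexicographically; a feature is ``None`` when
    its inputs were unavailable (e.g. no MS1 quantitation for either
    protein). At least one feature is always observed.
    """

    protein_a: str
    protein_b: str
    experiment_id: str
    pcc_noise: Optional[float] = None
    wcc: Optional[float] = None
    coapex: Optional[float] = None
    euclid_sim: Optional[float] = None

    def __post_init__(self) -> None:
        if self.protein_a == self.protein_b:
            raise ContractError(f"self-pair {self.protein_a!r}")
        if self.protein_a > self.protein_b:
            raise ContractError(
                f"pair ({self.protein_a!r}, {self.protein_b!r}) not in canonical order"
            )
        if all(getattr(self, name) is None for name in FEATURE_NAMES):
            raise ContractError("record must carry at least one observed feature")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.protein_a, self.protein_b)

    def feature(self, name: str) -> Optional[float]:
        return getattr(self, name)


def pearson_plain(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson correlation with the zero-variance convention r = 0.0.

    A constant profile carries no co-elution information, and downstream
    learners need a total (non-NaN) value, so zero variance maps to 0.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape or xv.ndim != 1:
        raise ContractError("pearson_plain expects two equal-length 1-D vectors")
    if xv.size < 3:
        raise ContractError("pearson_plain needs length >= 3")
    xc = xv - xv.mean()
    yc = yv - yv.mean()
    den = float(np.sqrt((xc @ xc) * (yc @ yc)))
    if den == 0.0:
        return 0.0
    return float(np.clip((xc @ yc) / den, -1.0, 1.0))


def _pair_rng(seed: int, pair_key: str) -> np.random.Generator:
    # Substream keyed by (seed, canonical pair id): independent per pair yet
    # fully reproducible, and shared by both orderings of the pair.
    digest = hashlib.sha256(pair_key.encode("utf-8")).digest()
    sub = int.from_bytes(digest[:8], "little")
    return np.random.default_rng(np.random.SeedSequence(entropy=seed & 0x7FFFFFFF, spawn_key=(sub,)))


def _rowwise_pearson(x_reps: np.ndarray, y_reps: np.ndarray) -> np.ndarray:
    xc = x_reps - x_reps.mean(axis=1, keepdims=True)
    yc = y_reps - y_reps.mean(axis=1, keepdims=True)
    num = (xc * yc).sum(axis=1)
    den = np.sqrt((xc * xc).sum(axis=1) * (yc * yc).sum(axis=1))
    out = np.zeros(len(num))
    nz = den > 0
    out[nz] = num[nz] / den[nz]
    return np.clip(out, -1.0, 1.0)


def pearson_poisson_noise(
    x: Sequence[float],
    y: Sequence[float],
    params: ScoreParams,
    pair_key: str = "",
) -> float:
    """Mean Pearson correlation over Poisson-resampled replicates of two
    MS2 count profiles.

    Replicate r draws ``x_i ~ Poisson(x_i + p)`` independently (likewise y)
    and computes the plain Pearson correlation; the score is the mean over
    the R replicates. ``R = 0`` returns the noise-free correlation exactly.
    ``pair_key`` selects the per-pair noise substream; the first R×n block
    of draws always belongs to ``x``, so callers passing profiles in
    canonical pair order get an exactly symmetric score.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape or xv.ndim != 1:
        raise ContractError("pearson_poisson_noise expects two equal-length 1-D vectors")
    for name, v in (("x", xv), ("y", yv)):
        if v.size and (v.min() < 0 or not np.allclose(v, np.round(v))):
            raise ContractError(f"{name} must contain non-negative integer counts")
    if params.noise_reps == 0:
        return pearson_plain(xv, yv)
    rng = _pair_rng(params.rng_seed, pair_key)
    shape = (params.noise_reps, xv.size)
    x_reps = rng.poisson(xv + params.noise_pseudocount, size=shape)
    y_reps = rng.poisson(yv + params.noise_pseudocount, size=shape)
    return float(np.clip(_rowwise_pearson(x_reps, y_reps).mean(), -1.0, 1.0))


def weighted_cross_correlation(
    x: Sequence[float], y: Sequence[float], params: ScoreParams
) -> float:
    """Lag-weighted Pearson cross-correlation.

    ``WCC = sum_k w_k * rho_k / sum_k w_k`` over lags k = −K..K, where rho_k
    is the Pearson correlation of the length-(n−|k|) aligned overlap of x
    and y shifted by k, and ``w_k = 1/(1+|k|)``. K = 0 reduces exactly to the
    plain Pearson correlation.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape or xv.ndim != 1:
        raise ContractError("weighted_cross_correlation expects equal-length vectors")
    n = xv.size
    k_max = params.max_lag
    if n - k_max < 3:
        raise ContractError(f"max_lag {k_max} too large for {n} fractions (need n - K >= 3)")
    num = 0.0
    den = 0.0
    for k in range(-k_max, k_max + 1):
        if k >= 0:
            xs, ys = xv[k:], yv[: n - k]
        else:
            xs, ys = xv[: n + k], yv[-k:]
        w = 1.0 / (1.0 + abs(k))
        num += w * pearson_plain(xs, ys)
        den += w
    return float(np.clip(num / den, -1.0, 1.0))


def co_apex(x: Sequence[float], y: Sequence[float]) -> Optional[float]:
    """Closeness of the two profiles' peak fractions: ``1/(1 + |Δapex|)``.

    The apex is the smallest fraction index attaining the maximum (ties break
    to the earliest fraction). Returns ``None`` (missing) when either profile
    is all-zero and hence has no apex.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape or xv.ndim != 1:
        raise ContractError("co_apex expects two equal-length 1-D vectors")
    if not np.any(xv > 0) or not np.any(yv > 0):
        return None
    delta = abs(int(np.argmax(xv)) - int(np.argmax(yv)))
    return 1.0 / (1.0 + delta)


def euclidean_similarity(x: Sequence[float], y: Sequence[float]) -> Optional[float]:
    """Similarity of unit-sum-normalized MS1 profiles.

    With both profiles normalized to sum 1, the Euclidean distance between
    two non-negative vectors lies in [0, √2]; the score is ``1 − d/√2`` in
    [0, 1]. Returns ``None`` when either vector has zero sum. Multiplying a
    profile by any positive constant leaves the score unchanged.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape or xv.ndim != 1:
        raise ContractError("euclidean_similarity expects two equal-length 1-D vectors")
    xn, x_degenerate = normalize_row(xv, NormMode.UNIT_SUM)
    yn, y_degenerate = normalize_row(yv, NormMode.UNIT_SUM)
    if x_degenerate or y_degenerate:
        return None
    d = float(np.linalg.norm(xn - yn))
    return float(np.clip(1.0 - d / _SQRT2, 0.0, 1.0))


def score_experiment(
    ms2: ProfileMatrix,
    ms1: Optional[ProfileMatrix],
    params: ScoreParams,
) -> list[PairScoreRecord]:
    """Score every qualifying unordered protein pair of one experiment.

    A pair qualifies when its MS2 profiles are jointly nonzero in at least
    ``params.min_overlap`` fractions. MS2 yields ``pcc_noise``, ``wcc`` and
    ``coapex``; ``euclid_sim`` comes from MS1 and is missing when either
    protein lacks MS1 quantitation (``ms1`` should already be restricted to
    MS2-identified proteins; see ``profiles.filter_ms1_by_ms2``).
    """
    if ms1 is not None and ms1.experiment_id != ms2.experiment_id:
        raise ContractError("MS1 and MS2 matrices must come from the same experiment")
    ids = ms2.protein_ids
    values = ms2.values
    nonzero = values > 0
    # pairwise overlap counts in one matrix product
    overlap = nonzero.astype(np.int32) @ nonzero.astype(np.int32).T
    ms1_rows: dict[str, np.ndarray] = {}
    if ms1 is not None:
        for pid, row in zip(ms1.protein_ids, ms1.values):
            ms1_rows[pid] = row
    order = np.argsort(np.asarray(ids))
    records: list[PairScoreRecord] = []
    for ii in range(len(order)):
        i = order[ii]
        for jj in range(ii + 1, len(order)):
            j = order[jj]
            if overlap[i, j] < params.min_overlap:
                continue
            a, b = ids[i], ids[j]  # a < b by sort order
            xa, xb = values[i], values[j]
            pair_key = f"{a}|{b}"
            pcc = pearson_poisson_noise(xa, xb, params, pair_key=pair_key)
            wcc = weighted_cross_correlation(xa, xb, params)
            capex = co_apex(xa, xb)
            euclid = None
            if a in ms1_rows and b in ms1_rows:
                euclid = euclidean_similarity(ms1_rows[a], ms1_rows[b])
            records.append(
                PairScoreRecord(
                    protein_a=a,
                    protein_b=b,
                    experiment_id=ms2.experiment_id,
                    pcc_noise=pcc,
                    wcc=wcc,
                    coapex=capex,
                    euclid_sim=euclid,
                )
            )
    logger.info(
        "score_experiment(%s): %d proteins -> %d scored pairs",
        ms2.experiment_id, len(ids), len(records),
    )
    return records


def write_pair_scores(records: Iterable[PairScoreRecord], path) -> None:
    """Write the long pair-score TSV; missing features are written as ``NA``."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("protein_a\tprotein_b\texperiment_id\t" + "\t".join(FEATURE_NAMES) + "\n")
        for rec in records:
            feats = [
                "NA" if rec.feature(name) is None else repr(float(rec.feature(name)))
                for name in FEATURE_NAMES
            ]
            fh.write(f"{rec.protein_a}\t{rec.protein_b}\t{rec.experiment_id}\t" + "\t".join(feats) + "\n")


def read_pair_scores(path) -> list[PairScoreRecord]:
    """Read a pair-score TSV written by :func:`write_pair_scores`."""
    records: list[PairScoreRecord] = []
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["protein_a", "protein_b", "experiment_id", *FEATURE_NAMES]
        if header != expected:
            raise ContractError(f"{path}: unexpected pair-score header {header}")
        for ln in fh:
            ln = ln.rstrip("\n")
            if not ln:
                continue
            cells = ln.split("\t")
            feats = {
                name: (None if cell == "NA" else float(cell))
                for name, cell in zip(FEATURE_NAMES, cells[3:])
            }
            records.append(PairScoreRecord(cells[0], cells[1], cells[2], **feats))
    return records
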