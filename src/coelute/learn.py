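"""Supervised co-complex interaction prediction.

A gold standard of reference complexes induces pair labels: two proteins are
a *positive* pair when they co-occur in at least one complex, *negative*
when both appear in the gold standard but never together, and unlabeled
otherwise. Per-experiment co-elution features for each reference pair are
assembled into a wide feature table, a gradient-boosted tree classifier is
trained on the labeled rows, and every pair receives a co-complex
probability. "High confidence" is operationalized as the score threshold at
which held-out precision reaches a target (default 0.90).

Cross-validation is *complex-held-out*: folds partition complexes, not
pairs, and a labeled pair enters a fold only if every gold-standard complex
touching either of its proteins lies in that fold. Pairs straddling folds
are excluded from CV entirely. This prevents the leakage that pair-level
splits suffer, where the same complex contributes pairs to both train and
test.

Missing features (a pair not co-detected in an experiment) are informative
in CF-MS — "not co-detected" differs from "uncorrelated" — so each feature
column is paired with an observed-mask column and the sentinel fill is 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.metrics import average_precision_score

from .profiles import ContractError, ProfileFormatError
from .scoring import FEATURE_NAMES, PairScoreRecord

logger = logging.getLogger(__name__)

__all__ = [
    "GoldStandard",
    "load_gold_standard",
    "write_gold_standard",
    "derive_pair_labels",
    "FoldAssignment",
    "split_by_complex",
    "FeatureTable",
    "build_feature_table",
    "CoComplexModel",
    "train_classifier",
    "score_pairs",
    "ScoredNetwork",
    "write_network",
    "read_network",
    "PRCurve",
    "precision_recall_curve",
    "threshold_at_precision",
    "CVResult",
    "cross_validate",
    "DEFAULT_HYPERPARAMS",
]

POSITIVE = 1
NEGATIVE = 0

#: Default gradient-boosting hyperparameters. Shallow, slow-learning,
#: subsampled trees keep the predicted probabilities well away from
#: saturation on the small labeled sets typical of co-complex supervision;
#: an unregularized fit drives scores to ~1-1e-8, where a precision
#: threshold picked on held-out folds no longer transfers to the final model.
DEFAULT_HYPERPARAMS: dict = {
    "n_estimators": 300,
    "learning_rate": 0.05,
    "max_depth": 2,
    "min_samples_leaf": 10,
    "subsample": 0.8,
}


# ---------------------------------------------------------------------------
# Gold standard and labels
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GoldStandard:
    """Reference complexes (name, member set) in the reference namespace."""

    complexes: tuple[tuple[str, frozenset[str]], ...]

    def __post_init__(self) -> None:
        names = [name for name, _ in self.complexes]
        if len(set(names)) != len(names):
            raise ContractError("duplicate complex names in gold standard")
        for name, members in self.complexes:
            if len(members) < 2:
                raise ContractError(f"complex {name!r} has fewer than 2 members")
        object.__setattr__(
            self,
            "complexes",
            tuple((name, frozenset(members)) for name, members in self.complexes),
        )

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.complexes)

    def members(self, name: str) -> frozenset[str]:
        for cname, m in self.complexes:
            if cname == name:
                return m
        raise KeyError(name)

    def all_proteins(self) -> frozenset[str]:
        out: set[str] = set()
        for _, members in self.complexes:
            out |= members
        return frozenset(out)

    def positive_pairs(self) -> frozenset[tuple[str, str]]:
        """All within-complex pairs, canonically ordered."""
        pairs: set[tuple[str, str]] = set()
        for _, members in self.complexes:
            mem = sorted(members)
            for i in range(len(mem)):
                for j in range(i + 1, len(mem)):
                    pairs.add((mem[i], mem[j]))
        return frozenset(pairs)

    def complexes_touching(self, protein: str) -> tuple[str, ...]:
        return tuple(name for name, members in self.complexes if protein in members)


def load_gold_standard(path) -> GoldStandard:
    """Read ``name<TAB>member1,member2,...`` lines (one complex per line)."""
    complexes: list[tuple[str, frozenset[str]]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, ln in enumerate(fh, start=1):
            ln = ln.rstrip("\n")
            if not ln:
                continue
            cells = ln.split("\t")
            if len(cells) < 2 or not cells[0]:
                raise ProfileFormatError(
                    f"{path}: line {lineno}: expected 'name<TAB>member1,member2,...'"
                )
            members = frozenset(m for m in cells[1].split(",") if m)
            complexes.append((cells[0], members))
    return GoldStandard(tuple(complexes))


def write_gold_standard(gold: GoldStandard, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in gold.complexes:
            fh.write(f"{name}\t{','.join(sorted(members))}\n")


def derive_pair_labels(
    gold: GoldStandard, pairs: Iterable[tuple[str, str]]
) -> dict[tuple[str, str], Optional[int]]:
    """Label pairs against the gold standard.

    positive (1): both proteins share at least one complex; negative (0):
    both appear in the gold standard but never together; ``None``: at least
    one protein is absent from the gold standard.
    """
    positives = gold.positive_pairs()
    universe = gold.all_proteins()
    labels: dict[tuple[str, str], Optional[int]] = {}
    for a, b in pairs:
        key = (min(a, b), max(a, b))
        if key in positives:
            labels[(a, b)] = POSITIVE
        elif a in universe and b in universe:
            labels[(a, b)] = NEGATIVE
        else:
            labels[(a, b)] = None
    return labels


# ---------------------------------------------------------------------------
# Complex-held-out folds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldAssignment:
    """Fold index per complex, plus the pair-level membership rule."""

    fold_of: Mapping[str, int]
    k: int

    def pair_fold(self, gold: GoldStandard, pair: tuple[str, str]) -> Optional[int]:
        """Fold of a labeled pair, or ``None`` if it straddles folds.

        The pair's defining complexes are all complexes touching either
        protein; the pair belongs to a fold only when they all lie in it.
        """
        touching = set(gold.complexes_touching(pair[0])) | set(
            gold.complexes_touching(pair[1])
        )
        if not touching:
            return None
        folds = {self.fold_of[name] for name in touching}
        return folds.pop() if len(folds) == 1 else None


def split_by_complex(gold: GoldStandard, k: int, seed: int) -> FoldAssignment:
    """Partition complexes into k folds by seeded shuffle (round-robin deal)."""
    if k < 2:
        raise ContractError("need at least 2 folds")
    names = list(gold.names)
    if k > len(names):
        raise ContractError(f"{k} folds requested for {len(names)} complexes")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(len(names)))
    fold_of = {names[idx]: i % k for i, idx in enumerate(order)}
    return FoldAssignment(fold_of=fold_of, k=k)


# ---------------------------------------------------------------------------
# Feature table
# ---------------------------------------------------------------------------

@dataclass
class FeatureTable:
    """Wide per-pair feature table: one row per reference pair, one column
    per (experiment, co-elution score); NaN marks missing features.

    ``labels`` (optional) aligns with ``frame`` and holds 1/0 for
    positive/negative pairs, NaN for unlabeled rows.
    """

    frame: pd.DataFrame
    labels: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if self.frame.index.has_duplicates:
            raise ContractError("duplicate pair keys in feature table")
        if len(self.frame) and bool(self.frame.isna().all(axis=1).any()):
            raise ContractError("feature table row with no observed feature")
        if self.labels is not None and not self.labels.index.equals(self.frame.index):
            raise ContractError("labels index must match feature frame index")

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return list(self.frame.index)

    def with_labels(self, gold: GoldStandard) -> "FeatureTable":
        lab = derive_pair_labels(gold, self.pairs)
        series = pd.Series(
            [np.nan if lab[p] is None else float(lab[p]) for p in self.pairs],
            index=self.frame.index,
            dtype=float,
        )
        return FeatureTable(frame=self.frame, labels=series)


def build_feature_table(
    records: Iterable[PairScoreRecord],
    extra_features: Optional[pd.DataFrame] = None,
) -> FeatureTable:
    """Pivot long pair-score records into the wide per-pair feature table.

    Columns are named ``<experiment_id>::<feature>``. Experiments are kept
    as separate columns rather than averaged, letting the learner weight
    species and cell types differently. ``extra_features`` (optional,
    indexed by pair) appends external-evidence columns pass-through.
    """
    cells: dict[tuple[str, str], dict[str, float]] = {}
    for rec in records:
        row = cells.setdefault(rec.pair, {})
        for name in FEATURE_NAMES:
            value = rec.feature(name)
            if value is not None:
                row[f"{rec.experiment_id}::{name}"] = value
    index = sorted(cells)
    columns = sorted({col for row in cells.values() for col in row})
    frame = pd.DataFrame(
        [[cells[pair].get(col, np.nan) for col in columns] for pair in index],
        index=pd.MultiIndex.from_tuples(index, names=["protein_a", "protein_b"])
        if index
        else pd.MultiIndex.from_tuples([], names=["protein_a", "protein_b"]),
        columns=columns,
        dtype=float,
    )
    if extra_features is not None and len(extra_features.columns):
        frame = frame.join(extra_features, how="left")
    return FeatureTable(frame=frame)


def _design_matrix(frame: pd.DataFrame) -> np.ndarray:
    """Sentinel-fill + observed-mask encoding of a (possibly NaN) frame."""
    observed = frame.notna().to_numpy(dtype=float)
    filled = frame.fillna(0.0).to_numpy(dtype=float)
    return np.hstack([filled, observed])


# ---------------------------------------------------------------------------
# Classifier
# ---------------------------------------------------------------------------

@dataclass
class CoComplexModel:
    """A trained probabilistic co-complex scorer with its feature schema."""

    classifier: GradientBoostingClassifier
    feature_columns: tuple[str, ...]
    hyperparams: dict
    seed: int

    def predict_proba(self, frame: pd.DataFrame) -> np.ndarray:
        if tuple(frame.columns) != self.feature_columns:
            raise ContractError(
                "feature table schema does not match the model "
                f"(expected {len(self.feature_columns)} columns)"
            )
        if not len(frame):
            return np.zeros(0)
        proba = self.classifier.predict_proba(_design_matrix(frame))
        pos_col = int(np.where(self.classifier.classes_ == POSITIVE)[0][0])
        return proba[:, pos_col]

    def save(self, path) -> None:
        joblib.dump(
            {
                "classifier": self.classifier,
                "feature_columns": self.feature_columns,
                "hyperparams": self.hyperparams,
                "seed": self.seed,
            },
            path,
        )

    @classmethod
    def load(cls, path) -> "CoComplexModel":
        blob = joblib.load(path)
        return cls(
            classifier=blob["classifier"],
            feature_columns=tuple(blob["feature_columns"]),
            hyperparams=dict(blob["hyperparams"]),
            seed=int(blob["seed"]),
        )

    @property
    def model_id(self) -> str:
        return f"gbt-d{self.hyperparams.get('max_depth')}-n{self.hyperparams.get('n_estimators')}-s{self.seed}"


def train_classifier(
    table: FeatureTable,
    hyperparams: Optional[dict] = None,
    seed: int = 0,
) -> CoComplexModel:
    """Fit the gradient-boosted co-complex classifier on the labeled rows.

    Requires at least 10 positives and 10 negatives; training is
    deterministic given the seed.
    """
    if table.labels is None:
        raise ContractError("feature table carries no labels; call with_labels first")
    labeled = table.labels.dropna()
    n_pos = int((labeled == POSITIVE).sum())
    n_neg = int((labeled == NEGATIVE).sum())
    if n_pos == 0 or n_neg == 0:
        raise ContractError("degenerate single-class training input")
    if n_pos < 10 or n_neg < 10:
        raise ContractError(
            f"need >= 10 positives and >= 10 negatives (got {n_pos}/{n_neg})"
        )
    hp = dict(DEFAULT_HYPERPARAMS)
    if hyperparams:
        hp.update(hyperparams)
    frame = table.frame.loc[labeled.index]
    clf = GradientBoostingClassifier(random_state=seed, **hp)
    clf.fit(_design_matrix(frame), labeled.to_numpy(dtype=int))
    logger.info("train_classifier: %d positives, %d negatives, %d feature columns",
                n_pos, n_neg, len(table.frame.columns))
    return CoComplexModel(
        classifier=clf,
        feature_columns=tuple(table.frame.columns),
        hyperparams=hp,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Scored network
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScoredNetwork:
    """Classifier-scored pair list; scores in [0, 1], canonical pair order."""

    edges: tuple[tuple[str, str, float], ...]
    threshold: Optional[float] = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for a, b, s in self.edges:
            if a == b:
                raise ContractError(f"self-edge {a!r}")
            if a > b:
                raise ContractError(f"edge ({a!r}, {b!r}) not in canonical order")
            if not (0.0 <= s <= 1.0):
                raise ContractError(f"edge score {s} outside [0, 1]")
        object.__setattr__(self, "edges", tuple(self.edges))

    def apply_threshold(self, threshold: float) -> "ScoredNetwork":
        kept = tuple(e for e in self.edges if e[2] >= threshold)
        return ScoredNetwork(edges=kept, threshold=threshold, provenance=dict(self.provenance))

    def edge_dict(self) -> dict[tuple[str, str], float]:
        return {(a, b): s for a, b, s in self.edges}


def score_pairs(model: CoComplexModel, table: FeatureTable) -> ScoredNetwork:
    """Score every pair of the table with the trained model (no threshold)."""
    scores = model.predict_proba(table.frame)
    edges = tuple(
        (a, b, float(np.clip(s, 0.0, 1.0)))
        for (a, b), s in zip(table.frame.index, scores)
    )
    return ScoredNetwork(
        edges=edges,
        threshold=None,
        provenance={"model": model.model_id, "n_pairs": str(len(edges))},
    )


def write_network(network: ScoredNetwork, path, provenance_path=None) -> None:
    """Write the ``protein_a<TAB>protein_b<TAB>score`` TSV and an optional
    key-value provenance sidecar."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("protein_a\tprotein_b\tscore\n")
        for a, b, s in network.edges:
            fh.write(f"{a}\t{b}\t{s!r}\n")
    if provenance_path is not None:
        with open(provenance_path, "w", encoding="utf-8") as fh:
            for key in sorted(network.provenance):
                fh.write(f"{key}={network.provenance[key]}\n")
            if network.threshold is not None:
                fh.write(f"threshold={network.threshold!r}\n")


def read_network(path) -> ScoredNetwork:
    edges: list[tuple[str, str, float]] = []
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if header != "protein_a\tprotein_b\tscore":
            raise ContractError(f"{path}: unexpected network header {header!r}")
        for ln in fh:
            ln = ln.rstrip("\n")
            if not ln:
                continue
            a, b, s = ln.split("\t")
            edges.append((a, b, float(s)))
    return ScoredNetwork(edges=tuple(edges))


# ---------------------------------------------------------------------------
# Precision-recall thresholding
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PRCurve:
    """Cumulative precision/recall over labeled edges sorted by descending
    score, with tied scores grouped into a single curve point."""

    thresholds: tuple[float, ...]
    precision: tuple[float, ...]
    recall: tuple[float, ...]


def precision_recall_curve(
    network: ScoredNetwork, labels: Mapping[tuple[str, str], Optional[int]]
) -> PRCurve:
    """PR curve over the network's labeled edges.

    Edges are sorted by descending score; each distinct score value is one
    curve point whose precision/recall include all edges at or above it.
    """
    scored = [
        (s, labels[(a, b)])
        for a, b, s in network.edges
        if (a, b) in labels and labels[(a, b)] is not None
    ]
    n_pos = sum(1 for _, lab in scored if lab == POSITIVE)
    n_neg = len(scored) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ContractError("PR curve needs at least one positive and one negative labeled edge")
    scored.sort(key=lambda t: -t[0])
    thresholds: list[float] = []
    precision: list[float] = []
    recall: list[float] = []
    tp = 0
    seen = 0
    i = 0
    while i < len(scored):
        j = i
        while j < len(scored) and scored[j][0] == scored[i][0]:
            tp += scored[j][1] == POSITIVE
            seen += 1
            j += 1
        thresholds.append(scored[i][0])
        precision.append(tp / seen)
        recall.append(tp / n_pos)
        i = j
    return PRCurve(tuple(thresholds), tuple(precision), tuple(recall))


def threshold_at_precision(curve: PRCurve, target_precision: float) -> Optional[float]:
    """Lowest score whose cumulative precision meets the target.

    Returns ``None`` when no curve point attains the target — an explicit
    "no threshold" result rather than a silent clamp. Raising the target
    never lowers the returned threshold.
    """
    qualifying = [
        t for t, p in zip(curve.thresholds, curve.precision) if p >= target_precision
    ]
    return min(qualifying) if qualifying else None


def write_pr_curve(curve: PRCurve, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("threshold\tprecision\trecall\n")
        for t, p, r in zip(curve.thresholds, curve.precision, curve.recall):
            fh.write(f"{t!r}\t{p!r}\t{r!r}\n")


# ---------------------------------------------------------------------------
# Complex-held-out cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    """Pooled held-out scores/labels from complex-held-out CV."""

    scores: pd.Series
    labels: pd.Series
    auprc: float
    folds: FoldAssignment
    n_excluded: int


def cross_validate(
    table: FeatureTable,
    gold: GoldStandard,
    k: int = 5,
    seed: int = 0,
    hyperparams: Optional[dict] = None,
) -> CVResult:
    """Complex-held-out k-fold CV of the co-complex classifier.

    Complexes are dealt into k folds; a labeled pair participates only when
    all complexes touching its proteins share one fold. Each fold's pairs
    are scored by a model trained on the remaining folds; held-out scores
    are pooled and summarized as AUPRC (average precision).
    """
    if table.labels is None:
        table = table.with_labels(gold)
    folds = split_by_complex(gold, k, seed)
    labeled = table.labels.dropna()
    pair_folds: dict[tuple[str, str], Optional[int]] = {
        pair: folds.pair_fold(gold, pair) for pair in labeled.index
    }
    usable = [p for p, f in pair_folds.items() if f is not None]
    n_excluded = len(labeled) - len(usable)
    held_scores: dict[tuple[str, str], float] = {}
    for f in range(k):
        test_pairs = [p for p in usable if pair_folds[p] == f]
        train_pairs = [p for p in usable if pair_folds[p] != f]
        if not test_pairs:
            continue
        train_table = FeatureTable(
            frame=table.frame.loc[train_pairs],
            labels=table.labels.loc[train_pairs],
        )
        model = train_classifier(train_table, hyperparams=hyperparams, seed=seed)
        scores = model.predict_proba(table.frame.loc[test_pairs])
        for pair, s in zip(test_pairs, scores):
            held_scores[pair] = float(s)
    index = pd.MultiIndex.from_tuples(sorted(held_scores), names=["protein_a", "protein_b"])
    score_series = pd.Series([held_scores[p] for p in index], index=index, dtype=float)
    label_series = table.labels.loc[index].astype(int)
    auprc = float(average_precision_score(label_series.to_numpy(), score_series.to_numpy()))
    logger.info(
        "cross_validate: %d held-out pairs (%d excluded as fold-straddling), AUPRC %.3f",
        len(score_series), n_excluded, auprc,
    )
    return CVResult(
        scores=score_series,
        labels=label_series,
        auprc=auprc,
        folds=folds,
        n_excluded=n_excluded,
    )
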