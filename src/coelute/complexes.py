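"""Clustering the thresholded co-complex network into putative complexes.

The clusterer grows overlapping, cohesive node sets in the spirit of
ClusterONE: the *cohesiveness* of a node set S is

    C(S) = W_in(S) / (W_in(S) + W_bound(S) + penalty * |S|)

where W_in is the total weight of edges inside S, W_bound the total weight
of edges crossing the boundary of S, and the penalty term models unobserved
interactions of each member. Growth is greedy: seed with the highest-weight
not-yet-covered edge, then repeatedly apply the single-node addition or
removal that most increases C(S) until a local optimum; accept the set when
it meets the cohesiveness and size floors; finally merge accepted sets that
overlap heavily (Jaccard above a merge threshold). All tie-breaks are
explicit (higher weight first, then lexicographic node id), so two runs on
the same network and parameters are identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional

from .learn import GoldStandard, ScoredNetwork
from .profiles import ContractError

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterParams",
    "PredictedComplex",
    "ComplexSet",
    "cohesiveness",
    "cluster_network",
    "compare_complexes",
    "write_complexes",
    "read_complexes",
]


@dataclass(frozen=True)
class ClusterParams:
    """Knobs of the cohesiveness-growth clusterer.

    min_size
        Smallest reported complex (default 3; dimers are rarely resolvable
        from co-fractionation alone).
    cohesiveness_min
        Acceptance floor for C(S).
    overlap_merge_jaccard
        Accepted sets with member Jaccard at or above this merge.
    penalty
        Per-member penalty term of C(S) modelling unobserved edges.
    """

    min_size: int = 3
    cohesiveness_min: float = 0.3
    overlap_merge_jaccard: float = 0.8
    penalty: float = 2.0

    def __post_init__(self) -> None:
        if self.min_size < 2:
            raise ContractError("min_size must be >= 2")
        if not (0.0 <= self.cohesiveness_min <= 1.0):
            raise ContractError("cohesiveness_min must lie in [0, 1]")
        if not (0.0 < self.overlap_merge_jaccard <= 1.0):
            raise ContractError("overlap_merge_jaccard must lie in (0, 1]")
        if self.penalty < 0:
            raise ContractError("penalty must be >= 0")


@dataclass(frozen=True)
class PredictedComplex:
    complex_id: str
    members: frozenset[str]
    cohesiveness: float


@dataclass(frozen=True)
class ComplexSet:
    """Possibly overlapping predicted complexes with their cohesiveness."""

    complexes: tuple[PredictedComplex, ...]

    def __iter__(self):
        return iter(self.complexes)

    def __len__(self) -> int:
        return len(self.complexes)

    def member_sets(self) -> list[frozenset[str]]:
        return [c.members for c in self.complexes]


def _adjacency(network: ScoredNetwork) -> dict[str, dict[str, float]]:
    adj: dict[str, dict[str, float]] = {}
    for a, b, w in network.edges:
        adj.setdefault(a, {})[b] = w
        adj.setdefault(b, {})[a] = w
    return adj


def cohesiveness(
    members: frozenset[str] | set[str],
    adj: Mapping[str, Mapping[str, float]],
    penalty: float,
) -> float:
    """C(S) = W_in / (W_in + W_bound + penalty * |S|); 0 for an empty set."""
    if not members:
        return 0.0
    w_in = 0.0
    w_bound = 0.0
    for u in members:
        for v, w in adj.get(u, {}).items():
            if v in members:
                w_in += w / 2.0  # each internal edge visited from both ends
            else:
                w_bound += w
    denom = w_in + w_bound + penalty * len(members)
    return w_in / denom if denom > 0 else 0.0


def _grow_from_seed(
    seed_edge: tuple[str, str],
    adj: Mapping[str, Mapping[str, float]],
    penalty: float,
) -> frozenset[str]:
    """Greedy single-node growth/shrink to a local cohesiveness optimum."""
    members: set[str] = set(seed_edge)
    current = cohesiveness(members, adj, penalty)
    while True:
        best_gain = 1e-12
        best_move: Optional[tuple[str, str]] = None  # ("add"/"remove", node)
        boundary = sorted(
            {v for u in members for v in adj.get(u, {}) if v not in members}
        )
        for v in boundary:
            c = cohesiveness(members | {v}, adj, penalty)
            if c - current > best_gain:
                best_gain = c - current
                best_move = ("add", v)
        if len(members) > 2:
            for v in sorted(members):
                if v in seed_edge:
                    continue  # the seed edge anchors the cluster
                c = cohesiveness(members - {v}, adj, penalty)
                if c - current > best_gain:
                    best_gain = c - current
                    best_move = ("remove", v)
        if best_move is None:
            return frozenset(members)
        op, node = best_move
        if op == "add":
            members.add(node)
        else:
            members.discard(node)
        current = cohesiveness(members, adj, penalty)


def _jaccard(a: frozenset[str], b: frozenset[str]) -> float:
    union = len(a | b)
    return len(a & b) / union if union else 0.0


def cluster_network(
    network: ScoredNetwork, params: Optional[ClusterParams] = None
) -> ComplexSet:
    """Greedy seeded cohesiveness growth over a thresholded network.

    Seeds are taken from edges in descending weight order (ties broken by
    node ids); an edge already inside an accepted complex is not reused as a
    seed. Grown sets are kept when they meet the cohesiveness and size
    floors; heavily overlapping accepted sets (Jaccard >=
    ``overlap_merge_jaccard``) are merged, and merged sets are re-audited
    against both floors. An empty network yields an empty set.
    """
    params = params or ClusterParams()
    adj = _adjacency(network)
    edges = sorted(network.edges, key=lambda e: (-e[2], e[0], e[1]))
    accepted: list[frozenset[str]] = []
    covered: set[str] = set()
    for a, b, _w in edges:
        # an edge whose endpoints are both inside accepted complexes is
        # "used": seeding from it would only regrow covered territory
        if a in covered and b in covered:
            continue
        grown = _grow_from_seed((a, b), adj, params.penalty)
        score = cohesiveness(grown, adj, params.penalty)
        if len(grown) >= params.min_size and score >= params.cohesiveness_min:
            accepted.append(grown)
            covered |= grown
    # merge heavily overlapping sets to a fixpoint
    merged = True
    while merged:
        merged = False
        out: list[frozenset[str]] = []
        for s in accepted:
            hit = None
            for i, t in enumerate(out):
                if _jaccard(s, t) >= params.overlap_merge_jaccard:
                    hit = i
                    break
            if hit is None:
                out.append(s)
            else:
                out[hit] = out[hit] | s
                merged = True
        accepted = out
    final: list[PredictedComplex] = []
    for members in accepted:
        score = cohesiveness(members, adj, params.penalty)
        if len(members) >= params.min_size and score >= params.cohesiveness_min:
            final.append(PredictedComplex("", members, score))
    final.sort(key=lambda c: (-c.cohesiveness, sorted(c.members)))
    final = [
        PredictedComplex(f"M{i + 1:04d}", c.members, c.cohesiveness)
        for i, c in enumerate(final)
    ]
    logger.info("cluster_network: %d edges -> %d complexes", len(network.edges), len(final))
    return ComplexSet(tuple(final))


@dataclass(frozen=True)
class ComplexRecovery:
    precision: float
    recall: float
    f1: float
    matched_pairs: tuple[tuple[str, str], ...]  # (predicted id, reference name)


def compare_complexes(
    predicted: ComplexSet,
    reference: GoldStandard,
    jaccard_match: float = 0.25,
) -> ComplexRecovery:
    """Complex-level recovery against a reference set.

    A predicted/reference pair matches when the Jaccard index of their
    member sets is at least ``jaccard_match``. Precision is the fraction of
    predicted complexes with a match, recall the fraction of reference
    complexes with a match, F1 their harmonic mean.
    """
    matches: list[tuple[str, str]] = []
    matched_pred: set[str] = set()
    matched_ref: set[str] = set()
    for pred in predicted:
        for name, members in reference.complexes:
            if _jaccard(pred.members, members) >= jaccard_match:
                matches.append((pred.complex_id, name))
                matched_pred.add(pred.complex_id)
                matched_ref.add(name)
    precision = len(matched_pred) / len(predicted) if len(predicted) else 0.0
    recall = len(matched_ref) / len(reference.complexes) if reference.complexes else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return ComplexRecovery(
        precision=precision, recall=recall, f1=f1, matched_pairs=tuple(matches)
    )


def write_complexes(complexes: ComplexSet, path) -> None:
    """Gold-standard file format plus a trailing cohesiveness column."""
    with open(path, "w", encoding="utf-8") as fh:
        for c in complexes:
            fh.write(f"{c.complex_id}\t{','.join(sorted(c.members))}\t{c.cohesiveness!r}\n")


def read_complexes(path) -> ComplexSet:
    out: list[PredictedComplex] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, ln in enumerate(fh, start=1):
            ln = ln.rstrip("\n")
            if not ln:
                continue
            cells = ln.split("\t")
            if len(cells) != 3:
                raise ContractError(f"{path}: line {lineno}: expected 3 columns")
            out.append(
                PredictedComplex(
                    cells[0], frozenset(cells[1].split(",")), float(cells[2])
                )
            )
    return ComplexSet(tuple(out))
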