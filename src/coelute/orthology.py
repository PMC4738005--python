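"""Cross-species harmonization of co-elution evidence.

Experiments run in different species are merged in a single reference
(human) gene namespace: each species carries an ortholog map, a possibly
many-to-many relation from its genes to reference genes. Pair scores are
mapped *into* the reference namespace before learning; the final scored
network is projected *out of* it to paint the predicted co-complex map onto
other species.

Many-to-many orthology is handled by full expansion: a source pair expands
to every combination of reference co-orthologs, and when several source
pairs collide on one reference pair the maximum observed value of each
feature is kept — the strongest co-elution evidence wins. Genes without an
ortholog are dropped, keeping the reference table purely orthologous.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Optional

from .profiles import ProfileFormatError
from .scoring import FEATURE_NAMES, PairScoreRecord

logger = logging.getLogger(__name__)

__all__ = [
    "OrthologMap",
    "load_ortholog_map",
    "write_ortholog_map",
    "map_scores_to_reference",
    "project_network",
]


@dataclass(frozen=True)
class OrthologMap:
    """A many-to-many (source gene → reference gene) relation for one species."""

    species: str
    entries: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        for src, ref in self.entries:
            if not src or not ref:
                raise ValueError("ortholog map genes must be non-empty strings")
        object.__setattr__(self, "entries", frozenset(self.entries))

    def to_reference(self, source_gene: str) -> frozenset[str]:
        return frozenset(ref for src, ref in self.entries if src == source_gene)

    def to_source(self, reference_gene: str) -> frozenset[str]:
        return frozenset(src for src, ref in self.entries if ref == reference_gene)

    def forward_index(self) -> dict[str, set[str]]:
        idx: dict[str, set[str]] = {}
        for src, ref in self.entries:
            idx.setdefault(src, set()).add(ref)
        return idx

    def inverse_index(self) -> dict[str, set[str]]:
        idx: dict[str, set[str]] = {}
        for src, ref in self.entries:
            idx.setdefault(ref, set()).add(src)
        return idx


def load_ortholog_map(path, species: str) -> OrthologMap:
    """Read a two-column ``source_gene<TAB>reference_gene`` TSV.

    Exact duplicate lines collapse (set semantics); an empty field is a
    format error reported with its line number.
    """
    entries: set[tuple[str, str]] = set()
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, ln in enumerate(fh, start=1):
            ln = ln.rstrip("\n")
            if not ln:
                continue
            cells = ln.split("\t")
            if len(cells) != 2 or not cells[0] or not cells[1]:
                raise ProfileFormatError(
                    f"{path}: line {lineno}: expected two non-empty tab-separated genes"
                )
            entries.add((cells[0], cells[1]))
    return OrthologMap(species=species, entries=frozenset(entries))


def write_ortholog_map(omap: OrthologMap, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for src, ref in sorted(omap.entries):
            fh.write(f"{src}\t{ref}\n")


def _merge_features(
    records: list[PairScoreRecord], a: str, b: str, experiment_id: str
) -> PairScoreRecord:
    feats: dict[str, Optional[float]] = {}
    for name in FEATURE_NAMES:
        observed = [r.feature(name) for r in records if r.feature(name) is not None]
        feats[name] = max(observed) if observed else None
    return PairScoreRecord(protein_a=a, protein_b=b, experiment_id=experiment_id, **feats)


def map_scores_to_reference(
    records: Iterable[PairScoreRecord], omap: OrthologMap
) -> list[PairScoreRecord]:
    """Translate source-species pair scores into the reference namespace.

    Each record (a, b) expands to every (H(a), H(b)) combination under the
    map; pairs with an unmapped side are dropped, as are expansions that
    collapse to a self-pair. When multiple source records land on the same
    reference pair within an experiment, each feature takes the maximum over
    the non-missing source values. Output is canonically ordered and sorted.
    """
    forward = omap.forward_index()
    collided: dict[tuple[str, str, str], list[PairScoreRecord]] = {}
    n_in = 0
    for rec in records:
        n_in += 1
        refs_a = forward.get(rec.protein_a, set())
        refs_b = forward.get(rec.protein_b, set())
        if not refs_a or not refs_b:
            continue
        for ra, rb in itertools.product(refs_a, refs_b):
            if ra == rb:
                continue
            key = (min(ra, rb), max(ra, rb), rec.experiment_id)
            collided.setdefault(key, []).append(rec)
    out = [
        _merge_features(recs, a, b, exp)
        for (a, b, exp), recs in sorted(collided.items())
    ]
    logger.info(
        "map_scores_to_reference(%s): %d source records -> %d reference records",
        omap.species, n_in, len(out),
    )
    return out


def project_network(network, omap: OrthologMap):
    """Project a reference-namespace scored network onto one species.

    Runs the ortholog map in reverse: an edge (u, v, score) yields every
    (s(u), s(v), score) with both endpoints mapped; self-pairs are dropped
    and duplicate projected edges keep the maximum score. Projecting through
    a bijective map and back is the identity.
    """
    from .learn import ScoredNetwork  # local import: learn depends on scoring only

    inverse = omap.inverse_index()
    best: dict[tuple[str, str], float] = {}
    for u, v, score in network.edges:
        sources_u = inverse.get(u, set())
        sources_v = inverse.get(v, set())
        for su, sv in itertools.product(sources_u, sources_v):
            if su == sv:
                continue
            key = (min(su, sv), max(su, sv))
            if key not in best or score > best[key]:
                best[key] = score
    edges = tuple((a, b, s) for (a, b), s in sorted(best.items()))
    provenance = dict(network.provenance)
    provenance["projected_to"] = omap.species
    return ScoredNetwork(edges=edges, threshold=network.threshold, provenance=provenance)
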