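"""Target-protein proximity on a scored protein-protein interaction graph.

A STRING-style edge table (protein1, protein2, combined_score) is loaded
with a confidence cutoff (default: drop scores below 700, the usual
"high confidence" threshold).  The distance between two drugs' target
sets is the minimum unweighted shortest-path length over all cross
pairs — 0 when the sets share a protein, ``UNREACHABLE`` when no cross
pair is connected.  The module compares hub drugs' proximity to their
combination partners against therapeutically similar non-partners, and
tallies target cellular localizations.
"""

from __future__ import annotations

import logging
import math
import statistics
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx

from .atc import DrugRecord
from .network import TsCache

__all__ = [
    "UNREACHABLE",
    "load_ppi",
    "target_set_distance",
    "proximity_comparison",
    "localization_tally",
]

logger = logging.getLogger(__name__)

#: Sentinel distance for target sets with no connecting path.
UNREACHABLE: float = math.inf


def load_ppi(rows: Iterable[tuple[str, str, int]], min_score: int = 700) -> nx.Graph:
    """Build a PPI graph from (protein1, protein2, score) rows.

    Edges scoring below ``min_score`` are dropped (threshold inclusive:
    a score equal to ``min_score`` is kept).  Duplicate pairs collapse to
    one edge keeping the maximum score; self-interactions are ignored.
    """
    ppi = nx.Graph()
    n_rows = n_dropped = 0
    for p1, p2, score in rows:
        n_rows += 1
        if p1 == p2:
            continue
        if score < min_score:
            n_dropped += 1
            continue
        if ppi.has_edge(p1, p2):
            ppi[p1][p2]["score"] = max(ppi[p1][p2]["score"], score)
        else:
            ppi.add_edge(p1, p2, score=score)
    if n_rows == 0:
        logger.warning("PPI table is empty")
    logger.info(
        "PPI: kept %d edges over %d proteins (%d below score %d dropped)",
        ppi.number_of_edges(), ppi.number_of_nodes(), n_dropped, min_score,
    )
    return ppi


def target_set_distance(
    ppi: nx.Graph, targets_a: Iterable[str], targets_b: Iterable[str]
) -> float:
    """Minimum shortest-path length between two protein sets.

    Proteins absent from the PPI graph are ignored with a warning; 0 if
    the filtered sets intersect; ``UNREACHABLE`` if no cross pair is
    connected.  Raises if either set is empty after filtering.
    """
    a = {p for p in targets_a if p in ppi}
    b = {p for p in targets_b if p in ppi}
    missing = (set(targets_a) - a) | (set(targets_b) - b)
    if missing:
        logger.warning("%d target proteins absent from PPI graph", len(missing))
    if not a or not b:
        raise ValueError("a target set is empty after filtering against the PPI graph")
    if a & b:
        return 0.0
    best = UNREACHABLE
    # multi-source BFS from the smaller set
    src, dst = (a, b) if len(a) <= len(b) else (b, a)
    dist = nx.multi_source_dijkstra_path_length(ppi, src, weight=None)
    for p in dst:
        d = dist.get(p)
        if d is not None and d < best:
            best = float(d)
    return best


@dataclass(frozen=True)
class ProximityComparison:
    partner_distances: tuple[float, ...]
    similar_nonpartner_distances: tuple[float, ...]

    @property
    def partner_median(self) -> float:
        return statistics.median(self.partner_distances)

    @property
    def similar_nonpartner_median(self) -> float:
        if not self.similar_nonpartner_distances:
            return math.nan
        return statistics.median(self.similar_nonpartner_distances)


def proximity_comparison(
    ppi: nx.Graph,
    drugs: Mapping[str, DrugRecord],
    net: nx.Graph,
    hub_set: Iterable[str],
    n_levels: int = 3,
) -> ProximityComparison:
    """Hub-to-partner vs hub-to-similar-non-partner target distances.

    For each hub drug with targets, the target-set distance to every
    combination partner (network neighbor) and to every therapeutically
    similar (TS > 0) drug that is not a partner.  Pairs where either
    target set is empty or absent from the PPI graph are skipped.
    """
    ts = TsCache(drugs, n_levels)
    partner, similar = [], []
    for hub in sorted(hub_set):
        if not drugs[hub].targets:
            continue
        neighbors = set(net.neighbors(hub))
        for other in sorted(net.nodes()):
            if other == hub or not drugs[other].targets:
                continue
            if other in neighbors:
                bucket = partner
            elif ts(hub, other) > 0:
                bucket = similar
            else:
                continue
            try:
                bucket.append(target_set_distance(ppi, drugs[hub].targets, drugs[other].targets))
            except ValueError:
                continue
    if not similar:
        logger.warning("no therapeutically similar non-partner pairs with targets")
    return ProximityComparison(tuple(partner), tuple(similar))


def localization_tally(
    drugs: Mapping[str, DrugRecord],
    localization: Mapping[str, str],
    drug_set: Iterable[str],
) -> dict[str, float]:
    """Fraction of the drug set's target proteins per localization class.

    The union of targets over the drug set is tallied; proteins without
    a localization annotation fall into the ``"unannotated"`` class.
    """
    targets: set[str] = set()
    for did in drug_set:
        targets |= drugs[did].targets
    if not targets:
        raise ValueError("drug set has no target annotations")
    counts: dict[str, int] = {}
    for p in targets:
        cls = localization.get(p, "unannotated")
        counts[cls] = counts.get(cls, 0) + 1
    return {cls: c / len(targets) for cls, c in sorted(counts.items())}
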