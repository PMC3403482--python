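"""The drug cocktail network and its topological descriptors.

Nodes are drugs; an edge joins two drugs that appear together in an
effective combination.  Combinations with more than two members are split
into all pairwise edges.  The module computes the degree distribution and
its log-log power-law fit, connected components, star drugs (degree >= 2),
hub drugs (degree >= 7 by default, i.e. "more than 6 neighbors"), and the
therapeutic-similarity structure around star drugs.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .atc import DrugRecord, therapeutic_similarity

__all__ = [
    "CombinationRecord",
    "PowerLawFit",
    "TsCache",
    "build_network",
    "degree_distribution",
    "fit_power_law",
    "connected_components",
    "star_drugs",
    "hub_drugs",
    "star_neighbor_ts_profile",
    "neighbor_pair_effective_fraction",
]

logger = logging.getLogger(__name__)

STATUSES = frozenset({"approved", "clinical", "preclinical"})


@dataclass(frozen=True)
class CombinationRecord:
    """One curated drug combination (two or more member drugs)."""

    combo_id: str
    members: tuple[str, ...]
    status: str = "approved"
    effective: bool = True

    def __post_init__(self) -> None:
        members = tuple(self.members)
        if len(members) < 2:
            raise ValueError(f"combination {self.combo_id!r} needs >= 2 members")
        if len(set(members)) != len(members):
            raise ValueError(f"combination {self.combo_id!r} has duplicate members")
        if self.status not in STATUSES:
            raise ValueError(
                f"combination {self.combo_id!r}: unknown status {self.status!r}"
            )
        object.__setattr__(self, "members", members)

    def pairs(self) -> list[tuple[str, str]]:
        """All unordered member pairs (C(k,2) edges for a k-member combo)."""
        return [tuple(sorted(p)) for p in itertools.combinations(self.members, 2)]


class TsCache:
    """Memoized pairwise therapeutic similarity over a drug table."""

    def __init__(self, drugs: Mapping[str, DrugRecord], n_levels: int = 3):
        self.drugs = drugs
        self.n_levels = n_levels
        self._cache: dict[frozenset[str], float] = {}

    def __call__(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        key = frozenset((a, b))
        ts = self._cache.get(key)
        if ts is None:
            ts = therapeutic_similarity(self.drugs[a], self.drugs[b], self.n_levels)
            self._cache[key] = ts
        return ts


def build_network(
    combinations: Iterable[CombinationRecord],
    drugs: Mapping[str, DrugRecord],
) -> nx.Graph:
    """Build the cocktail network from effective combinations.

    Combinations containing a member with no drug record are dropped with
    a warning (they cannot be scored for therapeutic similarity).
    Duplicate pairs across combinations collapse to a single edge.
    """
    net = nx.Graph()
    dropped = 0
    for combo in combinations:
        if not combo.effective:
            continue
        if any(m not in drugs for m in combo.members):
            dropped += 1
            logger.warning(
                "combination %s dropped: member without drug record", combo.combo_id
            )
            continue
        net.add_edges_from(combo.pairs())
    if dropped:
        logger.warning("%d combinations dropped for missing drug records", dropped)
    logger.info(
        "cocktail network: %d nodes, %d edges", net.number_of_nodes(), net.number_of_edges()
    )
    return net


def degree_distribution(net: nx.Graph) -> dict[int, float]:
    """Fraction of nodes at each observed degree; fractions sum to 1."""
    if net.number_of_nodes() == 0:
        raise ValueError("degree distribution of an empty network is undefined")
    n = net.number_of_nodes()
    counts: dict[int, int] = {}
    for _, deg in net.degree():
        counts[deg] = counts.get(deg, 0) + 1
    return {k: c / n for k, c in sorted(counts.items())}


@dataclass(frozen=True)
class PowerLawFit:
    """p(k) = c * k^-alpha fitted by least squares on log10-log10 points."""

    c: float
    alpha: float
    r_squared: float


def fit_power_law(dist: Mapping[int, float]) -> PowerLawFit:
    """Least-squares line through (log10 k, log10 P(k)).

    alpha is the negated slope and c = 10^intercept.  Degrees with zero
    probability are excluded (log undefined).  Requires at least three
    distinct degrees, otherwise the fit is unconstrained.
    """
    pts = [(k, p) for k, p in dist.items() if p > 0 and k > 0]
    if len(pts) < 3:
        raise ValueError(
            f"power-law fit needs >= 3 distinct positive degrees, got {len(pts)}"
        )
    x = np.log10([k for k, _ in pts])
    y = np.log10([p for _, p in pts])
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return PowerLawFit(c=float(10.0**intercept), alpha=float(-slope), r_squared=r2)


def connected_components(net: nx.Graph) -> list[set[str]]:
    """Components sorted by size descending, ties by smallest contained id."""
    comps = [set(c) for c in nx.connected_components(net)]
    return sorted(comps, key=lambda c: (-len(c), min(c)))


def star_drugs(net: nx.Graph) -> set[str]:
    """Drugs with at least two neighbors in the cocktail network."""
    return {node for node, deg in net.degree() if deg >= 2}


def hub_drugs(net: nx.Graph, min_neighbors: int = 7) -> set[str]:
    """Drugs with degree >= ``min_neighbors`` (default 7: "more than 6")."""
    if min_neighbors < 1:
        raise ValueError("min_neighbors must be >= 1")
    return {node for node, deg in net.degree() if deg >= min_neighbors}


def star_neighbor_ts_profile(
    net: nx.Graph,
    drugs: Mapping[str, DrugRecord],
    n_levels: int = 3,
) -> dict:
    """TS scores between each star drug and its neighbors.

    Returns per-star lists of TS scores, the pooled distribution, and the
    fraction of similar pairs under two counting conventions: per
    undirected star-incident edge (each edge once) and per ordered
    star/neighbor pair (an edge between two star drugs counts twice).
    """
    stars = star_drugs(net)
    if not stars:
        raise ValueError("network has no star drugs")
    ts = TsCache(drugs, n_levels)
    per_star: dict[str, list[float]] = {}
    edge_ts: dict[tuple[str, str], float] = {}
    for s in sorted(stars):
        scores = []
        for nb in net.neighbors(s):
            val = ts(s, nb)
            scores.append(val)
            edge_ts[tuple(sorted((s, nb)))] = val
        per_star[s] = scores
    pooled = [v for scores in per_star.values() for v in scores]
    edge_vals = list(edge_ts.values())
    return {
        "per_star": per_star,
        "pooled": pooled,
        "fraction_similar_edges": sum(v > 0 for v in edge_vals) / len(edge_vals),
        "fraction_similar_ordered": sum(v > 0 for v in pooled) / len(pooled),
        "n_edges": len(edge_vals),
        "n_ordered_pairs": len(pooled),
    }


def neighbor_pair_effective_fraction(
    net: nx.Graph,
    drugs: Mapping[str, DrugRecord],
    ts_grid: Sequence[float],
    n_levels: int = 3,
) -> list[tuple[float, float]]:
    """Fraction of star-neighbor pairs at TS >= t that are themselves edges.

    A "star-neighbor pair" is two distinct drugs sharing at least one
    common neighbor of degree >= 2; each unordered pair is counted once
    however many star drugs it shares.  For each threshold ``t`` in
    ``ts_grid`` the returned curve gives the fraction of such pairs with
    TS >= t that are edges of the network (NaN where no pair qualifies).
    """
    if any(not 0 <= t <= 1 for t in ts_grid):
        raise ValueError("ts_grid values must lie in [0, 1]")
    ts = TsCache(drugs, n_levels)
    pairs: set[tuple[str, str]] = set()
    for s in star_drugs(net):
        for a, b in itertools.combinations(sorted(net.neighbors(s)), 2):
            pairs.add((a, b))
    scored = [(ts(a, b), net.has_edge(a, b)) for a, b in pairs]
    curve = []
    for t in ts_grid:
        hits = [(v, e) for v, e in scored if v >= t]
        frac = math.nan if not hits else sum(e for _, e in hits) / len(hits)
        curve.append((float(t), frac))
    return curve
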