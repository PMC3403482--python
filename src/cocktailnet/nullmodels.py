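"""Null models for the cocktail network.

Random combination networks are produced by degree-preserving rewiring
(repeated double-edge swaps), which keeps every drug's number of partners
while shuffling who partners with whom.  The observed network-level mean
therapeutic similarity is compared against the rewired ensemble to give
an empirical p-value; per-component enrichment of level-1 ATC classes is
scored with the one-sided hypergeometric tail and Benjamini-Hochberg
correction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy import stats

from .atc import DrugRecord, atc_level_set, level_similarity, therapeutic_similarity

__all__ = [
    "RandomizationResult",
    "rewire_degree_preserving",
    "network_mean_ts",
    "ts_significance",
    "component_atc_enrichment",
]

logger = logging.getLogger(__name__)


def rewire_degree_preserving(
    net: nx.Graph, swap_factor: float = 10.0, seed: int = 0
) -> nx.Graph:
    """Randomize edges with double-edge swaps, preserving every degree.

    Attempts ``ceil(swap_factor * |E|)`` swaps; each picks two distinct
    edges (a,b), (c,d) and rewires to (a,d), (c,b) when that creates no
    self-loop or parallel edge.  Rigid graphs where no attempt can succeed
    (e.g. a triangle) come back unchanged with a warning.  Deterministic
    for a given seed.
    """
    if net.number_of_edges() < 2:
        raise ValueError("rewiring needs at least 2 edges")
    rng = np.random.default_rng(seed)
    out = nx.Graph()
    out.add_nodes_from(net.nodes())
    out.add_edges_from(net.edges())
    edges = [tuple(e) for e in out.edges()]
    attempts = math.ceil(swap_factor * len(edges))
    swapped = 0
    for _ in range(attempts):
        i, j = rng.integers(0, len(edges), size=2)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if rng.integers(0, 2):
            c, d = d, c
        # proposed: a-d and c-b
        if len({a, b, c, d}) < 4:
            continue
        if out.has_edge(a, d) or out.has_edge(c, b):
            continue
        out.remove_edge(a, b)
        out.remove_edge(c, d)
        out.add_edge(a, d)
        out.add_edge(c, b)
        edges[i] = (a, d)
        edges[j] = (c, b)
        swapped += 1
    if swapped == 0:
        logger.warning("no valid double-edge swap found; network returned unchanged")
    else:
        logger.debug("rewiring: %d/%d attempted swaps succeeded", swapped, attempts)
    return out


def network_mean_ts(
    net: nx.Graph,
    drugs: Mapping[str, DrugRecord],
    n_levels: int = 3,
    ts: Callable[[str, str], float] | None = None,
) -> float:
    """Mean therapeutic similarity over the network's edges."""
    if net.number_of_edges() == 0:
        raise ValueError("mean TS of an edgeless network is undefined")
    if ts is None:
        ts = lambda a, b: therapeutic_similarity(drugs[a], drugs[b], n_levels)
    return sum(ts(a, b) for a, b in net.edges()) / net.number_of_edges()


@dataclass(frozen=True)
class RandomizationResult:
    """Observed vs. degree-preserving-null mean TS at one ATC depth."""

    observed_ts: float
    replicate_ts: tuple[float, ...]
    empirical_p: float
    n_replicates: int
    seed: int
    atc_level: int

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.replicate_ts))

    @property
    def null_sd(self) -> float:
        return float(np.std(self.replicate_ts, ddof=1)) if self.n_replicates > 1 else 0.0


def ts_significance(
    net: nx.Graph,
    drugs: Mapping[str, DrugRecord],
    n_replicates: int = 1000,
    atc_levels: Sequence[int] = (1, 2, 3, 4),
    seed: int = 0,
    swap_factor: float = 10.0,
    agg: str = "mean",
) -> dict[int, RandomizationResult]:
    """Empirical significance of the observed network mean TS.

    For each ATC depth ``k`` the observed mean TS is compared with
    ``n_replicates`` degree-preserving rewirings; the empirical p-value is
    the fraction of replicates whose mean TS is >= the observed value
    (ties count toward the numerator).  ``agg="mean"`` scores drug pairs
    with the TS aggregated over levels 1..k; ``agg="single-level"`` uses
    the level-k Jaccard alone.  Replicate seeds are ``seed + replicate
    index``, so the rewired ensemble is shared across depths and runs are
    reproducible.
    """
    if agg not in ("mean", "single-level"):
        raise ValueError(f"agg must be 'mean' or 'single-level', got {agg!r}")
    cache: dict[tuple[frozenset[str], int], float] = {}

    def pair_ts(a: str, b: str, k: int) -> float:
        key = (frozenset((a, b)), k)
        val = cache.get(key)
        if val is None:
            if agg == "mean":
                val = therapeutic_similarity(drugs[a], drugs[b], k)
            else:
                val = level_similarity(drugs[a], drugs[b], k)
            cache[key] = val
        return val

    replicates = [
        rewire_degree_preserving(net, swap_factor, seed=seed + i)
        for i in range(n_replicates)
    ]
    results: dict[int, RandomizationResult] = {}
    for k in atc_levels:
        ts_k = lambda a, b: pair_ts(a, b, k)
        observed = network_mean_ts(net, drugs, ts=ts_k)
        rep_ts = tuple(network_mean_ts(rep, drugs, ts=ts_k) for rep in replicates)
        p = sum(r >= observed for r in rep_ts) / n_replicates
        results[k] = RandomizationResult(
            observed_ts=observed,
            replicate_ts=rep_ts,
            empirical_p=p,
            n_replicates=n_replicates,
            seed=seed,
            atc_level=k,
        )
    return results


def component_atc_enrichment(
    component: Iterable[str],
    drugs: Mapping[str, DrugRecord],
    universe: Iterable[str],
) -> list[dict]:
    """Level-1 ATC class enrichment of a component against the universe.

    A drug carrying several level-1 classes counts once toward each.  For
    each class present in the component: the hypergeometric upper-tail
    p-value of drawing at least the observed number of class carriers in
    a component-sized sample from the universe, plus the BH-adjusted q.
    Rows are sorted by ascending p (ties by class label).
    """
    component = set(component)
    universe = set(universe)
    if not component <= universe:
        raise ValueError("component must be a subset of the universe")
    class_universe: dict[str, int] = {}
    class_component: dict[str, int] = {}
    for did in universe:
        for cls in atc_level_set(drugs[did], 1):
            class_universe[cls] = class_universe.get(cls, 0) + 1
            if did in component:
                class_component[cls] = class_component.get(cls, 0) + 1
    M, n = len(universe), len(component)
    rows = []
    for cls in sorted(class_component):
        k, K = class_component[cls], class_universe[cls]
        p = float(stats.hypergeom.sf(k - 1, M, K, n))
        rows.append(
            {"atc_class": cls, "count_component": k, "count_universe": K, "p_value": p}
        )
    if rows:
        qs = stats.false_discovery_control([r["p_value"] for r in rows], method="bh")
        for r, q in zip(rows, qs):
            r["q_value"] = float(q)
    rows.sort(key=lambda r: (r["p_value"], r["atc_class"]))
    return rows
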