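"""DCPred: shared-neighbor scoring and ranking of candidate drug pairs.

Two drugs with ``n1`` and ``n2`` partners in a cocktail network of ``N``
drugs share ``m`` of them.  Under the null that the two neighborhoods are
independent uniform random subsets, the probability of observing exactly
``m`` common partners is

    P(m, n1, n2, N) = C(N,m) C(N-m, n1-m) C(N-n1, n2-m) / [C(N,n1) C(N,n2)]

which is algebraically the hypergeometric point probability
``C(n1,m) C(N-n1, n2-m) / C(N,n2)``.  Small values flag pairs sharing
unexpectedly many partners.  Three ranking models are provided: DCPred1
ranks therapeutically similar pairs by descending TS alone; DCPred2 and
DCPred3 restrict to drugs with at least 2 or 3 neighbors and rank by
ascending p-value.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import exp, lgamma
from typing import Mapping, Sequence

import networkx as nx

from .atc import DrugRecord
from .network import TsCache

__all__ = [
    "MODELS",
    "SharedNeighborStat",
    "CandidateScore",
    "shared_neighbor_pvalue",
    "candidate_pairs",
    "rank_candidates",
]

#: model name -> minimum degree both drugs must have
MODELS: dict[str, int] = {"DCPred1": 0, "DCPred2": 2, "DCPred3": 3}


def _normalize_model(model: str) -> str:
    for name in MODELS:
        if model.lower() == name.lower():
            return name
    raise ValueError(f"unknown model {model!r}; expected one of {sorted(MODELS)}")


def _log_comb(n: int, k: int) -> float:
    return lgamma(n + 1) - lgamma(k + 1) - lgamma(n - k + 1)


def shared_neighbor_pvalue(
    m: int, n1: int, n2: int, N: int, tail: bool = False
) -> float:
    """Probability of the observed shared-neighbor count.

    With ``tail=False`` (default) the point probability of exactly ``m``
    shared partners; with ``tail=True`` the upper tail P(M >= m).
    Computed in log space for numerical stability; exact symmetry in
    ``(n1, n2)`` is inherited from the formula.
    """
    for name, val in (("m", m), ("n1", n1), ("n2", n2), ("N", N)):
        if not isinstance(val, (int,)) or isinstance(val, bool):
            raise TypeError(f"{name} must be an integer, got {val!r}")
    if m < 0:
        raise ValueError(f"m must be >= 0, got {m}")
    if m > min(n1, n2):
        raise ValueError(f"m={m} exceeds min(n1, n2)={min(n1, n2)}")
    if max(n1, n2) > N:
        raise ValueError(f"max(n1, n2)={max(n1, n2)} exceeds N={N}")
    if tail:
        return min(1.0, sum(
            _point(j, n1, n2, N) for j in range(m, min(n1, n2) + 1)
        ))
    return _point(m, n1, n2, N)


def _point(m: int, n1: int, n2: int, N: int) -> float:
    if n1 > n2:  # canonical order makes the (n1, n2) symmetry exact in FP
        n1, n2 = n2, n1
    if n2 - m > N - n1:  # an overlap this small is impossible: zero mass
        return 0.0
    return exp(
        _log_comb(n1, m) + _log_comb(N - n1, n2 - m) - _log_comb(N, n2)
    )


@dataclass(frozen=True)
class SharedNeighborStat:
    m: int
    n1: int
    n2: int
    N: int
    p_value: float


@dataclass(frozen=True)
class CandidateScore:
    """One scored candidate pair in a model's ranking."""

    drug_a: str
    drug_b: str
    ts: float
    stat: SharedNeighborStat
    model: str
    rank: int
    known_positive: bool


def candidate_pairs(
    net: nx.Graph,
    drugs: Mapping[str, DrugRecord],
    model: str = "DCPred2",
    ts_min: float = 0.0,
    n_levels: int = 3,
) -> list[tuple[str, str]]:
    """Unordered pairs of network drugs eligible for ranking.

    Eligibility: therapeutic similarity strictly above ``ts_min``
    (default: TS > 0, "similar ATC codes"), and for DCPred2/3 both drugs
    must have at least 2/3 neighbors.  Existing edges are retained — they
    are the known positives the ranking is evaluated against.
    """
    model = _normalize_model(model)
    min_deg = MODELS[model]
    ts = TsCache(drugs, n_levels)
    nodes = sorted(n for n in net.nodes() if net.degree(n) >= min_deg)
    return [
        (a, b)
        for a, b in itertools.combinations(nodes, 2)
        if ts(a, b) > ts_min
    ]


def rank_candidates(
    candidates: Sequence[tuple[str, str]],
    net: nx.Graph,
    drugs: Mapping[str, DrugRecord],
    model: str = "DCPred2",
    n_levels: int = 3,
    N: int | None = None,
    tail: bool = False,
    exclude_pair_edge: bool = False,
) -> list[CandidateScore]:
    """Score and rank candidate pairs under one DCPred model.

    ``m``, ``n1``, ``n2`` come from the full neighbor sets in the network
    and ``N`` defaults to the node count.  DCPred1 orders by descending
    TS; DCPred2/3 by ascending p-value.  Ties break by descending TS,
    then lexicographic pair id, making the ranking deterministic and
    independent of input order.  ``exclude_pair_edge`` removes an
    existing edge's own contribution to the two degree counts.
    """
    model = _normalize_model(model)
    if not candidates:
        raise ValueError("candidate list is empty")
    if N is None:
        N = net.number_of_nodes()
    ts = TsCache(drugs, n_levels)
    scored = []
    for a, b in candidates:
        a, b = sorted((a, b))
        nbrs_a, nbrs_b = set(net.neighbors(a)), set(net.neighbors(b))
        m = len(nbrs_a & nbrs_b)
        n1, n2 = len(nbrs_a), len(nbrs_b)
        is_edge = net.has_edge(a, b)
        if exclude_pair_edge and is_edge:
            n1, n2 = n1 - 1, n2 - 1
        p = shared_neighbor_pvalue(m, n1, n2, N, tail=tail)
        scored.append(
            (a, b, ts(a, b), SharedNeighborStat(m, n1, n2, N, p), is_edge)
        )
    if model == "DCPred1":
        key = lambda r: (-r[2], r[0], r[1])
    else:
        key = lambda r: (r[3].p_value, -r[2], r[0], r[1])
    scored.sort(key=key)
    return [
        CandidateScore(a, b, t, stat, model, rank, pos)
        for rank, (a, b, t, stat, pos) in enumerate(scored, start=1)
    ]
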