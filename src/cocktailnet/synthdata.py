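"""Synthetic drug-combination data with known ground truth.

The generators emulate the statistical structure the analyses assume,
with a fabricated ATC alphabet so fixtures can never collide with real
codes: drugs carry 1-3 codes drawn from a synthetic five-level hierarchy
and cluster into therapeutic families; the combination network grows by
preferential attachment (scale-free degrees) with two biases — edges
preferentially join therapeutically similar drugs (TS-assortativity) and
new edges close triangles (triadic closure), so that truly combinable
pairs share partners.  A configurable fraction of true pairs is withheld
from the emitted table and returned as planted positives for evaluating
the ranking models.  A toy small-world PPI graph with drug-target
assignments places combination partners' targets close together.

Everything is deterministic per seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .atc import DrugRecord
from .network import CombinationRecord, TsCache, build_network

__all__ = [
    "GeneratorConfig",
    "generate_drugs",
    "generate_cocktail_network",
    "generate_ppi",
    "drug_records_from_frame",
    "combinations_from_frame",
    "planted_benchmark",
]

# Level-1 letters unused by the real ATC system.
_SYNTH_CLASSES = "EFIKOQTUWXYZ"


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic study conditions.

    Defaults describe the benchmark scenario: 500 drugs over 6
    therapeutic classes, a scale-free combination network with strong
    therapeutic assortativity (most edges join TS-similar drugs, as in
    curated combination data), triadic closure so combinable pairs share
    partners, and 10% of true pairs withheld for evaluation.
    """

    n_drugs: int = 500
    n_atc_classes: int = 6
    #: probability of a drug carrying 1, 2 or 3 ATC codes
    codes_per_drug: tuple[float, ...] = (0.6, 0.3, 0.1)
    #: target exponent of the degree distribution (log-log OLS scale)
    degree_exponent: float = 2.0
    #: probability an edge endpoint is chosen among TS-similar drugs
    ts_assortativity: float = 0.7
    #: probability an extra edge of a new drug closes a triangle
    triadic_closure: float = 0.6
    #: probability a new drug brings 1, 2 or 3 edges
    edges_per_drug: tuple[float, ...] = (0.5, 0.3, 0.2)
    #: fraction of generated true pairs withheld as evaluation positives
    planted_fraction: float = 0.1
    #: proteins in the toy PPI graph, as a multiple of n_drugs
    ppi_size_factor: float = 2.0
    #: probability a partner's target is placed within 2 hops
    partner_target_proximity: float = 0.8
    ppi_min_score: int = 700
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_drugs < 4:
            raise ValueError("n_drugs must be >= 4")
        if not 1 <= self.n_atc_classes <= len(_SYNTH_CLASSES):
            raise ValueError(f"n_atc_classes must be in 1..{len(_SYNTH_CLASSES)}")
        for name in ("ts_assortativity", "triadic_closure", "planted_fraction",
                     "partner_target_proximity"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("codes_per_drug", "edges_per_drug"):
            w = getattr(self, name)
            if abs(sum(w) - 1) > 1e-9 or any(p < 0 for p in w):
                raise ValueError(f"{name} must be a probability vector")


def _code_pool(n_classes: int) -> dict[str, list[str]]:
    """Full level-5 code pool per synthetic level-1 class."""
    pool: dict[str, list[str]] = {}
    for cls in _SYNTH_CLASSES[:n_classes]:
        codes = []
        for lvl2 in ("01", "02", "03"):
            for lvl3 in "AB":
                for lvl4 in "AB":
                    for lvl5 in ("01", "02", "03", "04"):
                        codes.append(f"{cls}{lvl2}{lvl3}{lvl4}{lvl5}")
        pool[cls] = codes
    return pool


def generate_drugs(cfg: GeneratorConfig) -> pd.DataFrame:
    """Drug table with synthetic ATC annotations.

    Each drug belongs to a therapeutic family (a level-3 prefix of its
    primary class) and samples most of its codes inside that family, so
    same-family drugs score high TS and cross-class drugs score 0.
    Columns match the drug-annotation TSV dialect; targets are left
    empty (filled by :func:`generate_ppi`).
    """
    rng = np.random.default_rng(cfg.seed)
    pool = _code_pool(cfg.n_atc_classes)
    classes = list(pool)
    rows = []
    for i in range(cfg.n_drugs):
        cls = classes[rng.integers(len(classes))]
        family = f"{cls}{['01','02','03'][rng.integers(3)]}{'AB'[rng.integers(2)]}"
        family_codes = [c for c in pool[cls] if c.startswith(family)]
        n_codes = 1 + rng.choice(len(cfg.codes_per_drug), p=cfg.codes_per_drug)
        codes: set[str] = set()
        while len(codes) < n_codes:
            u = rng.random()
            if u < 0.7:
                codes.add(family_codes[rng.integers(len(family_codes))])
            elif u < 0.9:
                codes.add(pool[cls][rng.integers(len(pool[cls]))])
            else:
                other = classes[rng.integers(len(classes))]
                codes.add(pool[other][rng.integers(len(pool[other]))])
        rows.append(
            {
                "drug_id": f"SD{i:04d}",
                "name": f"synthdrug-{i:04d}",
                "atc_codes": ";".join(sorted(codes)),
                "targets": "",
            }
        )
    return pd.DataFrame(rows)


def drug_records_from_frame(drugs: pd.DataFrame) -> dict[str, DrugRecord]:
    """Materialize DrugRecord objects from a drug table."""
    records = {}
    for row in drugs.itertuples(index=False):
        targets = [t for t in str(getattr(row, "targets", "") or "").split(";") if t]
        records[row.drug_id] = DrugRecord(
            drug_id=row.drug_id,
            name=row.name,
            atc_codes=frozenset(row.atc_codes.split(";")),
            targets=frozenset(targets),
        )
    return records


def combinations_from_frame(combos: pd.DataFrame) -> list[CombinationRecord]:
    """Materialize CombinationRecord objects from a combinations table."""
    return [
        CombinationRecord(
            combo_id=row.combo_id,
            members=tuple(row.members.split(";")),
            status=row.status,
            effective=bool(row.effective) if not isinstance(row.effective, str)
            else row.effective.strip().lower() in ("true", "1", "yes"),
        )
        for row in combos.itertuples(index=False)
    ]


def generate_cocktail_network(
    cfg: GeneratorConfig, drugs: pd.DataFrame
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Grow a TS-assortative scale-free combination network.

    Returns the emitted combinations table (one 2-member effective
    combination per kept edge) and the withheld planted pairs.  Growth:
    each new drug attaches 1-3 edges; the first partner is drawn by
    degree-preferential attachment, restricted with probability
    ``ts_assortativity`` to TS-similar existing drugs; each further edge
    closes a triangle through a random partner-of-partner with
    probability ``triadic_closure``.  Withheld pairs are sampled only
    where both endpoints keep degree >= 2, so the emitted network loses
    no nodes.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    records = drug_records_from_frame(drugs)
    ids = list(drugs["drug_id"])
    ts = TsCache(records)
    g = nx.Graph()
    g.add_edge(ids[0], ids[1])

    def pick_preferential(pool: list[str]) -> str:
        weights = np.array([g.degree(x) + 1.0 for x in pool])
        return pool[rng.choice(len(pool), p=weights / weights.sum())]

    for new in ids[2:]:
        existing = list(g.nodes())
        n_edges = 1 + rng.choice(len(cfg.edges_per_drug), p=cfg.edges_per_drug)
        similar = [x for x in existing if ts(new, x) > 0]
        if similar and rng.random() < cfg.ts_assortativity:
            first = pick_preferential(similar)
        else:
            first = pick_preferential(existing)
        g.add_edge(new, first)
        anchor = first
        for _ in range(n_edges - 1):
            closure = [
                x for x in g.neighbors(anchor) if x != new and not g.has_edge(new, x)
            ]
            if closure and rng.random() < cfg.triadic_closure:
                nxt = closure[rng.integers(len(closure))]
            else:
                pool = [x for x in existing if x != new and not g.has_edge(new, x)]
                if not pool:
                    break
                if similar and rng.random() < cfg.ts_assortativity:
                    spool = [x for x in pool if ts(new, x) > 0]
                    nxt = pick_preferential(spool or pool)
                else:
                    nxt = pick_preferential(pool)
            g.add_edge(new, nxt)

    edges = sorted(tuple(sorted(e)) for e in g.edges())
    n_plant = int(round(cfg.planted_fraction * len(edges)))
    planted: list[tuple[str, str]] = []
    order = rng.permutation(len(edges))
    for idx in order:
        if len(planted) == n_plant:
            break
        a, b = edges[idx]
        if g.degree(a) > 2 and g.degree(b) > 2:
            g.remove_edge(a, b)
            planted.append((a, b))
    kept = sorted(tuple(sorted(e)) for e in g.edges())
    statuses = rng.choice(
        ["approved", "clinical", "preclinical"], size=len(kept), p=(0.4, 0.33, 0.27)
    )
    combos = pd.DataFrame(
        {
            "combo_id": [f"SC{i:05d}" for i in range(len(kept))],
            "members": [f"{a};{b}" for a, b in kept],
            "status": statuses,
            "effective": ["true"] * len(kept),
        }
    )
    return combos, sorted(planted)


def generate_ppi(
    cfg: GeneratorConfig,
    drugs: pd.DataFrame,
    net: nx.Graph | None = None,
) -> tuple[pd.DataFrame, dict[str, set[str]]]:
    """Toy small-world PPI graph plus drug-target assignment.

    Targets of combination partners (edges of ``net``, when given) are
    placed within two hops of each other with probability
    ``partner_target_proximity``; other drugs target random proteins.
    All emitted scores are >= ``ppi_min_score``.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    n_prot = max(10, int(cfg.ppi_size_factor * cfg.n_drugs))
    g = nx.connected_watts_strogatz_graph(n_prot, k=6, p=0.1, seed=cfg.seed + 2)
    proteins = [f"SP{i:05d}" for i in range(n_prot)]
    rows = [
        {
            "protein1": proteins[a],
            "protein2": proteins[b],
            "combined_score": int(rng.integers(cfg.ppi_min_score, 1000)),
        }
        for a, b in sorted(g.edges())
    ]
    ppi_df = pd.DataFrame(rows)

    idx = {p: i for i, p in enumerate(proteins)}
    targets: dict[str, set[str]] = {}
    for did in drugs["drug_id"]:
        n_targets = 1 + rng.integers(3)
        chosen: set[str] = set()
        anchor_pool: list[str] = []
        if net is not None and did in net:
            for nb in net.neighbors(did):
                anchor_pool.extend(targets.get(nb, ()))
        if anchor_pool and rng.random() < cfg.partner_target_proximity:
            base = anchor_pool[rng.integers(len(anchor_pool))]
            near = list(nx.single_source_shortest_path_length(g, idx[base], cutoff=2))
            chosen.add(proteins[near[rng.integers(len(near))]])
        while len(chosen) < n_targets:
            chosen.add(proteins[rng.integers(n_prot)])
        targets[did] = chosen
    return ppi_df, targets


def planted_benchmark(
    cfg: GeneratorConfig, models: tuple[str, ...] = ("DCPred1", "DCPred2")
) -> dict[str, float]:
    """Generate, rank, and score recovery of withheld pairs (AUC per model).

    Candidates are each model's eligible non-edge pairs of the emitted
    network; positives are the planted (withheld) true pairs.
    """
    from .dcpred import candidate_pairs, rank_candidates
    from .evaluate import roc_auc

    drugs = generate_drugs(cfg)
    combos, planted = generate_cocktail_network(cfg, drugs)
    records = drug_records_from_frame(drugs)
    net = build_network(combinations_from_frame(combos), records)
    out: dict[str, float] = {}
    for model in models:
        cands = [
            p
            for p in candidate_pairs(net, records, model)
            if not net.has_edge(*p)
        ]
        ranking = rank_candidates(cands, net, records, model)
        out[model] = roc_auc(
            ranking, positives=[frozenset(p) for p in planted]
        ).auc
    return out
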