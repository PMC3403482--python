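"""ROC/AUC and threshold metrics for ranked candidate lists.

Positives default to the candidate pairs that are edges of the cocktail
network (the known effective combinations); every other candidate is a
negative.  The ROC sweeps all score thresholds with tied scores grouped
(all equally-scored items cross together), and the AUC is the trapezoid
area — equal to the probability that a random positive outranks a random
negative.  An optional hold-out mode masks a fraction of edges, ranks
without them, and scores recovery of the masked pairs, avoiding the
optimism of scoring known edges with their own contribution present.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve

from .atc import DrugRecord
from .dcpred import CandidateScore, candidate_pairs, rank_candidates

__all__ = ["EvaluationReport", "roc_auc", "threshold_metrics", "holdout_evaluation"]


@dataclass(frozen=True)
class EvaluationReport:
    roc_points: tuple[tuple[float, float], ...]
    auc: float
    threshold_table: tuple[dict, ...]
    n_pos: int
    n_neg: int


def _scores_labels(
    ranking: Sequence[CandidateScore],
    positives: Iterable[frozenset[str]] | None,
) -> tuple[np.ndarray, np.ndarray]:
    if not ranking:
        raise ValueError("ranking is empty")
    model = ranking[0].model
    if model == "DCPred1":
        scores = np.array([r.ts for r in ranking])
    else:  # ascending p-value: better candidates get larger scores
        scores = np.array([-r.stat.p_value for r in ranking])
    if positives is None:
        labels = np.array([r.known_positive for r in ranking], dtype=int)
    else:
        pos = {frozenset(p) for p in positives}
        labels = np.array(
            [frozenset((r.drug_a, r.drug_b)) in pos for r in ranking], dtype=int
        )
    if labels.min() == labels.max():
        raise ValueError("need at least one positive and one negative label")
    return scores, labels


def roc_auc(
    ranking: Sequence[CandidateScore],
    positives: Iterable[frozenset[str]] | None = None,
    cutoffs: Sequence[int] | None = None,
) -> EvaluationReport:
    """ROC curve, trapezoid AUC and threshold metrics for a ranking."""
    scores, labels = _scores_labels(ranking, positives)
    fpr, tpr, _ = roc_curve(labels, scores)
    report_auc = float(_trapezoid_auc(fpr, tpr))
    if cutoffs is None:
        cutoffs = range(len(ranking) + 1)
    table = threshold_metrics(ranking, cutoffs, positives=positives)
    return EvaluationReport(
        roc_points=tuple(zip(map(float, fpr), map(float, tpr))),
        auc=report_auc,
        threshold_table=tuple(table),
        n_pos=int(labels.sum()),
        n_neg=int(len(labels) - labels.sum()),
    )


def threshold_metrics(
    ranking: Sequence[CandidateScore],
    cutoffs: Iterable[int],
    positives: Iterable[frozenset[str]] | None = None,
) -> list[dict]:
    """Sensitivity, specificity and accuracy at each rank cutoff.

    At cutoff ``c`` the top ``c`` ranked pairs are called positive and
    the rest negative; standard confusion-matrix definitions apply.
    """
    _, labels = _scores_labels(ranking, positives)
    order = np.argsort([r.rank for r in ranking])
    lab = labels[order]
    n_pos, n_neg = int(lab.sum()), int(len(lab) - lab.sum())
    rows = []
    for c in cutoffs:
        if not 0 <= c <= len(lab):
            raise ValueError(f"cutoff {c} outside 0..{len(lab)}")
        tp = int(lab[:c].sum())
        fp = c - tp
        fn = n_pos - tp
        tn = n_neg - fp
        rows.append(
            {
                "cutoff": int(c),
                "sensitivity": tp / n_pos,
                "specificity": tn / n_neg,
                "accuracy": (tp + tn) / len(lab),
            }
        )
    return rows


def holdout_evaluation(
    net: nx.Graph,
    drugs: Mapping[str, DrugRecord],
    model: str = "DCPred2",
    holdout_frac: float = 0.2,
    seed: int = 0,
    ts_min: float = 0.0,
    n_levels: int = 3,
) -> EvaluationReport:
    """Mask a fraction of edges, rank without them, score their recovery.

    The masked edges are the positives; candidates are the model's
    eligible non-edge pairs of the reduced network.  Node set (and hence
    N) is kept fixed so degree-1 drugs are not silently dropped.
    """
    if not 0 < holdout_frac < 1:
        raise ValueError("holdout_frac must be in (0, 1)")
    rng = np.random.default_rng(seed)
    edges = sorted(tuple(sorted(e)) for e in net.edges())
    n_mask = max(1, int(round(holdout_frac * len(edges))))
    mask_idx = rng.choice(len(edges), size=n_mask, replace=False)
    masked = {edges[i] for i in mask_idx}
    reduced = nx.Graph()
    reduced.add_nodes_from(net.nodes())
    reduced.add_edges_from(e for e in edges if e not in masked)
    cands = [
        p
        for p in candidate_pairs(reduced, drugs, model, ts_min, n_levels)
        if not reduced.has_edge(*p)
    ]
    ranking = rank_candidates(cands, reduced, drugs, model, n_levels)
    return roc_auc(ranking, positives=[frozenset(e) for e in masked])
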