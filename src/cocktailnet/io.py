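"""Readers and writers for the package's TSV dialects.

All tables are UTF-8 TSV with a required header row; ``#`` lines are
comments; semicolons separate in-cell lists.  Loading applies the
curation rules of the analysis — drugs without ATC codes and
combinations that are ineffective or reference unknown drugs are
excluded, with counts reported — and malformed rows fail with
line-numbered errors rather than being silently skipped.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .atc import DrugRecord
from .dcpred import CandidateScore, SharedNeighborStat
from .network import CombinationRecord, TsCache, hub_drugs, star_drugs

__all__ = [
    "ExclusionReport",
    "read_drugs",
    "read_combinations",
    "load_dataset",
    "read_ppi_table",
    "read_localization",
    "write_network",
    "write_ranking",
    "read_ranking",
]

logger = logging.getLogger(__name__)

_TRUE = {"true", "1", "yes"}
_FALSE = {"false", "0", "no"}


def _rows(path: str | Path, required: Sequence[str]):
    """Yield (line_number, dict) for each data row; validate the header."""
    path = Path(path)
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = None
        for lineno, raw in enumerate(reader, start=1):
            if not raw or raw[0].startswith("#"):
                continue
            if header is None:
                header = [h.strip() for h in raw]
                missing = [c for c in required if c not in header]
                if missing:
                    raise ValueError(
                        f"{path}: missing required column(s) {missing} in header"
                    )
                continue
            yield lineno, dict(zip(header, raw))
        if header is None:
            raise ValueError(f"{path}: no header row found")


def _split(cell: str) -> list[str]:
    return [x.strip() for x in (cell or "").split(";") if x.strip()]


def read_drugs(path: str | Path) -> tuple[dict[str, DrugRecord], int]:
    """Load the drug annotation table.

    Returns the drug records plus the number of rows discarded for
    having no ATC code.  Malformed ATC codes and duplicate drug ids
    raise with the offending line number.
    """
    drugs: dict[str, DrugRecord] = {}
    no_atc = 0
    for lineno, row in _rows(path, ["drug_id", "name", "atc_codes", "targets"]):
        did = row["drug_id"].strip()
        if did in drugs:
            raise ValueError(f"{path}:{lineno}: duplicate drug_id {did!r}")
        codes = _split(row["atc_codes"])
        if not codes:
            no_atc += 1
            continue
        try:
            drugs[did] = DrugRecord(
                drug_id=did,
                name=row["name"].strip(),
                atc_codes=frozenset(codes),
                targets=frozenset(_split(row.get("targets", ""))),
            )
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
    if no_atc:
        logger.info("%d drugs without ATC codes discarded", no_atc)
    return drugs, no_atc


def read_combinations(path: str | Path) -> tuple[list[CombinationRecord], int]:
    """Load the combinations table, dropping non-effective records.

    Returns the effective combinations plus the count of dropped
    ineffective/unclear ones.
    """
    combos: list[CombinationRecord] = []
    dropped = 0
    for lineno, row in _rows(path, ["combo_id", "members", "status", "effective"]):
        flag = row["effective"].strip().lower()
        if flag not in _TRUE | _FALSE:
            raise ValueError(
                f"{path}:{lineno}: effective must be true/false, got {row['effective']!r}"
            )
        if flag in _FALSE:
            dropped += 1
            continue
        try:
            combos.append(
                CombinationRecord(
                    combo_id=row["combo_id"].strip(),
                    members=tuple(_split(row["members"])),
                    status=row["status"].strip().lower(),
                    effective=True,
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
    if dropped:
        logger.info("%d non-effective combinations discarded", dropped)
    return combos, dropped


@dataclass(frozen=True)
class ExclusionReport:
    """What the curation rules removed and what remains."""

    drugs_without_atc: int
    non_effective_combos: int
    combos_missing_drug_record: int
    retained_combinations: int
    pairs_after_splitting: int
    unique_edges: int


def load_dataset(
    drugs_path: str | Path, combos_path: str | Path
) -> tuple[dict[str, DrugRecord], list[CombinationRecord], ExclusionReport]:
    """Load both tables and apply the curation rules.

    Combinations with a member lacking a (retained) drug record are
    dropped and counted; ``pairs_after_splitting`` counts every pairwise
    split of the retained multi-member combinations before edge
    deduplication.
    """
    drugs, no_atc = read_drugs(drugs_path)
    combos_all, non_eff = read_combinations(combos_path)
    retained, missing = [], 0
    for combo in combos_all:
        if all(m in drugs for m in combo.members):
            retained.append(combo)
        else:
            missing += 1
    pairs = [p for c in retained for p in c.pairs()]
    report = ExclusionReport(
        drugs_without_atc=no_atc,
        non_effective_combos=non_eff,
        combos_missing_drug_record=missing,
        retained_combinations=len(retained),
        pairs_after_splitting=len(pairs),
        unique_edges=len(set(pairs)),
    )
    logger.info("dataset loaded: %s", report)
    return drugs, retained, report


def read_ppi_table(path: str | Path) -> list[tuple[str, str, int]]:
    """Parse a STRING-style PPI TSV into (protein1, protein2, score) rows."""
    rows = []
    for lineno, row in _rows(path, ["protein1", "protein2", "combined_score"]):
        try:
            score = int(row["combined_score"])
        except ValueError as exc:
            raise ValueError(
                f"{path}:{lineno}: combined_score must be an integer, "
                f"got {row['combined_score']!r}"
            ) from exc
        rows.append((row["protein1"].strip(), row["protein2"].strip(), score))
    return rows


def read_localization(path: str | Path) -> dict[str, str]:
    """Parse a protein localization TSV (protein_id, localization)."""
    return {
        row["protein_id"].strip(): row["localization"].strip()
        for _, row in _rows(path, ["protein_id", "localization"])
    }


def write_network(
    net: nx.Graph,
    drugs: Mapping[str, DrugRecord],
    out_dir: str | Path,
    n_levels: int = 3,
    hub_threshold: int = 7,
) -> dict:
    """Export the network as edge TSV + GraphML and return a summary.

    GraphML nodes carry degree and star/hub flags; edges carry the TS
    score, so the export is self-describing for external graph tools.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ts = TsCache(drugs, n_levels)
    stars, hubs = star_drugs(net), hub_drugs(net, hub_threshold)
    export = nx.Graph()
    for node in net.nodes():
        export.add_node(
            node,
            degree=net.degree(node),
            star=node in stars,
            hub=node in hubs,
        )
    with (out_dir / "edges.tsv").open("w", encoding="utf-8") as fh:
        fh.write("drug_id_1\tdrug_id_2\tts\n")
        for a, b in sorted(tuple(sorted(e)) for e in net.edges()):
            val = ts(a, b)
            export.add_edge(a, b, ts=val)
            fh.write(f"{a}\t{b}\t{val:.10g}\n")
    nx.write_graphml(export, out_dir / "network.graphml")
    summary = {
        "n_nodes": net.number_of_nodes(),
        "n_edges": net.number_of_edges(),
        "n_star_drugs": len(stars),
        "n_hub_drugs": len(hubs),
        "hub_threshold": hub_threshold,
    }
    (out_dir / "network_summary.json").write_text(json.dumps(summary, indent=2))
    return summary


_RANKING_COLS = [
    "rank", "drug_id_1", "drug_id_2", "ts", "m", "n1", "n2", "N",
    "p_value", "known_positive", "model",
]


def write_ranking(ranking: Iterable[CandidateScore], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("\t".join(_RANKING_COLS) + "\n")
        for r in ranking:
            fh.write(
                f"{r.rank}\t{r.drug_a}\t{r.drug_b}\t{r.ts!r}\t{r.stat.m}\t"
                f"{r.stat.n1}\t{r.stat.n2}\t{r.stat.N}\t{r.stat.p_value!r}\t"
                f"{str(r.known_positive).lower()}\t{r.model}\n"
            )


def read_ranking(path: str | Path) -> list[CandidateScore]:
    ranking = []
    for lineno, row in _rows(path, _RANKING_COLS):
        try:
            ranking.append(
                CandidateScore(
                    drug_a=row["drug_id_1"],
                    drug_b=row["drug_id_2"],
                    ts=float(row["ts"]),
                    stat=SharedNeighborStat(
                        m=int(row["m"]), n1=int(row["n1"]), n2=int(row["n2"]),
                        N=int(row["N"]), p_value=float(row["p_value"]),
                    ),
                    model=row["model"],
                    rank=int(row["rank"]),
                    known_positive=row["known_positive"].strip().lower() in _TRUE,
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
    ranking.sort(key=lambda r: r.rank)
    return ranking
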