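"""ATC codes and therapeutic similarity.

The WHO Anatomical Therapeutic Chemical (ATC) system classifies drugs at
five hierarchical levels, all encoded as prefixes of a 7-character code:
level 1 is the anatomical main group (1 letter), level 2 the therapeutic
subgroup (+2 digits), levels 3 and 4 pharmacological/chemical subgroups
(+1 letter each), and level 5 the chemical substance (+2 digits).  Two
drugs' therapeutic closeness is scored per level as the Jaccard similarity
of their level-k code sets, and aggregated as the mean over the first
``n`` levels (default ``n = 3``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "ATC_LEVEL_LENGTHS",
    "AtcCode",
    "DrugRecord",
    "atc_level_set",
    "level_similarity",
    "therapeutic_similarity",
]

#: Prefix length of each ATC level (level -> number of characters).
ATC_LEVEL_LENGTHS: dict[int, int] = {1: 1, 2: 3, 3: 4, 4: 5, 5: 7}

_ATC_RE = re.compile(r"^[A-Z]\d\d[A-Z][A-Z]\d\d$")


@dataclass(frozen=True)
class AtcCode:
    """A full (level-5) ATC code, e.g. ``C03AA03``."""

    code: str

    def __post_init__(self) -> None:
        if not _ATC_RE.match(self.code):
            raise ValueError(
                f"malformed ATC code {self.code!r}: expected 7 characters "
                "shaped letter-digit-digit-letter-letter-digit-digit"
            )

    def level(self, k: int) -> str:
        """Return the level-``k`` prefix of this code."""
        _check_level(k)
        return self.code[: ATC_LEVEL_LENGTHS[k]]

    @property
    def levels(self) -> dict[int, str]:
        return {k: self.code[:n] for k, n in ATC_LEVEL_LENGTHS.items()}


@dataclass(frozen=True)
class DrugRecord:
    """A drug with its ATC annotation and optional protein targets.

    Drugs without any ATC code cannot be scored for therapeutic
    similarity and are rejected at load time, mirroring the curation rule
    that combinations whose members lack ATC codes are discarded.
    """

    drug_id: str
    name: str = ""
    atc_codes: frozenset[AtcCode] = field(default_factory=frozenset)
    targets: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.atc_codes:
            raise ValueError(f"drug {self.drug_id!r} has no ATC codes")
        object.__setattr__(self, "atc_codes", frozenset(
            c if isinstance(c, AtcCode) else AtcCode(c) for c in self.atc_codes
        ))
        object.__setattr__(self, "targets", frozenset(self.targets))


def _check_level(k: int) -> None:
    if k not in ATC_LEVEL_LENGTHS:
        raise ValueError(f"ATC level must be in 1..5, got {k}")


def atc_level_set(drug: DrugRecord, k: int) -> set[str]:
    """Distinct level-``k`` prefixes over all of the drug's ATC codes."""
    _check_level(k)
    return {code.level(k) for code in drug.atc_codes}


def level_similarity(d1: DrugRecord, d2: DrugRecord, k: int) -> float:
    """Jaccard similarity of the two drugs' level-``k`` code sets.

    ``S_k = |ATC_k(d1) ∩ ATC_k(d2)| / |ATC_k(d1) ∪ ATC_k(d2)|``
    """
    a, b = atc_level_set(d1, k), atc_level_set(d2, k)
    return len(a & b) / len(a | b)


def therapeutic_similarity(d1: DrugRecord, d2: DrugRecord, n: int = 3) -> float:
    """Mean of the level similarities ``S_1 .. S_n`` (the TS score).

    ``n = 3`` is the standard aggregation depth: level 5 is too sparse to
    be informative (few drug pairs share a full substance code) and level
    4 adds little beyond level 3.  Symmetric in its drug arguments; 1.0
    for identically-annotated drugs, 0.0 for drugs disjoint at every
    level up to ``n``.
    """
    if not 1 <= n <= 5:
        raise ValueError(f"aggregation depth n must be in 1..5, got {n}")
    return sum(level_similarity(d1, d2, k) for k in range(1, n + 1)) / n
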