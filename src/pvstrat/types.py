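"""Core domain containers for spontaneous-report signal detection.

A spontaneous reporting system (SRS) collects voluntary reports of suspected
adverse drug reactions (ADRs).  After splitting each report into one
drug-to-one-ADR records and aggregating, the unit of analysis is the
(drug, ADR) pair with its occurrence count.  A curated reference database of
known drug-ADR associations (extracted from product labeling) provides the
``known`` annotation used downstream for recall/precision evaluation.
"""

from __future__ import annotations

from collections.abc import Iterable
from dataclasses import dataclass, field, replace
from enum import Enum

__all__ = [
    "DrugType",
    "ReportRecord",
    "ReferenceDB",
    "DrugAdrPair",
    "Sample",
]


class DrugType(str, Enum):
    """Drug class recorded on a spontaneous report."""

    TCM = "TCM"
    WESTERN = "western"
    BIOLOGICAL = "biological"

    @classmethod
    def coerce(cls, value: "DrugType | str") -> "DrugType":
        """Accept enum members or (case-insensitive) string labels."""
        if isinstance(value, cls):
            return value
        text = str(value).strip()
        for member in cls:
            if member.value.lower() == text.lower():
                return member
        raise ValueError(f"unknown drug type: {value!r}")


@dataclass(frozen=True)
class ReportRecord:
    """One drug-to-one-ADR record obtained by splitting a raw report."""

    report_id: str
    drug_name: str
    drug_type: DrugType
    adr_name: str
    serious: bool = False


class ReferenceDB:
    """Set of known (drug, ADR) associations used as the evaluation standard.

    ``drugs`` and ``adrs`` are the projections of ``pairs`` and are computed
    once at construction; duplicates in the input are silently collapsed.
    """

    __slots__ = ("pairs", "drugs", "adrs")

    def __init__(self, pairs: Iterable[tuple[str, str]]):
        self.pairs: frozenset[tuple[str, str]] = frozenset(
            (str(d), str(a)) for d, a in pairs
        )
        self.drugs: frozenset[str] = frozenset(d for d, _ in self.pairs)
        self.adrs: frozenset[str] = frozenset(a for _, a in self.pairs)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self.pairs

    def __len__(self) -> int:
        return len(self.pairs)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ReferenceDB) and self.pairs == other.pairs

    def __repr__(self) -> str:
        return (
            f"ReferenceDB({len(self.pairs)} pairs, {len(self.drugs)} drugs, "
            f"{len(self.adrs)} ADRs)"
        )


@dataclass
class DrugAdrPair:
    """Aggregated (drug, ADR) pair with its occurrence count.

    ``known`` is None until :func:`pvstrat.report_ingest.annotate_known`
    stamps it against the reference database.
    """

    drug_name: str
    drug_type: DrugType
    adr_name: str
    count: int
    known: bool | None = None

    @property
    def key(self) -> tuple[str, str]:
        return (self.drug_name, self.adr_name)


@dataclass
class Sample:
    """A collection of aggregated pairs: the total sample or a drug-class stratum.

    ``n_reports`` is the number of one-drug-one-ADR records the pairs were
    aggregated from (equal to the sum of counts when no further filtering
    happened afterwards).
    """

    pairs: list[DrugAdrPair]
    label: str = "total"
    n_reports: int = 0

    def __post_init__(self) -> None:
        if self.label not in ("total", "stratum"):
            raise ValueError(f"sample label must be 'total' or 'stratum', got {self.label!r}")

    @property
    def total_count(self) -> int:
        return sum(p.count for p in self.pairs)

    @property
    def keys(self) -> set[tuple[str, str]]:
        return {p.key for p in self.pairs}

    def by_key(self) -> dict[tuple[str, str], DrugAdrPair]:
        index = {}
        for p in self.pairs:
            if p.key in index:
                raise ValueError(f"duplicate pair in sample: {p.key}")
            index[p.key] = p
        return index

    def margins(self) -> tuple[dict[str, int], dict[str, int], int]:
        """Per-drug and per-ADR record totals plus the grand total."""
        drug_margin: dict[str, int] = {}
        adr_margin: dict[str, int] = {}
        total = 0
        for p in self.pairs:
            drug_margin[p.drug_name] = drug_margin.get(p.drug_name, 0) + p.count
            adr_margin[p.adr_name] = adr_margin.get(p.adr_name, 0) + p.count
            total += p.count
        return drug_margin, adr_margin, total
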