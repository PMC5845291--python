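"""Ingest spontaneous reports and the reference database.

The cleaning funnel mirrors standard SRS preprocessing: raw reports carrying
several ADRs are split into one-drug-one-ADR records, records with an unknown
drug or ADR name are dropped, records are aggregated into (drug, ADR) pairs
with occurrence counts, pairs below the minimum case count or whose drug is
absent from the reference database are removed, and the survivors are
annotated as known/unknown against the reference pairs.  A drug-class stratum
(e.g. the traditional Chinese medicine subset) is then extracted from the
total sample.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Sequence
from pathlib import Path

import pandas as pd

from .types import DrugAdrPair, DrugType, ReferenceDB, ReportRecord, Sample

__all__ = [
    "split_multi_adr",
    "filter_unknown",
    "deduplicate",
    "aggregate_pairs",
    "apply_filters",
    "annotate_known",
    "extract_stratum",
    "build_total_sample",
    "read_reports",
    "read_reference",
    "write_pairs",
    "read_pairs",
]

logger = logging.getLogger(__name__)

#: names treated as missing after trimming + case folding
DEFAULT_SENTINELS = ("unknown", "")

ADR_DELIMITER = ";"


def split_multi_adr(
    raw_rows: Iterable[tuple[str, str, DrugType | str, Sequence[str] | str, bool | int]],
) -> list[ReportRecord]:
    """Expand rows whose ADR field lists several reactions into one record each.

    ``adr_list`` may be a sequence of names or a single ``;``-delimited string.
    Rows with an empty ADR list are rejected with a warning rather than an
    exception, matching how dirty SRS extracts are normally handled.
    """
    records: list[ReportRecord] = []
    for report_id, drug_name, drug_type, adr_list, serious in raw_rows:
        if isinstance(adr_list, str):
            adrs = [a for a in adr_list.split(ADR_DELIMITER)]
        else:
            adrs = list(adr_list)
        adrs = [a for a in adrs if str(a).strip() != ""]
        if not adrs:
            logger.warning("report %s rejected: empty ADR list", report_id)
            continue
        dtype = DrugType.coerce(drug_type)
        for adr in adrs:
            records.append(
                ReportRecord(
                    report_id=str(report_id),
                    drug_name=str(drug_name),
                    drug_type=dtype,
                    adr_name=str(adr),
                    serious=bool(int(serious)) if not isinstance(serious, bool) else serious,
                )
            )
    return records


def _is_sentinel(name: str, sentinels: Sequence[str]) -> bool:
    return name.strip().lower() in {s.strip().lower() for s in sentinels}


def filter_unknown(
    records: Iterable[ReportRecord],
    sentinels: Sequence[str] = DEFAULT_SENTINELS,
) -> list[ReportRecord]:
    """Drop records whose drug or ADR name is missing or a sentinel.

    Matching trims whitespace and ignores case, so ``"  Unknown "`` is dropped
    under the defaults.  Idempotent by construction.
    """
    return [
        r
        for r in records
        if not _is_sentinel(r.drug_name, sentinels)
        and not _is_sentinel(r.adr_name, sentinels)
    ]


def deduplicate(records: Iterable[ReportRecord]) -> list[ReportRecord]:
    """Strict mode: keep one record per (report_id, drug, ADR) triple.

    Off the default path — repeated mentions within one report are counted as
    distinct occurrences unless this is explicitly requested.
    """
    seen: set[tuple[str, str, str]] = set()
    out = []
    for r in records:
        key = (r.report_id, r.drug_name, r.adr_name)
        if key not in seen:
            seen.add(key)
            out.append(r)
    return out


def aggregate_pairs(records: Iterable[ReportRecord]) -> list[DrugAdrPair]:
    """Group records into (drug, ADR) pairs with occurrence counts.

    The sum of counts equals the number of input records.  The drug type of a
    pair is taken from its records (generic names are assumed to map to a
    single drug class; a conflict raises).
    """
    counts: dict[tuple[str, str], int] = {}
    dtypes: dict[tuple[str, str], DrugType] = {}
    for r in records:
        key = (r.drug_name, r.adr_name)
        counts[key] = counts.get(key, 0) + 1
        prev = dtypes.get(key)
        if prev is None:
            dtypes[key] = r.drug_type
        elif prev is not r.drug_type:
            raise ValueError(f"conflicting drug types for drug {r.drug_name!r}")
    return [
        DrugAdrPair(drug_name=d, drug_type=dtypes[(d, a)], adr_name=a, count=n)
        for (d, a), n in counts.items()
    ]


def apply_filters(
    pairs: Iterable[DrugAdrPair],
    refdb: ReferenceDB,
    min_count: int = 3,
) -> list[DrugAdrPair]:
    """Keep pairs with at least ``min_count`` occurrences whose drug is in the
    reference database.

    Both conditions are row-local so a single order-stable pass suffices.  A
    minimum case count of 3 is the conventional floor for disproportionality
    analysis; the reference restriction makes recall/precision evaluation
    meaningful.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    kept = [p for p in pairs if p.count >= min_count and p.drug_name in refdb.drugs]
    if not kept:
        logger.warning("apply_filters: no pairs survive filtering")
    return kept


def annotate_known(pairs: Iterable[DrugAdrPair], refdb: ReferenceDB) -> list[DrugAdrPair]:
    """Stamp each pair's ``known`` flag: 1 if the pair is in the reference
    database, 0 otherwise.  No pair is added or removed; idempotent."""
    out = []
    for p in pairs:
        p.known = p.key in refdb.pairs
        out.append(p)
    return out


def build_total_sample(
    records: Iterable[ReportRecord],
    refdb: ReferenceDB,
    min_count: int = 3,
    sentinels: Sequence[str] = DEFAULT_SENTINELS,
    strict_dedup: bool = False,
) -> Sample:
    """Run the full cleaning funnel on split records and return the total sample."""
    records = list(records)
    logger.info("ingest: %d split records", len(records))
    filtered = filter_unknown(records, sentinels)
    logger.info("ingest: %d records after sentinel filtering", len(filtered))
    if strict_dedup:
        filtered = deduplicate(filtered)
        logger.info("ingest: %d records after deduplication", len(filtered))
    pairs = aggregate_pairs(filtered)
    logger.info("ingest: %d aggregated pairs", len(pairs))
    pairs = apply_filters(pairs, refdb, min_count=min_count)
    logger.info("ingest: %d pairs after min-count/reference filters", len(pairs))
    pairs = annotate_known(pairs, refdb)
    pairs.sort(key=lambda p: p.key)
    n_serious = sum(1 for r in filtered if r.serious)
    logger.info(
        "ingest: %d serious records (%.2f%%)",
        n_serious,
        100.0 * n_serious / len(filtered) if filtered else 0.0,
    )
    return Sample(pairs=pairs, label="total", n_reports=len(filtered))


def extract_stratum(total: Sample, drug_type: DrugType | str) -> Sample:
    """Restrict the total sample to one drug class.

    The stratum's pair set is a subset of the total's; counts are unchanged
    (detection within the stratum later recomputes margins at stratum level).
    """
    dtype = DrugType.coerce(drug_type)
    pairs = [
        DrugAdrPair(p.drug_name, p.drug_type, p.adr_name, p.count, p.known)
        for p in total.pairs
        if p.drug_type is dtype
    ]
    return Sample(pairs=pairs, label="stratum", n_reports=sum(p.count for p in pairs))


# ---------------------------------------------------------------------------
# File formats: plain UTF-8 CSV with headers (drug names may be Chinese).
# ---------------------------------------------------------------------------

def read_reports(path: str | Path) -> list[ReportRecord]:
    """Read a reports CSV.

    Two layouts are accepted: pre-split rows with an ``adr_name`` column, or
    raw rows with a ``;``-delimited ``adr_names`` column, which are routed
    through :func:`split_multi_adr`.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    required = {"report_id", "drug_name", "drug_type", "serious"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if "adr_names" in df.columns:
        rows = [
            (r.report_id, r.drug_name, r.drug_type, r.adr_names, int(r.serious))
            for r in df.itertuples(index=False)
        ]
        return split_multi_adr(rows)
    if "adr_name" not in df.columns:
        raise ValueError(f"{path}: need an 'adr_name' or 'adr_names' column")
    return [
        ReportRecord(
            report_id=r.report_id,
            drug_name=r.drug_name,
            drug_type=DrugType.coerce(r.drug_type),
            adr_name=r.adr_name,
            serious=bool(int(r.serious)),
        )
        for r in df.itertuples(index=False)
    ]


def read_reference(path: str | Path) -> ReferenceDB:
    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    missing = {"drug_name", "adr_name"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return ReferenceDB(zip(df["drug_name"], df["adr_name"]))


def write_pairs(sample: Sample, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "drug_name": [p.drug_name for p in sample.pairs],
            "drug_type": [p.drug_type.value for p in sample.pairs],
            "adr_name": [p.adr_name for p in sample.pairs],
            "count": [p.count for p in sample.pairs],
            "known": [int(bool(p.known)) for p in sample.pairs],
        }
    )
    df.to_csv(path, index=False, encoding="utf-8")


def read_pairs(path: str | Path, label: str = "total") -> Sample:
    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    pairs = [
        DrugAdrPair(
            drug_name=r.drug_name,
            drug_type=DrugType.coerce(r.drug_type),
            adr_name=r.adr_name,
            count=int(r.count),
            known=bool(int(r.known)),
        )
        for r in df.itertuples(index=False)
    ]
    return Sample(pairs=pairs, label=label, n_reports=sum(p.count for p in pairs))
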