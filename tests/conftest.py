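from __future__ import annotations

import random

import pytest

from pvstrat.types import DrugAdrPair, DrugType, ReferenceDB, ReportRecord, Sample


def make_pair(drug, adr, count, dtype=DrugType.WESTERN, known=False):
    return DrugAdrPair(drug_name=drug, drug_type=dtype, adr_name=adr, count=count, known=known)


@pytest.fixture
def two_by_two_sample():
    """Four pairs over 2 drugs x 2 ADRs with counts 3,4,5,6."""
    pairs = [
        make_pair("d1", "e1", 3),
        make_pair("d1", "e2", 4),
        make_pair("d2", "e1", 5),
        make_pair("d2", "e2", 6),
    ]
    return Sample(pairs=pairs, label="total", n_reports=18)


@pytest.fixture
def toy_refdb():
    return ReferenceDB([("d1", "e1"), ("d1", "e3"), ("d2", "e2"), ("d9", "e9")])


def random_records(rng: random.Random, n: int, n_drugs=6, n_adrs=5,
                   sentinel_rate=0.1) -> list[ReportRecord]:
    """Small random record lists for oracle-equivalence checks."""
    records = []
    for i in range(n):
        drug = f"d{rng.randrange(n_drugs)}"
        adr = f"e{rng.randrange(n_adrs)}"
        if rng.random() < sentinel_rate:
            drug = rng.choice(["unknown", " Unknown ", ""])
        if rng.random() < sentinel_rate:
            adr = rng.choice(["unknown", ""])
        records.append(
            ReportRecord(
                report_id=f"r{i}",
                drug_name=drug,
                drug_type=DrugType.TCM if drug in ("d0", "d1") else DrugType.WESTERN,
                adr_name=adr,
                serious=rng.random() < 0.1,
            )
        )
    return records
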