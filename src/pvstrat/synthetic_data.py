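"""Synthetic spontaneous-reporting system with controlled ground truth.

Real national SRS data are not redistributable, so every pipeline stage is
exercised on simulated reports instead.  The generator emulates the gross
shape of such a database at toy scale:

* drugs belong to one of three classes (TCM / western / biological) with a
  class-specific drug count;
* report frequencies over drugs and ADRs are Zipf-skewed (a handful of
  popular terms carries most of the mass, as the top-ten ADR share of real
  data shows);
* a configurable fraction of reports links one drug to several ADRs and is
  later split into one-drug-one-ADR records;
* the stratum (TCM) draws its ADRs from a profile shifted away from the
  background, controlled by ``stratum_profile_shift`` (0 = identical);
* selected (drug, ADR) pairs are planted with a relative risk > 1 so that
  detection has a known optimum;
* a reference database of known pairs is sampled so that every drug owns at
  least one known pair, with planted signals included at a configurable rate.

All randomness flows from ``numpy.random.default_rng`` seeded from a single
integer; two calls with the same config are identical.

The module also ships the published fourfold cell counts of the worked
example (three methods over a 4697-pair stratum universe with 830 known
pairs) as frozen fixtures, so the evaluation and decision stages can be
checked against printed values without any large data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .reference_eval import FourfoldComparison
from .signal_detection import Method
from .types import DrugType, ReferenceDB

__all__ = [
    "SimConfig",
    "PaperFixture",
    "drug_names",
    "adr_names",
    "generate_reference",
    "generate_reports",
    "simulate",
    "write_reports",
    "write_reference",
    "paper_fixtures",
]


@dataclass(frozen=True)
class SimConfig:
    """Shape parameters of the simulated reporting system.

    Defaults describe a desk-scale system: ~100 drugs, 40 ADR terms, 20k
    reports, a third of them multi-ADR, Zipf exponent 1.0 (top-10 ADRs carry
    roughly 60% of split records), 5% serious reports.
    """

    n_drugs: dict[str, int] = field(
        default_factory=lambda: {"TCM": 30, "western": 60, "biological": 10}
    )
    n_adrs: int = 40
    n_reports: int = 20_000
    multi_adr_fraction: float = 0.334
    zipf_exponent: float = 1.0
    known_pair_fraction: float = 0.12
    signal_pairs: tuple[tuple[str, str, float], ...] = ()
    signal_known_fraction: float = 0.8
    stratum_profile_shift: float = 0.5
    serious_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("multi_adr_fraction", "known_pair_fraction",
                     "signal_known_fraction", "stratum_profile_shift",
                     "serious_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for _, _, rr in self.signal_pairs:
            if rr < 1.0:
                raise ValueError("planted relative risks must be >= 1")


def drug_names(config: SimConfig) -> list[tuple[str, DrugType]]:
    """Deterministic drug roster; index order is popularity order."""
    out: list[tuple[str, DrugType]] = []
    for dtype in DrugType:
        for i in range(config.n_drugs.get(dtype.value, 0)):
            out.append((f"{dtype.value}_drug_{i:03d}", dtype))
    return out


def adr_names(config: SimConfig) -> list[str]:
    """Deterministic ADR vocabulary; index order is popularity order."""
    return [f"adr_{j:03d}" for j in range(config.n_adrs)]


def _zipf_weights(n: int, s: float) -> np.ndarray:
    w = np.arange(1, n + 1, dtype=float) ** (-s)
    return w / w.sum()


def _adr_profiles(config: SimConfig) -> dict[DrugType, np.ndarray]:
    """Per-class ADR draw probabilities.

    The stratum (TCM) profile is a mixture of the background profile and a
    rotated copy of it; at shift 1 the popular background ADRs become rare in
    the stratum, at shift 0 the profiles coincide.
    """
    base = _zipf_weights(config.n_adrs, config.zipf_exponent)
    rolled = np.roll(base, config.n_adrs // 3)
    shift = config.stratum_profile_shift
    tcm = (1.0 - shift) * base + shift * rolled
    return {
        DrugType.TCM: tcm / tcm.sum(),
        DrugType.WESTERN: base,
        DrugType.BIOLOGICAL: base,
    }


def generate_reference(config: SimConfig) -> ReferenceDB:
    """Sample the known-pair reference database.

    Per drug, the number of known ADRs is Binomial(n_adrs, known_pair_fraction)
    clamped to at least one, drawn without replacement with popularity
    weighting.  Planted signal pairs join the reference independently with
    probability ``signal_known_fraction`` (so precision/recall of a detection
    run have a known optimum).
    """
    rng = np.random.default_rng([config.seed, 1])
    drugs = drug_names(config)
    adrs = adr_names(config)
    weights = _zipf_weights(config.n_adrs, config.zipf_exponent)
    pairs: set[tuple[str, str]] = set()
    for name, _dtype in drugs:
        k = int(rng.binomial(config.n_adrs, config.known_pair_fraction))
        k = max(1, k) if config.known_pair_fraction > 0 else 0
        if k:
            chosen = rng.choice(config.n_adrs, size=k, replace=False, p=weights)
            pairs.update((name, adrs[j]) for j in chosen)
    for drug, adr, _rr in config.signal_pairs:
        if rng.random() < config.signal_known_fraction:
            pairs.add((drug, adr))
    return ReferenceDB(pairs)


def generate_reports(
    config: SimConfig,
) -> list[tuple[str, str, str, list[str], int]]:
    """Draw raw report rows ``(report_id, drug, drug_type, adr_list, serious)``.

    Each report picks one drug from the Zipf-weighted roster; with probability
    ``multi_adr_fraction`` it lists 2-4 ADRs (60/30/10 mix), otherwise one.
    ADRs are drawn without replacement from the drug class profile; for drugs
    carrying planted signals, the planted ADRs' probabilities are multiplied
    by their relative risk and renormalised.
    """
    rng = np.random.default_rng([config.seed, 2])
    drugs = drug_names(config)
    adrs = adr_names(config)
    adr_index = {a: j for j, a in enumerate(adrs)}
    profiles = _adr_profiles(config)

    boosts: dict[str, dict[int, float]] = {}
    for drug, adr, rr in config.signal_pairs:
        boosts.setdefault(drug, {})[adr_index[adr]] = rr

    per_drug_profile: dict[str, np.ndarray] = {}
    for name, dtype in drugs:
        p = profiles[dtype]
        if name in boosts:
            p = p.copy()
            for j, rr in boosts[name].items():
                p[j] *= rr
            p = p / p.sum()
        per_drug_profile[name] = p

    drug_w = _zipf_weights(len(drugs), config.zipf_exponent)
    drug_idx = rng.choice(len(drugs), size=config.n_reports, p=drug_w)
    multi = rng.random(config.n_reports) < config.multi_adr_fraction
    extra = rng.choice([2, 3, 4], size=config.n_reports, p=[0.6, 0.3, 0.1])
    serious = rng.random(config.n_reports) < config.serious_fraction

    rows: list[tuple[str, str, str, list[str], int]] = []
    for i in range(config.n_reports):
        name, dtype = drugs[drug_idx[i]]
        k = int(extra[i]) if multi[i] else 1
        chosen = rng.choice(config.n_adrs, size=k, replace=False, p=per_drug_profile[name])
        rows.append(
            (
                f"R{i:07d}",
                name,
                dtype.value,
                [adrs[j] for j in chosen],
                int(serious[i]),
            )
        )
    return rows


def simulate(config: SimConfig) -> tuple[list[tuple[str, str, str, list[str], int]], ReferenceDB]:
    """Reports plus matching reference database from one seed."""
    return generate_reports(config), generate_reference(config)


def write_reports(rows, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "report_id": [r[0] for r in rows],
            "drug_name": [r[1] for r in rows],
            "drug_type": [r[2] for r in rows],
            "adr_names": [";".join(r[3]) for r in rows],
            "serious": [r[4] for r in rows],
        }
    )
    df.to_csv(path, index=False, encoding="utf-8")


def write_reference(refdb: ReferenceDB, path: str | Path) -> None:
    pairs = sorted(refdb.pairs)
    pd.DataFrame(
        {"drug_name": [d for d, _ in pairs], "adr_name": [a for _, a in pairs]}
    ).to_csv(path, index=False, encoding="utf-8")


@dataclass(frozen=True)
class PaperFixture:
    """Published fourfold cell counts of the worked example for one method."""

    method: Method
    fourfold: FourfoldComparison


# Worked-example fourfold cells: three detection methods compared over a
# 4697-pair stratum universe containing 830 reference-known pairs.
_FIXTURE_CELLS: dict[Method, dict[str, int]] = {
    Method.PRR: dict(a=1888, a1=561, b=330, b1=40, c=321, c1=34, d=2158, d1=195),
    Method.MHRA: dict(a=1488, a1=456, b=348, b1=56, c=332, c1=48, d=2529, d1=270),
    Method.IC: dict(a=579, a1=274, b=173, b1=43, c=81, c1=31, d=3864, d1=482),
}


def paper_fixtures() -> list[PaperFixture]:
    """The three frozen worked-example fixtures (PRR, MHRA, IC)."""
    return [
        PaperFixture(method, FourfoldComparison.from_cells(**cells))
        for method, cells in _FIXTURE_CELLS.items()
    ]
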