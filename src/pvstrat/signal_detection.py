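"""Disproportionality analysis on aggregated (drug, ADR) pairs.

For each target pair within a sample the 2x2 contingency table is

    =============  ===========  ==========
                   target ADR   other ADRs
    =============  ===========  ==========
    target drug    a            b
    other drugs    c            d
    =============  ===========  ==========

and four standard signal criteria are evaluated:

PRR
    proportional reporting ratio (a/(a+b)) / (c/(c+d)); signal when
    a >= 3, PRR >= 2 and Pearson chi-square >= 4.
ROR
    reporting odds ratio ad/bc; signal when a >= 3 and the lower bound of the
    95% CI of ln(ROR), exponentiated, exceeds 1.
MHRA
    the UK regulator's composite rule; identical sub-criteria to PRR by
    default (kept as a distinct method so the two configurations can diverge).
IC
    Bayesian information component.  The point estimate is the shrinkage
    observed/expected log-ratio log2((a + 0.5) / (E + 0.5)) with
    E = (a+b)(a+c)/N; the credible bound is IC - 2*SD with SD from the
    classic BCPNN closed-form variance approximation.  Signal when the bound
    is positive.

All thresholds live in :class:`DetectionConfig` and can be changed per run.
Statistics on degenerate tables (zero margins) come back as inf/NaN and never
signal; an optional Haldane +0.5 continuity correction exists for ROR and IC.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from .types import Sample

__all__ = [
    "Method",
    "ContingencyTable",
    "SignalResult",
    "DetectionRun",
    "DetectionConfig",
    "contingency",
    "chi_square",
    "prr",
    "ror",
    "mhra",
    "ic",
    "ic_raw",
    "detect",
    "method_correlation",
    "write_signals",
]


class Method(str, Enum):
    PRR = "PRR"
    ROR = "ROR"
    MHRA = "MHRA"
    IC = "IC"


@dataclass(frozen=True)
class ContingencyTable:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class SignalResult:
    method: Method
    table: ContingencyTable
    signal: bool
    statistic: float | None = None
    chi2: float | None = None
    interval_low: float | None = None
    drug_name: str = ""
    adr_name: str = ""


@dataclass
class DetectionRun:
    sample_label: str
    method: Method
    results: list[SignalResult]

    @property
    def positives(self) -> frozenset[tuple[str, str]]:
        return frozenset(
            (r.drug_name, r.adr_name) for r in self.results if r.signal
        )

    @property
    def universe(self) -> frozenset[tuple[str, str]]:
        return frozenset((r.drug_name, r.adr_name) for r in self.results)


@dataclass(frozen=True)
class DetectionConfig:
    """Criterion parameters for the four methods (standard published defaults)."""

    min_count: int = 3              # minimum a for PRR/ROR/MHRA
    prr_threshold: float = 2.0
    chi2_threshold: float = 4.0
    ror_ci_z: float = 1.96          # 95% two-sided normal quantile
    ic_interval_multiplier: float = 2.0
    continuity_correction: bool = False  # Haldane +0.5 on all cells (ROR, IC)
    yates: bool = False


DEFAULT_CONFIG = DetectionConfig()


def contingency(pair: tuple[str, str], sample: Sample) -> ContingencyTable:
    """Build the 2x2 table for one pair, with all margins computed within
    the given sample only (stratum detection is done at stratum level)."""
    drug_margin, adr_margin, total = sample.margins()
    index = sample.by_key()
    if pair not in index:
        raise KeyError(f"pair {pair} not present in sample {sample.label!r}")
    a = index[pair].count
    drug, adr = pair
    b = drug_margin[drug] - a
    c = adr_margin[adr] - a
    d = total - a - b - c
    return ContingencyTable(a, b, c, d)


def chi_square(t: ContingencyTable, yates: bool = False) -> float:
    """Pearson chi-square N(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)).

    With Yates' correction |ad-bc| is reduced by N/2 (floored at 0) before
    squaring.  Any zero margin makes the statistic undefined (NaN).
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    n = t.n
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return math.nan
    diff = abs(a * d - b * c)
    if yates:
        diff = max(0.0, diff - n / 2.0)
    return n * diff * diff / denom


def _corrected(t: ContingencyTable, config: DetectionConfig) -> tuple[float, float, float, float]:
    if config.continuity_correction:
        return (t.a + 0.5, t.b + 0.5, t.c + 0.5, t.d + 0.5)
    return (float(t.a), float(t.b), float(t.c), float(t.d))


def prr(t: ContingencyTable, config: DetectionConfig = DEFAULT_CONFIG) -> SignalResult:
    """Proportional reporting ratio with the {a>=3, PRR>=2, chi2>=4} rule."""
    a, b, c, d = t.a, t.b, t.c, t.d
    if a + b == 0 or c + d == 0:
        stat = math.nan
    elif c == 0:
        stat = math.inf if a > 0 else math.nan
    else:
        stat = (a / (a + b)) / (c / (c + d))
    x2 = chi_square(t, yates=config.yates)
    signal = (
        a >= config.min_count
        and not math.isnan(stat)
        and stat >= config.prr_threshold
        and not math.isnan(x2)
        and x2 >= config.chi2_threshold
    )
    return SignalResult(Method.PRR, t, signal, statistic=stat, chi2=x2)


def ror(t: ContingencyTable, config: DetectionConfig = DEFAULT_CONFIG) -> SignalResult:
    """Reporting odds ratio with the 95% CI lower-bound rule."""
    a, b, c, d = _corrected(t, config)
    if b * c == 0:
        stat = math.inf if a * d > 0 else math.nan
        low = math.nan
    else:
        stat = (a * d) / (b * c)
        if min(a, b, c, d) > 0:
            se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
            low = math.exp(math.log(stat) - config.ror_ci_z * se)
        else:
            low = math.nan
    signal = t.a >= config.min_count and not math.isnan(low) and low > 1.0
    return SignalResult(Method.ROR, t, signal, statistic=stat, interval_low=low)


def mhra(t: ContingencyTable, config: DetectionConfig = DEFAULT_CONFIG) -> SignalResult:
    """MHRA composite criterion: a >= 3, PRR >= 2 and chi-square >= 4.

    Criterion-only method — no signal score is reported.
    """
    base = prr(t, config)
    return SignalResult(Method.MHRA, t, base.signal, chi2=base.chi2)


def ic_raw(t: ContingencyTable) -> float:
    """Unshrunk information component log2(a*N / ((a+b)(a+c)))."""
    a, b, c = t.a, t.b, t.c
    n = t.n
    expected = (a + b) * (a + c) / n if n else math.nan
    if expected == 0 or a == 0:
        return math.nan
    return math.log2(a / expected)


def _bcpnn_sd(t: ContingencyTable) -> float:
    """Closed-form BCPNN posterior SD of the IC (standard priors
    alpha1 = beta1 = 1, alpha = beta = 2, gamma11 = 1)."""
    a, n = t.a, t.n
    row = t.a + t.b
    col = t.a + t.c
    gamma = (n + 2.0) ** 2 / ((row + 1.0) * (col + 1.0))
    var = (
        (n - a + gamma - 1.0) / ((a + 1.0) * (1.0 + n + gamma))
        + (n - row + 1.0) / ((row + 1.0) * (3.0 + n))
        + (n - col + 1.0) / ((col + 1.0) * (3.0 + n))
    ) / (math.log(2.0) ** 2)
    return math.sqrt(var)


def ic(t: ContingencyTable, config: DetectionConfig = DEFAULT_CONFIG) -> SignalResult:
    """Shrinkage information component with a two-SD lower credible bound.

    IC = log2((a + 0.5) / (E + 0.5)), E = (a+b)(a+c)/N.  The +0.5 shrinkage
    pulls small-count pairs toward independence (IC = 0).
    """
    if t.n == 0:
        raise ValueError("IC undefined on an empty sample")
    a, b, c, d = _corrected(t, config) if config.continuity_correction else (
        float(t.a), float(t.b), float(t.c), float(t.d)
    )
    n = a + b + c + d
    expected = (a + b) * (a + c) / n
    stat = math.log2((a + 0.5) / (expected + 0.5))
    sd = _bcpnn_sd(t)
    low = stat - config.ic_interval_multiplier * sd
    return SignalResult(Method.IC, t, low > 0.0, statistic=stat, interval_low=low)


_DISPATCH = {Method.PRR: prr, Method.ROR: ror, Method.MHRA: mhra, Method.IC: ic}


def detect(
    sample: Sample,
    method: Method | str,
    config: DetectionConfig = DEFAULT_CONFIG,
) -> DetectionRun:
    """Evaluate one method on every pair of a sample."""
    method = Method(method)
    if not sample.pairs:
        raise ValueError("cannot run detection on an empty sample")
    evaluate = _DISPATCH[method]
    drug_margin, adr_margin, total = sample.margins()
    results: list[SignalResult] = []
    for p in sorted(sample.pairs, key=lambda q: q.key):
        a = p.count
        b = drug_margin[p.drug_name] - a
        c = adr_margin[p.adr_name] - a
        d = total - a - b - c
        t = ContingencyTable(a, b, c, d)
        r = evaluate(t, config)
        results.append(
            SignalResult(
                method=r.method,
                table=t,
                signal=r.signal,
                statistic=r.statistic,
                chi2=r.chi2,
                interval_low=r.interval_low,
                drug_name=p.drug_name,
                adr_name=p.adr_name,
            )
        )
    return DetectionRun(sample_label=sample.label, method=method, results=results)


def method_correlation(run_a: DetectionRun, run_b: DetectionRun) -> float:
    """Pearson (phi) correlation of two runs' 0/1 signal vectors.

    Both runs must cover the same pair universe; vectors are ordered by the
    sorted shared pair list.  A constant vector has no defined correlation:
    NaN is returned with a warning.
    """
    if run_a.universe != run_b.universe:
        raise ValueError("detection runs cover different pair universes")
    order = sorted(run_a.universe)
    pa, pb = run_a.positives, run_b.positives
    x = np.array([1 if k in pa else 0 for k in order], dtype=float)
    y = np.array([1 if k in pb else 0 for k in order], dtype=float)
    if x.std() == 0 or y.std() == 0:
        warnings.warn("constant signal vector: correlation undefined", stacklevel=2)
        return math.nan
    return float(np.corrcoef(x, y)[0, 1])


def write_signals(runs: list[DetectionRun], path: str | Path) -> None:
    rows = []
    for run in runs:
        for r in run.results:
            rows.append(
                {
                    "method": run.method.value,
                    "drug_name": r.drug_name,
                    "adr_name": r.adr_name,
                    "a": r.table.a,
                    "b": r.table.b,
                    "c": r.table.c,
                    "d": r.table.d,
                    "statistic": "" if r.statistic is None else repr(r.statistic),
                    "chi2": "" if r.chi2 is None else repr(r.chi2),
                    "interval_low": "" if r.interval_low is None else repr(r.interval_low),
                    "signal": 1 if r.signal else 0,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False, encoding="utf-8")
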