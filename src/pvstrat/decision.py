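"""Threshold derivation and the stratification decision tree.

Whether a drug-class stratum should be analysed separately is decided by
walking three indicators in fixed order — recall (R), precision (P),
discrepancy (D) — each against an integer-percent threshold:

1. If R1 - R2 > Rt the pooled run covers clearly more known signals: do not
   separate.  If R2 - R1 > Rt the stratum run does: separate.  Otherwise fall
   through.
2. Same comparison on P1/P2 against Pt.
3. If D > Dt the verdict is non-separation, otherwise separation.

Comparisons are strict; ties fall through.  The D branch is implemented
exactly as stated even though its direction (large disagreement leading to
non-separation) can be argued either way; ``d_branch_inverted`` flips it for
sensitivity analysis.

Thresholds are derived from the per-method indicator differences: the mean
absolute difference (in percent) is raised to the next strictly larger
integer percent.  Branch differences are computed on the two-decimal rounded
percent values — the display convention the decision table itself uses — so
the recorded paths match the rendered table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from fractions import Fraction
from pathlib import Path

from .reference_eval import IndicatorSet, round_half_up
from .signal_detection import Method

__all__ = [
    "Verdict",
    "ThresholdSet",
    "BranchRecord",
    "DecisionOutcome",
    "DecisionReport",
    "derive_thresholds",
    "decide",
    "decide_all",
    "write_decision_report",
]


class Verdict(str, Enum):
    SEPARATION = "separation"
    NON_SEPARATION = "non_separation"


@dataclass(frozen=True)
class ThresholdSet:
    """Indicator thresholds as proportions (Rt = Fraction(2, 100) is '2%')."""

    rt: Fraction
    pt: Fraction
    dt: Fraction

    def __post_init__(self) -> None:
        if min(self.rt, self.pt, self.dt) <= 0:
            raise ValueError("thresholds must be positive")

    def as_percent_dict(self) -> dict[str, float]:
        return {"Rt": float(self.rt * 100), "Pt": float(self.pt * 100), "Dt": float(self.dt * 100)}


@dataclass(frozen=True)
class BranchRecord:
    """One visited node of the tree: the difference examined and where it led."""

    indicator: str          # "R", "P" or "D"
    difference: float       # percent, display-rounded
    threshold: float        # percent
    branch: str             # "separation" | "non_separation" | "fall_through"


@dataclass(frozen=True)
class DecisionOutcome:
    method: Method
    verdict: Verdict
    path: tuple[BranchRecord, ...]
    thresholds: ThresholdSet


@dataclass(frozen=True)
class DecisionReport:
    outcomes: tuple[DecisionOutcome, ...]
    thresholds: ThresholdSet
    consensus: str          # "separation" | "non_separation" | "split"
    tally: dict[str, int]


def _pct2(x: Fraction) -> Fraction:
    """Percent value rounded half-up at 2 decimals, kept exact."""
    return round_half_up(x * 100, 2)


def _next_integer_percent(mean_pct: Fraction) -> Fraction:
    """Smallest integer percent strictly greater than the mean."""
    return Fraction(mean_pct.numerator // mean_pct.denominator + 1)


def derive_thresholds(indicator_sets: list[IndicatorSet]) -> ThresholdSet:
    """Set each threshold to an integer percent slightly larger than the mean
    per-method difference (|R1-R2| for Rt, |P1-P2| for Pt, D itself for Dt).

    A mean that already sits on an integer percent still moves up by one, so
    the strict comparisons in :func:`decide` can never fire exactly at the
    mean.
    """
    if not indicator_sets:
        raise ValueError("at least one indicator set is required")
    n = len(indicator_sets)
    r_mean = sum(abs(_pct2(s.r1) - _pct2(s.r2)) for s in indicator_sets) / n
    p_mean = sum(abs(_pct2(s.p1) - _pct2(s.p2)) for s in indicator_sets) / n
    d_mean = sum(_pct2(s.d) for s in indicator_sets) / n
    return ThresholdSet(
        rt=_next_integer_percent(r_mean) / 100,
        pt=_next_integer_percent(p_mean) / 100,
        dt=_next_integer_percent(d_mean) / 100,
    )


def decide(
    ind: IndicatorSet,
    th: ThresholdSet,
    d_branch_inverted: bool = False,
) -> DecisionOutcome:
    """Walk the decision tree for one method's indicators.

    Total function: every finite indicator set reaches a verdict, and the
    recorded path is the prefix of branches actually visited.
    """
    path: list[BranchRecord] = []

    def record(indicator: str, diff: Fraction, thr: Fraction, branch: str) -> None:
        path.append(BranchRecord(indicator, float(diff), float(thr * 100), branch))

    r_diff = _pct2(ind.r1) - _pct2(ind.r2)
    if r_diff > th.rt * 100:
        record("R", r_diff, th.rt, Verdict.NON_SEPARATION.value)
        return DecisionOutcome(ind.method, Verdict.NON_SEPARATION, tuple(path), th)
    if -r_diff > th.rt * 100:
        record("R", r_diff, th.rt, Verdict.SEPARATION.value)
        return DecisionOutcome(ind.method, Verdict.SEPARATION, tuple(path), th)
    record("R", r_diff, th.rt, "fall_through")

    p_diff = _pct2(ind.p1) - _pct2(ind.p2)
    if p_diff > th.pt * 100:
        record("P", p_diff, th.pt, Verdict.NON_SEPARATION.value)
        return DecisionOutcome(ind.method, Verdict.NON_SEPARATION, tuple(path), th)
    if -p_diff > th.pt * 100:
        record("P", p_diff, th.pt, Verdict.SEPARATION.value)
        return DecisionOutcome(ind.method, Verdict.SEPARATION, tuple(path), th)
    record("P", p_diff, th.pt, "fall_through")

    d_val = _pct2(ind.d)
    exceeded = d_val > th.dt * 100
    if d_branch_inverted:
        verdict = Verdict.NON_SEPARATION if not exceeded else Verdict.SEPARATION
    else:
        verdict = Verdict.NON_SEPARATION if exceeded else Verdict.SEPARATION
    record("D", d_val, th.dt, verdict.value)
    return DecisionOutcome(ind.method, verdict, tuple(path), th)


def decide_all(
    sets: list[IndicatorSet],
    th: ThresholdSet | None = None,
    d_branch_inverted: bool = False,
) -> DecisionReport:
    """Per-method verdicts plus a consensus.

    With ``th=None`` thresholds are derived from the same indicator sets being
    judged (the self-calibrating mode; see the methods note on its
    circularity).  Consensus is the unanimous verdict, or ``"split"``.
    """
    if not sets:
        raise ValueError("at least one indicator set is required")
    thresholds = th if th is not None else derive_thresholds(sets)
    outcomes = tuple(decide(s, thresholds, d_branch_inverted) for s in sets)
    tally = {v.value: 0 for v in Verdict}
    for o in outcomes:
        tally[o.verdict.value] += 1
    verdicts = {o.verdict for o in outcomes}
    consensus = verdicts.pop().value if len(verdicts) == 1 else "split"
    return DecisionReport(outcomes, thresholds, consensus, tally)


def write_decision_report(report: DecisionReport, path: str | Path) -> None:
    payload = {
        "thresholds": report.thresholds.as_percent_dict(),
        "consensus": report.consensus,
        "tally": report.tally,
        "methods": {
            o.method.value: {
                "verdict": o.verdict.value,
                "path": [
                    {
                        "indicator": b.indicator,
                        "difference_pct": b.difference,
                        "threshold_pct": b.threshold,
                        "branch": b.branch,
                    }
                    for b in o.path
                ],
            }
            for o in report.outcomes
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def render_decision(report: DecisionReport) -> str:
    lines = [
        "thresholds: Rt={Rt:.0f}% Pt={Pt:.0f}% Dt={Dt:.0f}%".format(
            **report.thresholds.as_percent_dict()
        )
    ]
    for o in report.outcomes:
        steps = "; ".join(
            f"{b.indicator}: {b.difference:+.2f}% vs {b.threshold:.0f}% -> {b.branch}"
            for b in o.path
        )
        lines.append(f"{o.method.value}: {o.verdict.value}  ({steps})")
    lines.append(f"consensus: {report.consensus}")
    return "\n".join(lines)
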