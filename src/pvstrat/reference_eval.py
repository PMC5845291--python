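"""Compare pooled and stratum detection runs against the reference standard.

The two binary detection outcomes over a shared pair universe (the stratum's
pair set) cross-tabulate into a fourfold table

    ==============  ============  ============
                    stratum +     stratum -
    ==============  ============  ============
    total sample +  a (a1, a0)    b (b1, b0)
    total sample -  c (c1, c0)    d (d1, d0)
    ==============  ============  ============

where each cell splits into reference-known (suffix 1) and unknown (suffix 0)
pairs.  Three indicators summarise the table:

    R1 = (a1+b1)/K,  R2 = (a1+c1)/K          recall of known signals, K = a1+b1+c1+d1
    P1 = (a1+b1)/(a+b),  P2 = (a1+c1)/(a+c)  precision of the positive calls
    D  = |b1-c1| / (b+c)                     known-signal discrepancy between runs

All arithmetic is exact (integer/`fractions.Fraction`); percentages are
rendered half-up at two decimals only for display.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import pandas as pd

from .signal_detection import DetectionRun, Method
from .types import Sample

__all__ = [
    "FourfoldComparison",
    "IndicatorSet",
    "build_fourfold",
    "recall",
    "precision",
    "discrepancy",
    "indicators",
    "round_half_up",
    "percent",
    "percent_str",
    "write_fourfold",
    "write_indicators",
    "read_indicators",
]


def round_half_up(x: Fraction, ndigits: int = 2) -> Fraction:
    """Round an exact rational half-up (half away from zero) at ``ndigits``."""
    q = 10**ndigits
    scaled = x * q
    n, d = scaled.numerator, scaled.denominator
    if n >= 0:
        r = (2 * n + d) // (2 * d)
    else:
        r = -((2 * -n + d) // (2 * d))
    return Fraction(r, q)


def percent(x: Fraction, ndigits: int = 2) -> float:
    """Proportion -> percent, rounded half-up at ``ndigits`` decimals."""
    return float(round_half_up(x * 100, ndigits))


def percent_str(x: Fraction, ndigits: int = 2) -> str:
    return f"{percent(x, ndigits):.{ndigits}f}%"


@dataclass(frozen=True)
class FourfoldComparison:
    """The twelve cells of the fourfold table (known/unknown split per cell)."""

    a1: int
    a0: int
    b1: int
    b0: int
    c1: int
    c0: int
    d1: int
    d0: int

    def __post_init__(self) -> None:
        cells = (self.a1, self.a0, self.b1, self.b0, self.c1, self.c0, self.d1, self.d0)
        if min(cells) < 0:
            raise ValueError("fourfold cells must be non-negative")

    @property
    def a(self) -> int:
        return self.a1 + self.a0

    @property
    def b(self) -> int:
        return self.b1 + self.b0

    @property
    def c(self) -> int:
        return self.c1 + self.c0

    @property
    def d(self) -> int:
        return self.d1 + self.d0

    @property
    def universe_size(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def known_total(self) -> int:
        return self.a1 + self.b1 + self.c1 + self.d1

    @classmethod
    def from_cells(cls, *, a, a1, b, b1, c, c1, d, d1) -> "FourfoldComparison":
        """Build from cell totals plus known counts, validating a = a1 + a0 etc."""
        for name, total, known in (("a", a, a1), ("b", b, b1), ("c", c, c1), ("d", d, d1)):
            if known > total:
                raise ValueError(f"cell {name}: known count {known} exceeds total {total}")
        return cls(a1, a - a1, b1, b - b1, c1, c - c1, d1, d - d1)

    def swapped(self) -> "FourfoldComparison":
        """Exchange the roles of the two runs (b <-> c)."""
        return FourfoldComparison(
            self.a1, self.a0, self.c1, self.c0, self.b1, self.b0, self.d1, self.d0
        )


def build_fourfold(
    total_run: DetectionRun,
    sub_run: DetectionRun,
    universe: Sample,
) -> FourfoldComparison:
    """Cross-tabulate two runs over the stratum's pair universe.

    The comparison universe is the stratum sample: the total-sample run's
    positives are intersected with it (positives outside the stratum cannot
    appear in the stratum run and are not part of the comparison).
    """
    keys = universe.keys
    if sub_run.universe != frozenset(keys):
        raise ValueError("stratum run universe does not match the comparison universe")
    if not frozenset(keys) <= total_run.universe:
        raise ValueError("total-sample run does not cover the comparison universe")
    known = {p.key: bool(p.known) for p in universe.pairs}
    tp = total_run.positives & keys
    sp = sub_run.positives
    cells = dict(a1=0, a0=0, b1=0, b0=0, c1=0, c0=0, d1=0, d0=0)
    for k in keys:
        in_t, in_s = k in tp, k in sp
        cell = "a" if (in_t and in_s) else "b" if in_t else "c" if in_s else "d"
        cells[cell + ("1" if known[k] else "0")] += 1
    return FourfoldComparison(**cells)


def recall(f: FourfoldComparison, which: str = "total") -> Fraction:
    """Fraction of reference-known pairs recovered by one run (R1 or R2)."""
    k = f.known_total
    if k == 0:
        raise ZeroDivisionError("recall undefined: no known pairs in the universe")
    if which == "total":
        return Fraction(f.a1 + f.b1, k)
    if which == "sub":
        return Fraction(f.a1 + f.c1, k)
    raise ValueError(f"which must be 'total' or 'sub', got {which!r}")


def precision(f: FourfoldComparison, which: str = "total") -> Fraction:
    """Fraction of one run's positive calls that are reference-known (P1 or P2)."""
    if which == "total":
        if f.a + f.b == 0:
            raise ZeroDivisionError("precision undefined: no positives in the total-sample run")
        return Fraction(f.a1 + f.b1, f.a + f.b)
    if which == "sub":
        if f.a + f.c == 0:
            raise ZeroDivisionError("precision undefined: no positives in the stratum run")
        return Fraction(f.a1 + f.c1, f.a + f.c)
    raise ValueError(f"which must be 'total' or 'sub', got {which!r}")


def discrepancy(f: FourfoldComparison) -> Fraction:
    """Known-signal disagreement |b1 - c1| relative to all disagreement b + c.

    With no disagreement at all (b + c = 0) there is no diversity to measure;
    the ratio is defined as 0 with a warning.
    """
    if f.b + f.c == 0:
        warnings.warn("no disagreement between runs: discrepancy defined as 0", stacklevel=2)
        return Fraction(0)
    return Fraction(abs(f.b1 - f.c1), f.b + f.c)


@dataclass(frozen=True)
class IndicatorSet:
    """Exact R/P/D indicators for one detection method."""

    method: Method
    r1: Fraction
    r2: Fraction
    p1: Fraction
    p2: Fraction
    d: Fraction

    def as_percent_dict(self, ndigits: int = 2) -> dict[str, float]:
        return {
            "R1": percent(self.r1, ndigits),
            "R2": percent(self.r2, ndigits),
            "P1": percent(self.p1, ndigits),
            "P2": percent(self.p2, ndigits),
            "D": percent(self.d, ndigits),
        }


def indicators(f: FourfoldComparison, method: Method | str) -> IndicatorSet:
    """All five indicators from one fourfold table."""
    return IndicatorSet(
        method=Method(method),
        r1=recall(f, "total"),
        r2=recall(f, "sub"),
        p1=precision(f, "total"),
        p2=precision(f, "sub"),
        d=discrepancy(f),
    )


def write_fourfold(f: FourfoldComparison, method: Method | str, path: str | Path) -> None:
    payload = {
        "method": Method(method).value,
        "a": f.a, "a1": f.a1, "a0": f.a0,
        "b": f.b, "b1": f.b1, "b0": f.b0,
        "c": f.c, "c1": f.c1, "c0": f.c0,
        "d": f.d, "d1": f.d1, "d0": f.d0,
        "universe_size": f.universe_size,
        "known_total": f.known_total,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def write_indicators(sets: list[IndicatorSet], path: str | Path) -> None:
    """Raw proportions as CSV (full float precision; exact values live upstream)."""
    df = pd.DataFrame(
        {
            "method": [s.method.value for s in sets],
            "R1": [repr(float(s.r1)) for s in sets],
            "R2": [repr(float(s.r2)) for s in sets],
            "P1": [repr(float(s.p1)) for s in sets],
            "P2": [repr(float(s.p2)) for s in sets],
            "D": [repr(float(s.d)) for s in sets],
        }
    )
    df.to_csv(path, index=False, encoding="utf-8")


def read_indicators(path: str | Path) -> list[IndicatorSet]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    return [
        IndicatorSet(
            method=Method(r.method),
            r1=Fraction(r.R1),
            r2=Fraction(r.R2),
            p1=Fraction(r.P1),
            p2=Fraction(r.P2),
            d=Fraction(r.D),
        )
        for r in df.itertuples(index=False)
    ]


def render_report(sets: list[IndicatorSet]) -> str:
    """Human-readable decision-making table (percent view)."""
    lines = [
        f"{'method':8s} {'R1':>8s} {'R2':>8s} {'P1':>8s} {'P2':>8s} {'D':>8s}",
    ]
    for s in sets:
        p = s.as_percent_dict()
        lines.append(
            f"{s.method.value:8s} {p['R1']:7.2f}% {p['R2']:7.2f}% "
            f"{p['P1']:7.2f}% {p['P2']:7.2f}% {p['D']:7.2f}%"
        )
    return "\n".join(lines)
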