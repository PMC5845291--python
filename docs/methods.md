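# Methods

## Problem and data model

A spontaneous reporting system accumulates voluntary reports of suspected
adverse drug reactions. One report may link a drug to several reactions, so
the unit of analysis is the one-drug-one-ADR *record*; records aggregate
into (drug, ADR) *pairs* with occurrence counts. Drug and ADR names are
treated as opaque UTF-8 strings (generic names; no terminology mapping or
fuzzy matching — real pipelines resolve nomenclature upstream). A curated
reference database of known drug–ADR associations, extracted from product
labeling, supplies the `known` annotation that all downstream evaluation
rests on.

Cleaning rules, in order: split multi-ADR rows; drop records whose drug or
ADR name is empty or matches a sentinel ("unknown", compared after trimming
and case-folding; the sentinel list is configurable); aggregate; drop pairs
below the minimum case count (default 3, the conventional floor for
disproportionality analysis) and pairs whose drug never occurs in the
reference database. The two pair-level filters are row-local, hence
order-independent and applied in one pass. Duplicate (report, drug, ADR)
triples are counted as distinct occurrences by default — reporting systems
do contain them and no principled merge rule exists at this layer; a strict
deduplication mode is available. The seriousness flag is carried through for
descriptive purposes only; it plays no role in detection or the decision.

## Signal detection

Every pair's 2×2 table is computed *within* its sample — the stratum run
recomputes margins at stratum level, which is precisely what makes pooled
and stratum detection differ. The four criteria use their standard published
forms and cut-offs (all configurable via `DetectionConfig`):

| method | statistic | default signal rule |
|---|---|---|
| PRR | (a/(a+b)) / (c/(c+d)) | a ≥ 3 and PRR ≥ 2 and χ² ≥ 4 |
| ROR | ad/bc | a ≥ 3 and exp(ln ROR − 1.96·√(1/a+1/b+1/c+1/d)) > 1 |
| MHRA | — (criterion only) | a ≥ 3 and PRR ≥ 2 and χ² ≥ 4 |
| IC | log₂((a+½)/(E+½)), E=(a+b)(a+c)/N | IC − 2·SD > 0 |

χ² is the uncorrected Pearson form N(ad−bc)²/((a+b)(c+d)(a+c)(b+d)); Yates'
correction is a flag (off by default — the χ²≥4 criterion is conventionally
quoted uncorrected). PRR and MHRA coincide under the defaults; both are kept
as distinct methods because their configurations may legitimately diverge
and users expect both names.

The IC is the two-parameter shrinkage observed/expected form; its SD comes
from the classic BCPNN closed-form posterior variance approximation
(priors α₁=β₁=1, α=β=2, γ₁₁=1). This is a documented standard variant —
which exact IC variant any given national centre runs is generally
unpublished, so the implementation makes no replication claim beyond the
form stated here. Note a real property of observed/expected measures: IC is
increasing in `a` only while `a` is small relative to the drug/ADR margins;
once the target pair dominates its own margins, O/E flattens toward 1. The
monotonicity test therefore sweeps the former regime.

Zero cells propagate as inf/NaN rather than being silently corrected (a NaN
bound never signals); an optional Haldane +0.5 continuity correction exists
for ROR and IC. Inter-method agreement is summarised by the phi coefficient
(Pearson correlation of the 0/1 signal vectors over a sample's pair list);
a constant vector yields NaN with a warning.

## Fourfold comparison and indicators

The comparison universe is the **stratum's pair set**: pooled-run positives
outside it are ignored (a pair absent from the stratum cannot be compared,
and only this convention makes the cell margins of the worked example
consistent). Cells: a = positive in both runs, b = pooled-only, c =
stratum-only, d = neither; each splits into known (₁) / unknown (₀).

Indicators are computed in exact rational arithmetic
(`fractions.Fraction`) and only rendered as percentages (half-up, two
decimals) for display; the identity R₁−R₂ = (b₁−c₁)/K is exact, as the
property tests assert. Degenerate cases: recall with no known pairs and
precision with no positives are explicit errors; discrepancy with b+c = 0
(no disagreement at all) is defined as 0 with a warning — no disagreement
means no diversity to measure.

## Threshold derivation and decision tree

Thresholds are "an integer percent slightly larger than the mean" of the
per-method differences: Rt from |R₁−R₂|, Pt from |P₁−P₂|, Dt from D itself,
implemented as floor(mean)+1 — a mean already on an integer still moves up,
so the strict branch comparisons can never fire exactly at the mean. On the
worked example this gives means ≈1.04%, ≈1.47%, ≈2.27% and thresholds
2%, 2%, 3%.

Branch differences are computed on the two-decimal rounded percent values —
the convention the published decision table itself uses (its printed MHRA
differences, 0.97% and 0.20%, are differences of rounded values; the exact
fractions give 0.96% and 0.19%). With integer-percent thresholds the two
conventions cannot produce different verdicts unless an exact difference
sits within 0.005% of a threshold; we follow the display convention so
recorded paths match the rendered table.

The tree: R₁−R₂ > Rt → non-separation; R₂−R₁ > Rt → separation; else the
same on P; else D > Dt → non-separation, otherwise separation. Comparisons
are strict; ties fall through. The D-branch direction is implemented as
specified even though one can argue large disagreement should *favour*
separation; `d_branch_inverted` flips it for sensitivity analysis. Auto
mode derives thresholds from the same indicator sets being judged — a
deliberate circularity of the original procedure (with a fixed dataset the
indicators are constants, so no held-out calibration is possible); fixed
user-supplied thresholds are fully supported.

## Synthetic reporting system

The generator emulates the gross shape of a national SRS at desk scale and
is the package's test bed. Defaults (chosen once as a realistic toy
configuration): 30 TCM + 60 western + 10 biological drugs, 40 ADR terms,
20 000 reports, 33.4% of reports multi-ADR (2/3/4 ADRs at 60/30/10%),
Zipf-skewed drug and ADR popularity with exponent 1.0 — calibrated so the
top-10 ADR terms carry 55–65% of split records, the share real national
data exhibit — 12% known-pair density (each drug forced to own ≥ 1 known
pair), 5% serious reports. The stratum ADR profile is a mixture of the
background Zipf profile and a rotated copy, weighted by
`stratum_profile_shift` (0 = identical profiles, 1 = maximally distinct).
Planted signal pairs multiply the chosen ADR's probability within the
chosen drug's profile by the configured relative risk and renormalise, and
enter the reference database with probability `signal_known_fraction`, so
recall and precision have a known optimum. All randomness flows from one
integer seed through named `numpy` generator streams; no global state.

What the simulator does **not** emulate: report-level covariates (age, sex,
region), drug nomenclature, terminology hierarchies, duplicate submissions,
secular reporting trends, and the sheer scale (~10⁶ reports) of national
data. Passing tests therefore demonstrate correctness of the machinery and
qualitative behaviour (planted relative risk ≥ 5 with ≥ 20 cases is
recovered by all four methods in ≥ 95% of seeds; strongly shifted strata
yield majority separation verdicts end-to-end over 20 seeds), not
quantitative claims about any real database. Multi-seed checks run at
4 000–6 000 reports per seed, a size at which the planted pair reliably
accrues ≥ 20 cases while the whole suite stays fast.

## Worked-example fixtures

The three published fourfold tables (PRR, MHRA, IC over a 4697-pair stratum
universe with 830 known pairs) are frozen in `synthetic_data.paper_fixtures`
and reproduce every published indicator value exactly at two decimals, the
2%/2%/3% thresholds, and the three decision paths (PRR and MHRA deciding at
the D branch, IC at the P branch, all "separation"). The national-scale
inputs behind those cells are not public, so pooled/stratum signal *counts*
cannot be reproduced; the detection layer is instead validated against
brute-force reimplementations and the simulator's ground truth.

## Known limitations

- The reference database is treated as a gold standard, but labeling-derived
  references lag novel signals; recall/precision inherit that bias.
- The decision procedure compares exactly two nested samples; multi-stratum
  or hierarchical designs are out of scope.
- No uncertainty is attached to R/P/D or to the verdict; with a fixed
  dataset they are constants of the data.
- MGPS/empirical-Bayes and regression-based detection methods are not
  implemented.
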