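"""Contingency construction and the four disproportionality criteria."""

from __future__ import annotations

import math
import random

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2_contingency

import oracles
from conftest import make_pair

from pvstrat.signal_detection import (
    ContingencyTable,
    DetectionConfig,
    Method,
    chi_square,
    contingency,
    detect,
    ic,
    ic_raw,
    method_correlation,
    mhra,
    prr,
    ror,
)
from pvstrat.types import DrugType, Sample

REF_TABLE = ContingencyTable(10, 90, 10, 890)

cell = st.integers(0, 500)
pos_cell = st.integers(1, 500)


def random_sample(rng: random.Random, n_drugs=5, n_adrs=4) -> Sample:
    pairs = []
    for i in range(n_drugs):
        for j in range(n_adrs):
            if rng.random() < 0.7:
                pairs.append(make_pair(f"d{i}", f"e{j}", rng.randrange(1, 40)))
    if not pairs:
        pairs = [make_pair("d0", "e0", 5)]
    return Sample(pairs=pairs, label="total", n_reports=sum(p.count for p in pairs))


class TestContingency:
    def test_single_pair_degenerate(self):
        sample = Sample(pairs=[make_pair("d1", "e1", 5)], label="total")
        t = contingency(("d1", "e1"), sample)
        assert (t.a, t.b, t.c, t.d) == (5, 0, 0, 0)

    def test_two_by_two_cells(self, two_by_two_sample):
        t = contingency(("d1", "e1"), two_by_two_sample)
        assert (t.a, t.b, t.c, t.d) == (3, 4, 5, 6)

    def test_missing_pair_raises(self, two_by_two_sample):
        with pytest.raises(KeyError):
            contingency(("d1", "e9"), two_by_two_sample)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_matches_double_loop_and_conserves_total(self, seed):
        rng = random.Random(seed)
        sample = random_sample(rng)
        counts = {p.key: p.count for p in sample.pairs}
        for p in sample.pairs:
            t = contingency(p.key, sample)
            assert (t.a, t.b, t.c, t.d) == oracles.brute_table(counts, p.key)
            assert t.n == sample.total_count


class TestChiSquare:
    def test_hand_value(self):
        assert chi_square(REF_TABLE) == pytest.approx(36.281, abs=5e-4)

    def test_independence_is_zero(self):
        assert chi_square(ContingencyTable(10, 20, 30, 60)) == 0.0

    def test_zero_margin_is_nan(self):
        assert math.isnan(chi_square(ContingencyTable(0, 0, 5, 5)))

    @given(pos_cell, pos_cell, pos_cell, pos_cell)
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_agrees_with_scipy(self, a, b, c, d):
        ours = chi_square(ContingencyTable(a, b, c, d))
        ref = chi2_contingency(np.array([[a, b], [c, d]]), correction=False).statistic
        assert ours == pytest.approx(ref, abs=1e-9, rel=1e-12)

    @given(pos_cell, pos_cell, pos_cell, pos_cell)
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_yates_agrees_with_scipy(self, a, b, c, d):
        ours = chi_square(ContingencyTable(a, b, c, d), yates=True)
        ref = chi2_contingency(np.array([[a, b], [c, d]]), correction=True).statistic
        assert ours == pytest.approx(ref, abs=1e-9, rel=1e-12)


class TestPrr:
    def test_reference_table(self):
        r = prr(REF_TABLE)
        assert r.statistic == pytest.approx(9.0)
        assert r.chi2 == pytest.approx(36.281, abs=5e-4)
        assert r.signal

    def test_minimum_count_blocks_signal(self):
        assert not prr(ContingencyTable(2, 1, 1, 1000)).signal

    def test_no_disproportionality(self):
        r = prr(ContingencyTable(10, 90, 20, 180))
        assert r.statistic == pytest.approx(1.0)
        assert not r.signal

    def test_zero_c_is_infinite(self):
        assert math.isinf(prr(ContingencyTable(5, 5, 0, 10)).statistic)


class TestRor:
    def test_reference_table_value(self):
        # ad/bc = 10*890 / (90*10)
        assert ror(REF_TABLE).statistic == pytest.approx(8900 / 900)

    def test_symmetric_identity(self):
        # a=d, b=c -> ROR = (a/b)^2
        r = ror(ContingencyTable(20, 5, 5, 20))
        assert r.statistic == pytest.approx(16.0)

    def test_zero_cell_and_continuity_correction(self):
        t = ContingencyTable(5, 0, 3, 10)
        assert math.isinf(ror(t).statistic)
        corrected = ror(t, DetectionConfig(continuity_correction=True))
        assert math.isfinite(corrected.statistic)

    @given(pos_cell, pos_cell, pos_cell, pos_cell)
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_ror_vs_prr_ordering_identity(self, a, b, c, d):
        """ROR >= PRR exactly when d(a+b) >= b(c+d)."""
        r = ror(ContingencyTable(a, b, c, d)).statistic
        p = prr(ContingencyTable(a, b, c, d)).statistic
        if d * (a + b) > b * (c + d):
            assert r >= p
        elif d * (a + b) < b * (c + d):
            assert r <= p
        else:
            assert r == pytest.approx(p)


class TestMhra:
    def test_reference_table_signals(self):
        r = mhra(REF_TABLE)
        assert r.signal and r.statistic is None

    def test_boundary_prr_below_two(self):
        # a=3 with PRR < 2 must not signal
        t = ContingencyTable(3, 97, 19, 581)  # PRR = (3/100)/(19/600) = 0.947
        assert not mhra(t).signal

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, derandomize=True, deadline=None)
    def test_nested_in_prr(self, seed):
        rng = random.Random(seed)
        sample = random_sample(rng)
        pos_mhra = detect(sample, Method.MHRA).positives
        pos_prr = detect(sample, Method.PRR).positives
        assert pos_mhra <= pos_prr


class TestIc:
    def test_independence_shrinks_to_zero(self):
        r = ic(ContingencyTable(25, 25, 25, 25))
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert not r.signal

    def test_raw_value_on_reference_table(self):
        assert ic_raw(REF_TABLE) == pytest.approx(math.log2(5))

    def test_shrunk_value_matches_independent_formula(self):
        r = ic(REF_TABLE)
        assert r.statistic == pytest.approx(oracles.brute_ic(10, 90, 10, 890), rel=1e-12)
        assert r.interval_low == pytest.approx(
            oracles.brute_ic(10, 90, 10, 890) - 2 * oracles.brute_ic_sd(10, 90, 10, 890),
            rel=1e-9,
        )

    def test_monotone_in_a_over_sweep(self):
        """IC grows with the observed count while it stays small relative to
        the fixed margins (the regime disproportionality analysis targets);
        with the drug/ADR margins dominated by `a` itself, observed/expected
        flattens instead, so the sweep keeps b and c large."""
        values = [ic(ContingencyTable(a, 200, 300, 10_000)).statistic for a in range(1, 101)]
        assert all(x < y for x, y in zip(values, values[1:]))

    def test_empty_table_raises(self):
        with pytest.raises(ValueError):
            ic(ContingencyTable(0, 0, 0, 0))


class TestDetect:
    def test_planted_pair_is_sole_positive_for_all_methods(self):
        pairs = [make_pair(f"d{i}", f"e{j}", 5) for i in range(1, 6) for j in range(1, 5)]
        pairs += [make_pair("d0", f"e{j}", 5) for j in range(1, 5)]
        pairs += [make_pair("d9", f"e{j}", 5) for j in range(1, 5)]
        pairs.append(make_pair("d0", "e0", 50))   # planted disproportionate pair
        pairs.append(make_pair("d9", "e0", 5))    # keeps the e0 margin non-degenerate
        sample = Sample(pairs=pairs, label="total")
        for method in Method:
            run = detect(sample, method)
            assert run.positives == {("d0", "e0")}, method

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            detect(Sample(pairs=[], label="total"), Method.PRR)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=15, derandomize=True, deadline=None)
    def test_all_four_statistics_match_bruteforce(self, seed):
        """Per-pair statistics and signal calls equal the naive closed forms."""
        rng = random.Random(seed)
        sample = random_sample(rng, n_drugs=6, n_adrs=5)
        counts = {p.key: p.count for p in sample.pairs}
        runs = {m: {(r.drug_name, r.adr_name): r for r in detect(sample, m).results}
                for m in Method}
        for key in counts:
            a, b, c, d = oracles.brute_table(counts, key)
            if min(b, c) > 0:
                assert runs[Method.PRR][key].statistic == pytest.approx(
                    oracles.brute_prr(a, b, c, d))
                assert runs[Method.ROR][key].statistic == pytest.approx(
                    oracles.brute_ror(a, b, c, d))
                assert runs[Method.PRR][key].signal == oracles.brute_prr_signal(a, b, c, d)
                assert runs[Method.ROR][key].signal == oracles.brute_ror_signal(a, b, c, d)
                assert runs[Method.MHRA][key].signal == oracles.brute_prr_signal(a, b, c, d)
            assert runs[Method.IC][key].statistic == pytest.approx(
                oracles.brute_ic(a, b, c, d))
            assert runs[Method.IC][key].signal == oracles.brute_ic_signal(a, b, c, d)

    def test_determinism(self):
        rng = random.Random(3)
        sample = random_sample(rng)
        first = detect(sample, Method.IC)
        second = detect(sample, Method.IC)
        assert [(r.drug_name, r.adr_name, r.statistic, r.signal) for r in first.results] == [
            (r.drug_name, r.adr_name, r.statistic, r.signal) for r in second.results
        ]


class TestMethodCorrelation:
    def _run_from_vector(self, vec, label="total", method=Method.PRR):
        """Build a DetectionRun-like object over a shared universe."""
        from pvstrat.signal_detection import DetectionRun, SignalResult

        results = [
            SignalResult(method, ContingencyTable(1, 1, 1, 1), bool(v),
                         drug_name=f"d{i}", adr_name="e")
            for i, v in enumerate(vec)
        ]
        return DetectionRun(sample_label=label, method=method, results=results)

    def test_identical_nonconstant_vectors(self):
        run = self._run_from_vector([1, 0, 1, 0])
        assert method_correlation(run, run) == pytest.approx(1.0)

    def test_orthogonal_vectors(self):
        a = self._run_from_vector([1, 1, 0, 0])
        b = self._run_from_vector([1, 0, 1, 0])
        assert method_correlation(a, b) == pytest.approx(0.0)

    def test_constant_vector_warns_nan(self):
        a = self._run_from_vector([1, 1, 1, 1])
        b = self._run_from_vector([1, 0, 1, 0])
        with pytest.warns(UserWarning):
            assert math.isnan(method_correlation(a, b))

    def test_mismatched_universe_raises(self):
        a = self._run_from_vector([1, 0, 1])
        b = self._run_from_vector([1, 0, 1, 0])
        with pytest.raises(ValueError):
            method_correlation(a, b)

    @given(st.lists(st.tuples(st.booleans(), st.booleans()), min_size=4, max_size=40))
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_matches_sum_formula_phi(self, flags):
        xs = [int(x) for x, _ in flags]
        ys = [int(y) for _, y in flags]
        if len(set(xs)) < 2 or len(set(ys)) < 2:
            return
        a = self._run_from_vector(xs)
        b = self._run_from_vector(ys)
        assert method_correlation(a, b) == pytest.approx(
            oracles.brute_phi(xs, ys), rel=1e-9
        )
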