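"""Contingency construction and the three signal-detection algorithms."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from otovigil.disproportionality import (
    ContingencyTable,
    build_contingency,
    compute_ic,
    compute_prr,
    compute_ror,
    evaluate_signal,
    pearson_chi2,
)
from otovigil.report_store import ReportCollection

from conftest import make_report

E1 = 90000111


def oracle_stats(a, b, c, d):
    """Independent textbook evaluation of ROR, PRR and the four-cell chi2."""
    n = a + b + c + d
    ror = (a * d) / (b * c)
    prr = (a / (a + c)) / (b / (b + d))
    chi2 = 0.0
    for obs, rm, cm in ((a, a + b, a + c), (b, a + b, b + d), (c, c + d, a + c), (d, c + d, b + d)):
        e = rm * cm / n
        chi2 += (obs - e) ** 2 / e
    ic = math.log2(a * n / ((a + c) * (a + b)))
    return ror, prr, chi2, ic


class TestBuildContingency:
    def test_hand_enumerated_six_reports(self, six_report_collection):
        t = build_contingency(six_report_collection, "x", lambda r: E1 in r.reaction_pts)
        # concomitant x in r6 does not count toward a
        assert (t.a, t.b, t.c, t.d) == (1, 3, 1, 1)

    def test_absent_drug_zero_margin(self, six_report_collection):
        t = build_contingency(six_report_collection, "nosuchdrug", lambda r: E1 in r.reaction_pts)
        assert t.a == 0 and t.c == 0
        assert t.n_total == 6

    def test_cells_partition_collection(self, six_report_collection):
        t = build_contingency(six_report_collection, "y", lambda r: E1 in r.reaction_pts)
        assert t.n_total == len(six_report_collection)

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            build_contingency(ReportCollection([]), "x", lambda r: True)


class TestPointEstimates:
    def test_independence_table(self):
        t = ContingencyTable(10, 90, 90, 810)
        assert compute_ror(t)[0] == pytest.approx(1.0)
        prr, chi2 = compute_prr(t)
        assert prr == pytest.approx(1.0) and chi2 == pytest.approx(0.0)
        assert compute_ic(t)[0] == pytest.approx(0.0)

    def test_equal_proportions_null_prr(self):
        prr, chi2 = compute_prr(ContingencyTable(10, 20, 90, 180))
        assert prr == pytest.approx(1.0) and chi2 == pytest.approx(0.0, abs=1e-12)

    def test_hand_evaluated_5_5_5_45(self):
        t = ContingencyTable(5, 5, 5, 45)
        ror, lo, hi = compute_ror(t)
        assert ror == pytest.approx(9.0)
        assert lo == pytest.approx(1.92, abs=0.01)
        assert hi == pytest.approx(42.2, abs=0.1)
        prr, chi2 = compute_prr(t)
        assert prr == pytest.approx(5.0)
        assert chi2 == pytest.approx(9.6)  # 6.667 + 1.333 + 1.333 + 0.267
        ic, ic025 = compute_ic(t)
        assert ic == pytest.approx(math.log2(3))
        assert ic025 == pytest.approx(0.338, abs=0.001)

    def test_a_cell_only_chi2_mode(self):
        t = ContingencyTable(5, 5, 5, 45)
        assert pearson_chi2(t, "a_cell_only") == pytest.approx(20 / 3)

    def test_ci_log_symmetric(self):
        ror, lo, hi = compute_ror(ContingencyTable(17, 243, 121, 5310))
        assert math.sqrt(lo * hi) == pytest.approx(ror, rel=1e-12)


cells = st.integers(min_value=1, max_value=10_000)


class TestOracleEquivalence:
    def test_thousand_random_tables(self):
        rng = np.random.default_rng(20240428)
        for _ in range(1000):
            a, b, c, d = rng.integers(1, 10_001, size=4)
            t = ContingencyTable(int(a), int(b), int(c), int(d))
            ror_o, prr_o, chi2_o, ic_o = oracle_stats(a, b, c, d)
            assert compute_ror(t)[0] == pytest.approx(ror_o, rel=1e-9)
            prr, chi2 = compute_prr(t)
            assert prr == pytest.approx(prr_o, rel=1e-9)
            assert chi2 == pytest.approx(chi2_o, rel=1e-9)
            assert compute_ic(t)[0] == pytest.approx(ic_o, rel=1e-9)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(a=cells, b=cells, c=cells, d=cells)
    def test_scipy_chi2_agrees(self, a, b, c, d):
        from scipy import stats

        t = ContingencyTable(a, b, c, d)
        ref = stats.chi2_contingency(np.array([[a, b], [c, d]]), correction=False)[0]
        assert pearson_chi2(t) == pytest.approx(ref, rel=1e-9, abs=1e-9)


class TestProperties:
    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(a=st.integers(1, 500), b=st.integers(1, 500), c=st.integers(1, 500), d=st.integers(1, 500))
    def test_monotone_in_a(self, a, b, c, d):
        t1, t2 = ContingencyTable(a, b, c, d), ContingencyTable(a + 1, b, c, d)
        assert compute_ror(t2)[0] > compute_ror(t1)[0]
        assert compute_prr(t2)[0] > compute_prr(t1)[0]

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(a=st.integers(0, 50), b=st.integers(0, 50), c=st.integers(0, 50), d=st.integers(0, 50))
    def test_zero_cells_stay_finite(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        t = ContingencyTable(a, b, c, d)
        s = evaluate_signal(t)
        for x in (s.ror, *s.ror_ci, s.prr, s.chi2, s.ic):
            assert math.isfinite(x)
        assert s.zero_corrected == t.has_zero_cell()
        assert s.ror_ci[0] <= s.ror <= s.ror_ci[1]
        assert s.chi2 >= 0
        assert s.positive == (s.ror_positive or s.prr_positive or s.bcpnn_positive)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(a=cells, b=cells, c=cells, d=cells)
    def test_ic_sign_marks_independence(self, a, b, c, d):
        t = ContingencyTable(a, b, c, d)
        ic = compute_ic(t)[0]
        lhs, rhs = a * t.n_total, (a + b) * (a + c)
        if lhs == rhs:
            assert ic == pytest.approx(0.0, abs=1e-12)
        else:
            assert (ic > 0) == (lhs > rhs)


class TestEvaluateSignal:
    def test_strong_sparse_signal_all_flags(self):
        # a small-n, high-strength table in the style of the rarest drug:
        # all three algorithms fire and the pair is an overall signal
        t = ContingencyTable(10, 12_000, 140, 1_100_000)
        s = evaluate_signal(t)
        assert s.n == 10
        assert s.ror_positive and s.prr_positive and s.bcpnn_positive and s.positive
        assert s.prr > 2 and s.chi2 > 4 and s.ror_ci[0] > 1 and s.ic025 > 0

    def test_independence_no_flags(self):
        s = evaluate_signal(ContingencyTable(10, 90, 90, 810))
        assert not (s.ror_positive or s.prr_positive or s.bcpnn_positive or s.positive)
        assert math.isnan(s.ic025)  # IC <= 0: lower limit not evaluable

    def test_multiplicative_ic025_positive_iff_ror_above_one(self):
        # algebraic identity: IC > 0 <=> a*N > (a+b)(a+c) <=> ad > bc <=> ROR > 1,
        # and the multiplicative lower limit IC·exp(−1.96s) keeps the sign of IC,
        # so under the default mode the BCPNN flag fires exactly when ROR > 1
        rng = np.random.default_rng(7)
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(1, 200, size=4))
            s = evaluate_signal(ContingencyTable(a, b, c, d))
            assert s.bcpnn_positive == (s.ror > 1.0)

    def test_ror_only_positive_at_n2_under_ic_minus_2sd(self):
        # with the credible-interval-style IC limit, the ROR rule can be the
        # sole trigger at n=2 (prr rule needs n>=3); found by brute force
        s = evaluate_signal(ContingencyTable(2, 1, 1, 13), ic_mode="ic_minus_2sd")
        assert s.ror_positive and not s.prr_positive and not s.bcpnn_positive
        assert s.positive  # ROR rule alone suffices

    def test_degenerate_margin_chi2_zero(self):
        s = evaluate_signal(ContingencyTable(0, 0, 5, 45))
        assert s.chi2 == 0.0
        assert s.degenerate_chi2
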