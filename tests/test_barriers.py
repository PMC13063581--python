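"""Contingency tests, BH correction, Wilson intervals and reason tables.

The published summary tables double as fixtures: the stratified citation
counts are printed in full, so every univariate p-value and interval can be
recomputed and compared to the printed value.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from conftest import eligible_non_user, eligible_user
from prapp import tables
from prapp.barriers import (
    DegenerateTableError,
    bh_adjust,
    build_reason_analysis,
    chi2_yates,
    choose_test,
    fisher_exact,
    participation_table,
    reason_analysis_from_counts,
    user_proportion,
    wilson_ci,
)
from prapp.selection import apply_selection_flow


class TestChi2Yates:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ((51, 250, 23, 44), 0.002),   # daily pill, by indication
            ((172, 160, 55, 26), 0.013),  # fear of side effects, by density
            ((10, 10, 10, 10), 1.0),
        ],
    )
    def test_published_values(self, table, expected):
        assert round(chi2_yates(*table), 3) == expected

    def test_zero_margin_rejected(self):
        with pytest.raises(DegenerateTableError):
            chi2_yates(0, 0, 3, 4)

    @given(st.tuples(*[st.integers(1, 50)] * 4))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_correction_is_conservative(self, table):
        uncorrected = stats.chi2_contingency(
            np.array(table).reshape(2, 2), correction=False
        )[1]
        assert chi2_yates(*table) >= uncorrected - 1e-12


def fisher_oracle(a, b, c, d):
    """Independent oracle: enumerate all tables with the observed margins
    and sum the hypergeometric mass of those no more probable."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def pmf(k):
        return (
            math.comb(r1, k) * math.comb(r2, c1 - k) / math.comb(n, c1)
        )

    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = pmf(a)
    return sum(pmf(k) for k in range(lo, hi + 1) if pmf(k) <= p_obs * (1 + 1e-9))


class TestFisherExact:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ((0, 5, 5, 0), 2 / 252),      # enumerated by hand: two extreme tables
            ((1, 1, 1, 1), 1.0),
            ((25, 276, 1, 66), 0.062),    # negative reactions, by indication
        ],
    )
    def test_examples(self, table, expected):
        assert fisher_exact(*table) == pytest.approx(expected, abs=5e-4)

    def test_degenerate_margin_returns_one(self):
        assert fisher_exact(0, 0, 0, 0) == 1.0
        assert fisher_exact(0, 3, 0, 4) == 1.0

    @given(st.tuples(*[st.integers(0, 10)] * 4))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_enumeration_oracle(self, table):
        a, b, c, d = table
        if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
            return
        assert fisher_exact(a, b, c, d) == pytest.approx(fisher_oracle(a, b, c, d))


class TestChooseTest:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ((51, 250, 23, 44), "chi_squared_yates"),  # min expected ~13.5
            ((25, 276, 1, 66), "fisher_exact"),        # min expected ~4.7
            ((0, 0, 0, 0), "fisher_exact"),
        ],
    )
    def test_expected_count_rule(self, table, expected):
        assert choose_test(*table) == expected


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_step_up_by_hand(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_order_preserving_and_bounded(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.001, 1.0, 20)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()
        assert (adj >= p - 1e-12).all() and (adj <= 1.0).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5])


class TestWilson:
    def test_berlin_participation(self):
        lo, hi = wilson_ci(282, 59_394)
        assert (round(100 * lo, 2), round(100 * hi, 2)) == (0.42, 0.53)

    def test_bremen_participation(self):
        lo, hi = wilson_ci(9, 3_930)
        assert (round(100 * lo, 2), round(100 * hi, 2)) == (0.12, 0.43)

    def test_zero_count_boundary(self):
        lo, _ = wilson_ci(0, 10)
        assert lo == 0.0

    @given(st.integers(1, 200), st.integers(0, 200))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_brackets_the_point_estimate(self, n, k):
        k = min(k, n)
        lo, hi = wilson_ci(k, n)
        assert 0.0 <= lo <= k / n <= hi <= 1.0

    def test_shrinks_with_sample_size(self):
        lo1, hi1 = wilson_ci(5, 20)
        lo2, hi2 = wilson_ci(50, 200)
        assert (hi2 - lo2) < (hi1 - lo1)


class TestReasonAnalysis:
    def test_indication_table_reproduced(self):
        results = {
            r.reason: r
            for r in reason_analysis_from_counts(
                tables.indication_test_counts(), "indication"
            )
        }
        daily = results["daily_pill"]
        assert daily.test_used == "chi_squared_yates"
        assert round(daily.p_raw, 3) == 0.002
        assert round(daily.p_adjusted, 3) == 0.019
        assert results["negative_reactions"].test_used == "fisher_exact"
        assert round(results["negative_reactions"].p_raw, 3) == 0.062
        assert round(results["effort_doctor_visits"].p_raw, 3) == 0.043

    def test_density_table_reproduced(self):
        results = {
            r.reason: r
            for r in reason_analysis_from_counts(tables.density_test_counts(), "density")
        }
        assert round(results["side_effects"].p_raw, 3) == 0.013
        assert round(results["side_effects"].p_adjusted, 3) == 0.083
        assert round(results["discuss_sex_life"].p_raw, 3) == 0.021
        assert round(results["risk_too_low"].p_raw, 3) == 0.045

    def test_identical_rates_across_strata_are_null(self):
        """Strata with exactly equal citation proportions: nothing rejects."""
        recs = []
        pid = 0
        for stratum_kw, n in (
            (dict(sdu_6m="no", chlamydia_dx_12m="1"), 200),   # partners/STI family
            (dict(sdu_6m="yes", condom_use_category=">95%",
                  n_sex_partners_6m_category="1"), 200),      # SDU only
        ):
            for i in range(n):
                reasons = ("side_effects",) if i < 60 else ()
                recs.append(
                    eligible_non_user(pid, reasons_not_taking_prep=reasons, **stratum_kw)
                )
                pid += 1
        cohort = apply_selection_flow(recs)
        results = build_reason_analysis(cohort, "indication")
        assert all(r.p_adjusted > 0.9 for r in results)


class TestUserProportion:
    def test_published_state_proportions(self):
        recs = []
        pid = 0
        for state, n, users in (
            ("Mecklenburg Western Pomerania", 19, 14),
            ("Bremen", 9, 8),
            ("Nowhere", 5, 0),
        ):
            for i in range(n):
                maker = eligible_user if i < users else eligible_non_user
                recs.append(maker(pid, federal_state=state))
                pid += 1
        out = user_proportion(apply_selection_flow(recs)).set_index("federal_state")
        assert out.loc["Mecklenburg Western Pomerania", "user_proportion"] == 0.74
        assert out.loc["Bremen", "user_proportion"] == 0.89
        assert out.loc["Nowhere", "user_proportion"] == 0.0


def test_participation_table_matches_published_row():
    part = participation_table(
        {"Berlin": 282}, {"Berlin": 59_394}
    ).set_index("federal_state")
    row = part.loc["Berlin"]
    assert round(row["participation_pct"], 2) == 0.47
    assert round(row["ci_low_pct"], 2) == 0.42
    assert round(row["ci_high_pct"], 2) == 0.53
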