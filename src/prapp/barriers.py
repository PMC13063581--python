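"""Univariate barrier analysis: contingency tests, FDR control, Wilson CIs.

Reasons for not taking PrEP are multi-select, so each reason is tested in
its own 2x2 table (citing vs not citing, by stratum): a Yates-corrected
chi-squared test by default, switching to Fisher's exact test (two-sided,
probability-mass definition) whenever any expected cell count falls below
5.  Raw p-values are Benjamini-Hochberg adjusted within the family of eight
reasons.  Participation probabilities per federal state get Wilson score
intervals, which behave well at the small counts involved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportion_confint

from .records import MISSING, REASONS
from .selection import AnalysisCohort

#: density dichotomy used for the low/high stratification
LOW_DENSITY_BANDS = ("0", "1-2", "3-5", "6-9")
HIGH_DENSITY_BANDS = ("10-13",)


class DegenerateTableError(ValueError):
    pass


def _as_table(a: int, b: int, c: int, d: int) -> np.ndarray:
    t = np.array([[a, b], [c, d]], dtype=float)
    if np.any(t < 0):
        raise ValueError("counts must be non-negative")
    return t


def expected_counts(a: int, b: int, c: int, d: int) -> np.ndarray:
    t = _as_table(a, b, c, d)
    total = t.sum()
    if total == 0:
        raise DegenerateTableError("empty table")
    return np.outer(t.sum(axis=1), t.sum(axis=0)) / total


def chi2_yates(a: int, b: int, c: int, d: int) -> float:
    """Continuity-corrected chi-squared p-value for a 2x2 table."""
    t = _as_table(a, b, c, d)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise DegenerateTableError("chi-squared undefined for a zero margin")
    return float(stats.chi2_contingency(t, correction=True)[1])


def fisher_exact(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p: hypergeometric mass of tables at most as probable."""
    t = _as_table(a, b, c, d)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        return 1.0  # a fixed margin of zero admits only the observed table
    return float(stats.fisher_exact(t.astype(int), alternative="two-sided")[1])


def choose_test(a: int, b: int, c: int, d: int) -> str:
    """``fisher_exact`` when any expected cell count < 5, else chi-squared."""
    try:
        expected = expected_counts(a, b, c, d)
    except DegenerateTableError:
        return "fisher_exact"
    if expected.min() < 5.0:
        return "fisher_exact"
    return "chi_squared_yates"


def test_2x2(a: int, b: int, c: int, d: int) -> tuple[str, float]:
    which = choose_test(a, b, c, d)
    if which == "fisher_exact":
        return which, fisher_exact(a, b, c, d)
    return which, chi2_yates(a, b, c, d)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, input order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def wilson_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion k/n."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    lo, hi = proportion_confint(k, n, alpha=1.0 - level, method="wilson")
    # the score interval is exact at the boundaries; snap off float noise
    lo = 0.0 if k == 0 else min(max(float(lo), 0.0), k / n)
    hi = 1.0 if k == n else max(min(float(hi), 1.0), k / n)
    return lo, hi


@dataclass
class ReasonTestResult:
    reason: str
    stratification: str
    n_citing: tuple[int, ...]
    n_total: tuple[int, ...]
    test_used: str
    p_raw: float
    p_adjusted: float = float("nan")

    @property
    def proportions(self) -> tuple[float, ...]:
        return tuple(k / n if n else float("nan") for k, n in zip(self.n_citing, self.n_total))


def reason_analysis_from_counts(
    counts: Mapping[str, tuple[int, int, int, int]], stratification: str
) -> list[ReasonTestResult]:
    """Run the per-reason 2x2 tests from (k1, n1, k2, n2) citation counts.

    ``counts`` maps each reason to (citing, total) per stratum; the raw,
    unrounded p-values feed the BH adjustment across the reason family.
    """
    results = []
    for reason in REASONS:
        if reason not in counts:
            raise KeyError(f"missing counts for reason {reason!r}")
        k1, n1, k2, n2 = counts[reason]
        test_used, p_raw = test_2x2(k1, n1 - k1, k2, n2 - k2)
        results.append(
            ReasonTestResult(
                reason=reason,
                stratification=stratification,
                n_citing=(k1, k2),
                n_total=(n1, n2),
                test_used=test_used,
                p_raw=p_raw,
            )
        )
    adjusted = bh_adjust([r.p_raw for r in results])
    for r, adj in zip(results, adjusted):
        r.p_adjusted = float(adj)
    return results


def build_reason_analysis(
    cohort: AnalysisCohort,
    stratification: str,
    density_bands: Mapping[str, str] | None = None,
) -> list[ReasonTestResult]:
    """Per-reason tests over the cohort's PrEP non-users.

    ``stratification="indication"`` compares the two single-criterion
    subgroups (partners/STI/HCV vs SDU-only); non-users qualifying through
    both clause families are tabulated elsewhere but excluded from the test.
    ``stratification="density"`` compares low (bands 0 through 6-9) vs high
    (band 10-13) HIV-specialist density; ``density_bands`` maps each
    non-user's participant_id to a band, and unmapped or missing bands are
    excluded from the dichotomy.
    """
    non_users = [
        (rec, sub)
        for rec, role, sub in zip(cohort.records, cohort.roles, cohort.subgroups)
        if role == "prep_non_user"
    ]
    if stratification == "indication":
        strata = [
            [r for r, sub in non_users if sub == "partners_sti_hcv"],
            [r for r, sub in non_users if sub == "sdu_only"],
        ]
    elif stratification == "density":
        if density_bands is None:
            raise ValueError("density stratification needs a participant -> band map")
        low, high = [], []
        for r, _ in non_users:
            band = density_bands.get(r.participant_id, MISSING)
            if band in LOW_DENSITY_BANDS:
                low.append(r)
            elif band in HIGH_DENSITY_BANDS:
                high.append(r)
        strata = [low, high]
    else:
        raise ValueError(f"unknown stratification {stratification!r}")

    counts = {}
    for reason in REASONS:
        k = [sum(reason in r.reasons_not_taking_prep for r in s) for s in strata]
        counts[reason] = (k[0], len(strata[0]), k[1], len(strata[1]))
    return reason_analysis_from_counts(counts, stratification)


def reason_results_frame(results: Sequence[ReasonTestResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {"reason": r.reason, "stratification": r.stratification}
        for i, (k, n) in enumerate(zip(r.n_citing, r.n_total), start=1):
            row[f"citing_{i}"] = k
            row[f"total_{i}"] = n
            row[f"pct_{i}"] = 100.0 * k / n if n else float("nan")
        row.update(test_used=r.test_used, p_raw=r.p_raw, p_adjusted=r.p_adjusted)
        rows.append(row)
    return pd.DataFrame(rows)


def user_proportion(cohort: AnalysisCohort) -> pd.DataFrame:
    """Per-state PrEP-user share among indicated participants.

    States with no participants (or only missing state entries) are omitted;
    the reported proportion is rounded to two decimals.
    """
    rows: dict[str, list[int]] = {}
    for rec, role in zip(cohort.records, cohort.roles):
        state = rec.federal_state
        if state == MISSING:
            continue
        n, users = rows.setdefault(state, [0, 0])
        rows[state][0] = n + 1
        rows[state][1] = users + (role == "prep_user")
    out = pd.DataFrame(
        [
            {
                "federal_state": s,
                "n_participants": n,
                "n_users": u,
                "user_proportion": round(u / n, 2),
            }
            for s, (n, u) in sorted(rows.items())
        ]
    )
    return out


def participation_table(
    participants: Mapping[str, int],
    gay_population: Mapping[str, int],
    level: float = 0.95,
) -> pd.DataFrame:
    """Participation probability per state with Wilson intervals (percent)."""
    rows = []
    for state, pop in gay_population.items():
        k = int(participants.get(state, 0))
        lo, hi = wilson_ci(k, int(pop), level)
        rows.append(
            {
                "federal_state": state,
                "estimated_gay_population": int(pop),
                "n_participants": k,
                "participation_pct": 100.0 * k / pop,
                "ci_low_pct": 100.0 * lo,
                "ci_high_pct": 100.0 * hi,
            }
        )
    return pd.DataFrame(rows)
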