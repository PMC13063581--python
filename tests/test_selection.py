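"""Eligibility clauses, subgroup classification and the selection flow."""

import itertools

import pytest

from conftest import eligible_non_user, eligible_user
from prapp.records import MISSING, ParticipantRecord
from prapp.selection import (
    apply_selection_flow,
    classify_subgroup,
    has_indication,
)


def record(**kw):
    defaults = dict(participant_id=0, age_years=30, sdu_6m="no",
                    condom_use_category=">95%", n_sex_partners_6m_category="1",
                    syphilis_dx_12m="0", gonorrhea_dx_12m="0",
                    chlamydia_dx_12m="0", hepatitis_c_dx_12m="0")
    defaults.update(kw)
    return ParticipantRecord(**defaults)


class TestHasIndication:
    @pytest.mark.parametrize(
        "role,kw,expected",
        [
            # SDU alone suffices regardless of condoms/partners
            ("prep_non_user", dict(sdu_6m="yes"), True),
            # many partners but good condom use: no indication for non-users
            ("prep_non_user", dict(n_sex_partners_6m_category="4-5",
                                   condom_use_category="75%"), False),
            # for users the condom clause is waived
            ("prep_user", dict(n_sex_partners_6m_category="2-3",
                               condom_use_category=">95%"), True),
            # any bacterial STI / HCV diagnosis suffices
            ("prep_non_user", dict(chlamydia_dx_12m="1"), True),
            ("prep_non_user", dict(hepatitis_c_dx_12m="2+"), True),
            # >=2 partners with low condom use
            ("prep_non_user", dict(n_sex_partners_6m_category="2-3",
                                   condom_use_category="50%"), True),
            ("prep_non_user", dict(n_sex_partners_6m_category="1",
                                   condom_use_category="0%"), False),
            # missing answers never satisfy a clause
            ("prep_non_user", dict(sdu_6m=MISSING, chlamydia_dx_12m=MISSING,
                                   n_sex_partners_6m_category=MISSING), False),
            ("prep_non_user", dict(n_sex_partners_6m_category="6-10",
                                   condom_use_category=MISSING), False),
        ],
    )
    def test_clauses(self, role, kw, expected):
        assert has_indication(record(**kw), role) is expected

    def test_unknown_role_rejected(self):
        with pytest.raises(ValueError, match="role"):
            has_indication(record(sdu_6m="yes"), "bystander")


class TestClassifySubgroup:
    def test_sdu_only(self):
        assert classify_subgroup(record(sdu_6m="yes")) == "sdu_only"

    def test_partners_sti_family(self):
        assert classify_subgroup(record(chlamydia_dx_12m="1")) == "partners_sti_hcv"
        # partners+condoms and an STI stay in the same family
        assert (
            classify_subgroup(
                record(chlamydia_dx_12m="1", n_sex_partners_6m_category="4-5",
                       condom_use_category="25%")
            )
            == "partners_sti_hcv"
        )

    def test_both_families(self):
        assert classify_subgroup(record(sdu_6m="yes", gonorrhea_dx_12m="1")) == "both"

    def test_requires_an_indication(self):
        with pytest.raises(ValueError):
            classify_subgroup(record())


class TestSelectionFlow:
    def test_empty_input(self):
        cohort = apply_selection_flow([])
        assert len(cohort) == 0
        assert all(s["n_before"] == s["n_after"] == 0 for s in cohort.ledger.as_dicts())

    def test_three_record_fixture(self):
        """Hand-enumerated: former user out, unconfirmed non-user out,
        eligible user kept; removals land at the matching ledger steps."""
        recs = [
            eligible_user(0, prep_status="former"),
            eligible_non_user(1, hiv_status_confirmed_negative="no"),
            eligible_user(2),
        ]
        cohort = apply_selection_flow(recs)
        assert [r.participant_id for r in cohort.records] == [2]
        steps = {s["filter"]: s["n_removed"] for s in cohort.ledger.as_dicts()}
        assert steps["former_users_removed"] == 1
        assert steps["hiv_negative_confirmed"] == 1
        assert sum(steps.values()) == 2

    def test_all_pass_cohort_is_kept_entirely(self):
        recs = [eligible_user(i) for i in range(10)]
        cohort = apply_selection_flow(recs)
        assert cohort.ledger.as_dicts()[-1]["n_after"] == 10

    def test_ledger_counts_are_consistent(self):
        recs = [eligible_user(i) for i in range(5)] + [
            eligible_non_user(9, survey_completed="no"),
            eligible_non_user(10, gender_identity="non-binary"),
        ]
        for name, before, removed, after in apply_selection_flow(recs).ledger.steps:
            assert after == before - removed >= 0

    def test_filters_are_conjunctive(self):
        """The final cohort is the plain conjunction of the record-level
        predicates, hence invariant to filter order."""
        recs = [
            eligible_user(0),
            eligible_user(1, survey_completed="no", prep_status="former"),
            eligible_non_user(2, prior_wave_participation="yes",
                              hiv_status_confirmed_negative="no"),
            eligible_non_user(3),
            record(participant_id=4, prep_status="never",
                   hiv_status_confirmed_negative="yes"),  # no indication
        ]
        kept = {r.participant_id for r in apply_selection_flow(recs).records}
        from prapp.selection import has_indication

        def conjunction(r):
            role = "prep_user" if r.prep_status == "current" else "prep_non_user"
            return (
                r.survey_completed == "yes"
                and r.gender_identity == "male"
                and r.sex_assigned_at_birth == "male"
                and r.prep_status in ("current", "never")
                and r.prior_wave_participation != "yes"
                and (r.prep_status == "current" or r.hiv_status_confirmed_negative == "yes")
                and has_indication(r, role)
            )

        assert kept == {r.participant_id for r in recs if conjunction(r)}

    def test_monotonicity_adding_a_record(self):
        base = [eligible_user(i) for i in range(4)]
        before = apply_selection_flow(base).ledger.as_dicts()
        after = apply_selection_flow(base + [eligible_non_user(99)]).ledger.as_dicts()
        for s_old, s_new in zip(before, after):
            assert s_new["n_after"] >= s_old["n_after"]

    def test_subgroups_partition_non_users(self):
        recs = [
            eligible_non_user(0),  # sdu + partners/condoms -> both
            eligible_non_user(1, sdu_6m="no"),  # partners only
            eligible_non_user(2, condom_use_category=">95%",
                              n_sex_partners_6m_category="1"),  # sdu only
            eligible_user(3),
        ]
        cohort = apply_selection_flow(recs)
        non_user_subs = [s for s, role in zip(cohort.subgroups, cohort.roles)
                         if role == "prep_non_user"]
        assert sorted(non_user_subs) == ["both", "partners_sti_hcv", "sdu_only"]
        assert all(s is None for s, role in zip(cohort.subgroups, cohort.roles)
                   if role == "prep_user")
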