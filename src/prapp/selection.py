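"""Participant selection flow and PrEP-indication classification.

The analysis population is cis-male survey completers who are either current
PrEP users or never-users, with a guideline-based PrEP indication:

* sexualized drug use (SDU) in the last six months, or
* a bacterial STI (syphilis, gonorrhea, chlamydia) or hepatitis C diagnosis
  in the last twelve months, or
* two or more sex partners in the last six months combined with low condom
  use (0-50%) -- the condom-use clause applies to non-users only, because
  infrequent condom use is expected among PrEP users.

A missing answer never satisfies a clause: eligibility must be demonstrated,
not assumed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .records import (
    MISSING,
    LOW_CONDOM_CATEGORIES,
    MULTI_PARTNER_CATEGORIES,
    ParticipantRecord,
)

ROLES = ("prep_user", "prep_non_user")
SUBGROUPS = ("both", "partners_sti_hcv", "sdu_only")

#: record-level filters in flow order (names appear in the ledger)
FLOW_STEPS = (
    "survey_completed",
    "cis_male",
    "prep_status_specified",
    "former_users_removed",
    "repeat_participants_removed",
    "hiv_negative_confirmed",
    "prep_indication",
)


@dataclass
class SelectionLedger:
    """Ordered record of how many participants each flow step removed."""

    steps: list[tuple[str, int, int, int]] = field(default_factory=list)

    def add(self, name: str, n_before: int, n_after: int) -> None:
        if not 0 <= n_after <= n_before:
            raise ValueError(f"inconsistent ledger step {name!r}")
        self.steps.append((name, n_before, n_before - n_after, n_after))

    def as_dicts(self) -> list[dict]:
        return [
            {"filter": s, "n_before": b, "n_removed": r, "n_after": a}
            for s, b, r, a in self.steps
        ]


@dataclass
class AnalysisCohort:
    records: list[ParticipantRecord]
    roles: list[str]
    subgroups: list[str | None]  # None for PrEP users
    ledger: SelectionLedger

    def __len__(self) -> int:
        return len(self.records)

    def non_users(self) -> list[ParticipantRecord]:
        return [r for r, role in zip(self.records, self.roles) if role == "prep_non_user"]


def _sdu_clause(record: ParticipantRecord) -> bool:
    return record.sdu_6m == "yes"


def _sti_clause(record: ParticipantRecord) -> bool:
    return any(v in ("1", "2+") for v in record.sti_hcv_fields().values())


def _partner_clause(record: ParticipantRecord, role: str) -> bool:
    many = record.n_sex_partners_6m_category in MULTI_PARTNER_CATEGORIES
    if role == "prep_user":
        return many
    return many and record.condom_use_category in LOW_CONDOM_CATEGORIES


def has_indication(record: ParticipantRecord, role: str) -> bool:
    """Guideline-based PrEP indication; see module docstring for clauses."""
    if role not in ROLES:
        raise ValueError(f"unknown role {role!r}")
    return _sdu_clause(record) or _sti_clause(record) or _partner_clause(record, role)


def classify_subgroup(record: ParticipantRecord, role: str = "prep_non_user") -> str:
    """Which clause family established the indication.

    ``sdu_only`` when only sexualized drug use fires, ``partners_sti_hcv``
    when only the partner/condom or STI/HCV clauses fire, ``both`` when both
    families fire.  A non-user qualifying through partners+condoms *and* an
    STI stays in ``partners_sti_hcv``: the two belong to the same family.
    """
    sdu = _sdu_clause(record)
    other = _sti_clause(record) or _partner_clause(record, role)
    if not (sdu or other):
        raise ValueError("record has no PrEP indication; cannot classify subgroup")
    if sdu and other:
        return "both"
    return "sdu_only" if sdu else "partners_sti_hcv"


def _role(record: ParticipantRecord) -> str:
    return "prep_user" if record.prep_status == "current" else "prep_non_user"


def apply_selection_flow(records: Iterable[ParticipantRecord]) -> AnalysisCohort:
    """Apply the fixed filter sequence and keep a per-step ledger.

    All filters are record-level predicates, so the final cohort does not
    depend on their order -- only the ledger's intermediate counts do.
    """
    ledger = SelectionLedger()
    current = list(records)

    def step(name: str, keep) -> None:
        nonlocal current
        n_before = len(current)
        current = [r for r in current if keep(r)]
        ledger.add(name, n_before, len(current))

    step("survey_completed", lambda r: r.survey_completed == "yes")
    step(
        "cis_male",
        lambda r: r.gender_identity == "male" and r.sex_assigned_at_birth == "male",
    )
    step("prep_status_specified", lambda r: r.prep_status in ("current", "never", "former"))
    step("former_users_removed", lambda r: r.prep_status != "former")
    step("repeat_participants_removed", lambda r: r.prior_wave_participation != "yes")
    step(
        "hiv_negative_confirmed",
        lambda r: r.prep_status == "current" or r.hiv_status_confirmed_negative == "yes",
    )
    step("prep_indication", lambda r: has_indication(r, _role(r)))

    roles = [_role(r) for r in current]
    subgroups: list[str | None] = [
        classify_subgroup(r, role) if role == "prep_non_user" else None
        for r, role in zip(current, roles)
    ]
    return AnalysisCohort(records=current, roles=roles, subgroups=subgroups, ledger=ledger)
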