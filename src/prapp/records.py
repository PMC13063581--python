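"""Survey record model and categorical vocabularies.

The questionnaire is almost entirely categorical: partner numbers, condom-use
frequency and STI diagnosis counts are pre-binned answer options, not
continuous measurements.  A single string sentinel (``"missing"``) marks any
unanswered or removed answer; downstream stages treat it uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from typing import Iterable, Sequence

import pandas as pd

MISSING = "missing"

#: multi-select answers are serialized into CSV cells with this separator
MULTI_SEP = ";"

CONDOM_CATEGORIES = ("0%", "25%", "50%", "75%", ">95%")
LOW_CONDOM_CATEGORIES = ("0%", "25%", "50%")

PARTNER_CATEGORIES = ("0", "1", "2-3", "4-5", "6-10", "11-20", ">20")
MULTI_PARTNER_CATEGORIES = ("2-3", "4-5", "6-10", "11-20", ">20")

STI_COUNT_CATEGORIES = ("0", "1", "2+")
PATHOGENS = ("syphilis", "gonorrhea", "chlamydia", "hepatitis_c")

AGE_BANDS = ("18-29", "30-39", "40-49", "50-80")
DENSITY_BANDS = ("0", "1-2", "3-5", "6-9", "10-13")
INCOME_BANDS = (
    "<1000",
    "1000-<2000",
    "2000-<3000",
    "3000-<4000",
    "4000-<5000",
    ">=5000",
)

PREP_STATUSES = ("current", "never", "former")

#: the eight reasons a non-user can give for not taking PrEP (multi-select)
REASONS = (
    "risk_too_low",
    "no_doctor",
    "effort_doctor_visits",
    "discuss_sex_life",
    "negative_reactions",
    "side_effects",
    "daily_pill",
    "medical_reasons",
)

REASON_LABELS = {
    "risk_too_low": "Personal HIV risk too low",
    "no_doctor": "No doctor prescribing PrEP",
    "effort_doctor_visits": "Effort with doctor visits and regular tests",
    "discuss_sex_life": "Not wanting to discuss sex life with doctor",
    "negative_reactions": "Negative reactions of sexual partners / others",
    "side_effects": "Fear of side effects",
    "daily_pill": "Daily pill too burdensome",
    "medical_reasons": "Medical reasons",
}

FEDERAL_STATES = (
    "Baden-Wuerttemberg",
    "Bavaria",
    "Berlin",
    "Brandenburg",
    "Bremen",
    "Hamburg",
    "Hesse",
    "Mecklenburg Western Pomerania",
    "Lower Saxony",
    "North Rhine-Westphalia",
    "Rhineland-Palatinate",
    "Saarland",
    "Saxony",
    "Saxony-Anhalt",
    "Schleswig-Holstein",
    "Thuringia",
)

SEX_PARTNER_GENDERS = ("male", "female", "non-binary")

SATISFACTION_CATEGORIES = ("content", "discontent", "sex_does_not_matter")

SCHOOL_CATEGORIES = (
    "no_qualification",
    "secondary_8_9",
    "secondary_10",
    "a_levels",
)


@dataclass
class ParticipantRecord:
    """One survey response.

    Every categorical field may carry the :data:`MISSING` sentinel, except
    ``prep_status`` which is guaranteed present for records that enter the
    analysis (records without a stated PrEP status are removed by the
    selection flow).  ``reasons_not_taking_prep`` is only meaningful for
    PrEP non-users and is empty for current users.
    """

    participant_id: int
    age_years: int
    gender_identity: str = "male"
    sex_assigned_at_birth: str = "male"
    country_of_origin: str = MISSING
    household_income_category: str = MISSING
    household_size: int | str = MISSING
    federal_state: str = MISSING
    urban_rural: str = MISSING
    condom_use_category: str = MISSING
    n_sex_partners_6m_category: str = MISSING
    sdu_6m: str = MISSING
    syphilis_dx_12m: str = MISSING
    gonorrhea_dx_12m: str = MISSING
    chlamydia_dx_12m: str = MISSING
    hepatitis_c_dx_12m: str = MISSING
    hiv_status_confirmed_negative: str = MISSING
    prep_status: str = MISSING
    prior_wave_participation: str = "no"
    survey_completed: str = "yes"
    reasons_not_taking_prep: tuple[str, ...] = ()
    sex_partner_genders: tuple[str, ...] = ()
    satisfaction_sex_life: str = MISSING
    school_qualification: str = MISSING

    def sti_hcv_fields(self) -> dict[str, str]:
        return {
            "syphilis": self.syphilis_dx_12m,
            "gonorrhea": self.gonorrhea_dx_12m,
            "chlamydia": self.chlamydia_dx_12m,
            "hepatitis_c": self.hepatitis_c_dx_12m,
        }


_MULTI_FIELDS = ("reasons_not_taking_prep", "sex_partner_genders")
_INT_FIELDS = ("participant_id", "age_years")


def records_to_frame(records: Iterable[ParticipantRecord]) -> pd.DataFrame:
    """Tabulate records; multi-select fields become ``;``-joined strings."""
    rows = []
    for rec in records:
        row = asdict(rec)
        for f in _MULTI_FIELDS:
            row[f] = MULTI_SEP.join(row[f])
        rows.append(row)
    columns = [f.name for f in fields(ParticipantRecord)]
    return pd.DataFrame(rows, columns=columns)


def frame_to_records(frame: pd.DataFrame) -> list[ParticipantRecord]:
    records = []
    for row in frame.itertuples(index=False):
        kwargs = row._asdict()
        for f in _MULTI_FIELDS:
            raw = kwargs.get(f, "")
            if raw is None or raw == "" or pd.isna(raw):
                kwargs[f] = ()
            else:
                kwargs[f] = tuple(str(raw).split(MULTI_SEP))
        for f in _INT_FIELDS:
            kwargs[f] = int(kwargs[f])
        hs = kwargs.get("household_size", MISSING)
        if hs != MISSING and not pd.isna(hs):
            try:
                kwargs["household_size"] = int(hs)
            except (TypeError, ValueError):
                kwargs["household_size"] = MISSING
        else:
            kwargs["household_size"] = MISSING
        records.append(ParticipantRecord(**kwargs))
    return records


def write_csv(records: Sequence[ParticipantRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False, lineterminator="\n")


def read_csv(path) -> list[ParticipantRecord]:
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    return frame_to_records(frame)
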