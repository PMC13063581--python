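"""Derived variables and the one-hot design matrix.

Three derived covariates need care:

* **Net equivalent income**: the midpoint of the household net-income answer
  option divided by the square root of household size (square-root
  equivalence scale).  The open-ended top option uses a fixed
  population-weighted value (default 6,260 EUR).  The result is binned into
  six bands from <1000 to >=5000 EUR/month.
* **HIV-specialist density**: each federal state's licensed HIV-care
  physicians per 10,000 estimated gay men, banded into 0, 1-2, 3-5, 6-9 and
  10-13 (density rounded to the nearest integer before interval lookup).
* **Missingness**: the answer options "I do not know" and "Prefer not to
  say" are recoded to the missing sentinel; in the default encoding each
  variable's missing values form their own indicator column, while the
  sensitivity variant folds them into the reference category.

One-hot encoding drops the most frequent category of each variable as the
reference (ties broken by schema order) and excludes constant columns,
which are inestimable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import math

import numpy as np
import pandas as pd

from .records import (
    MISSING,
    AGE_BANDS,
    CONDOM_CATEGORIES,
    DENSITY_BANDS,
    INCOME_BANDS,
    PARTNER_CATEGORIES,
    SATISFACTION_CATEGORIES,
    SCHOOL_CATEGORIES,
    STI_COUNT_CATEGORIES,
    ParticipantRecord,
)
from .selection import AnalysisCohort

NON_ANSWER_SENTINELS = ("I do not know", "Prefer not to say")

MISSING_MODES = ("separate_category", "reference")


class SchemaError(ValueError):
    pass


@dataclass(frozen=True)
class IncomeSchema:
    """Household-income answer options as (label, lower, upper) EUR bounds.

    ``upper is None`` marks the open-ended top option, valued at
    ``top_category_value`` instead of a midpoint.
    """

    categories: tuple[tuple[str, float, float | None], ...]
    top_category_value: float = 6260.0
    band_edges: tuple[float, ...] = (1000.0, 2000.0, 3000.0, 4000.0, 5000.0)
    band_labels: tuple[str, ...] = INCOME_BANDS

    def __post_init__(self):
        prev_upper = -math.inf
        for label, lo, hi in self.categories:
            if hi is not None and hi <= lo:
                raise SchemaError(f"income category {label!r} has empty bounds")
            if lo < prev_upper:
                raise SchemaError(f"income category {label!r} overlaps its predecessor")
            prev_upper = hi if hi is not None else math.inf
        lowers = [lo for _, lo, hi in self.categories]
        if self.top_category_value <= max(lowers):
            raise SchemaError("top_category_value below the highest lower bound")

    def category_value(self, label: str) -> float:
        for name, lo, hi in self.categories:
            if name == label:
                return self.top_category_value if hi is None else (lo + hi) / 2.0
        raise SchemaError(f"unknown income category {label!r}")


def default_income_schema() -> IncomeSchema:
    """500-EUR answer grid up to 5,000 EUR with an open-ended top option."""
    cats = []
    for lo in range(0, 5000, 500):
        hi = lo + 500
        label = f"<{hi}" if lo == 0 else f"{lo}-<{hi}"
        cats.append((label, float(lo), float(hi)))
    cats.append((">5000", 5000.0, None))
    return IncomeSchema(categories=tuple(cats))


def income_band(value: float, schema: IncomeSchema) -> str:
    idx = int(np.searchsorted(schema.band_edges, value, side="right"))
    return schema.band_labels[idx]


def equivalised_income(
    income_category: str, household_size, schema: IncomeSchema
) -> tuple[float | str, str]:
    """(net equivalent income in EUR, income band); missing propagates."""
    if income_category == MISSING or household_size == MISSING:
        return MISSING, MISSING
    size = int(household_size)
    if size < 1:
        raise SchemaError(f"household size must be >= 1, got {size}")
    value = schema.category_value(income_category) / math.sqrt(size)
    return value, income_band(value, schema)


@dataclass(frozen=True)
class DensityMap:
    """Federal state -> HIV-specialists per 10,000 gay men."""

    densities: Mapping[str, float]

    def __post_init__(self):
        for state, d in self.densities.items():
            if not 0.0 <= float(d) <= 13.0:
                raise SchemaError(f"density for {state!r} outside [0, 13]")


#: the three printed city-state densities; the full map is config-supplied
PUBLISHED_DENSITIES = {"Berlin": 10.27, "Hamburg": 10.73, "Bremen": 12.73}

_DENSITY_BAND_RANGES = {
    "0": (0, 0),
    "1-2": (1, 2),
    "3-5": (3, 5),
    "6-9": (6, 9),
    "10-13": (10, 13),
}


def density_band(state: str, dmap: DensityMap) -> str:
    """Band label for the state's density; unmapped states are missing."""
    if state not in dmap.densities:
        return MISSING
    rounded = int(math.floor(float(dmap.densities[state]) + 0.5))  # round half up
    rounded = min(max(rounded, 0), 13)
    for label, (lo, hi) in _DENSITY_BAND_RANGES.items():
        if lo <= rounded <= hi:
            return label
    raise AssertionError("unreachable")


def recode_missing(record: ParticipantRecord) -> ParticipantRecord:
    """Map the non-answer options to the missing sentinel, field by field."""
    from dataclasses import replace, fields as dc_fields

    updates = {}
    for f in dc_fields(record):
        v = getattr(record, f.name)
        if isinstance(v, str) and v in NON_ANSWER_SENTINELS:
            updates[f.name] = MISSING
    return replace(record, **updates) if updates else record


def age_band(age_years: int) -> str:
    for label in AGE_BANDS:
        lo, hi = label.split("-")
        if int(lo) <= age_years <= int(hi):
            return label
    return MISSING


# ---------------------------------------------------------------------------
# analysis frame and design matrix


#: default modelled variables with their grouped category order
DEFAULT_GROUPING: dict[str, tuple[str, ...]] = {
    "age_band": AGE_BANDS,
    "country_of_origin": ("Germany", "Outside Germany"),
    "income_band": INCOME_BANDS,
    "density_band": DENSITY_BANDS,
    "urban_rural": ("urban", "rural"),
    "condom_use_category": CONDOM_CATEGORIES,
    "n_sex_partners_6m_category": PARTNER_CATEGORIES,
    "sdu_6m": ("no", "yes"),
    "syphilis_dx_12m": STI_COUNT_CATEGORIES,
    "gonorrhea_dx_12m": STI_COUNT_CATEGORIES,
    "chlamydia_dx_12m": STI_COUNT_CATEGORIES,
    "hepatitis_c_dx_12m": STI_COUNT_CATEGORIES,
    "satisfaction_sex_life": SATISFACTION_CATEGORIES,
    "school_qualification": SCHOOL_CATEGORIES,
    "partner_male": ("no", "yes"),
    "partner_female": ("no", "yes"),
    "partner_non-binary": ("no", "yes"),
}


def build_analysis_frame(
    cohort: AnalysisCohort,
    income_schema: IncomeSchema | None = None,
    density_map: DensityMap | None = None,
) -> pd.DataFrame:
    """Grouped categorical frame (plus outcome) for the selected cohort."""
    income_schema = income_schema or default_income_schema()
    density_map = density_map or DensityMap(PUBLISHED_DENSITIES)
    rows = []
    for rec, role in zip(cohort.records, cohort.roles):
        _, band = equivalised_income(
            rec.household_income_category, rec.household_size, income_schema
        )
        row = {
            "outcome": 1 if role == "prep_user" else 0,
            "age_band": age_band(rec.age_years),
            "country_of_origin": rec.country_of_origin,
            "income_band": band,
            "density_band": density_band(rec.federal_state, density_map),
            "urban_rural": rec.urban_rural,
            "condom_use_category": rec.condom_use_category,
            "n_sex_partners_6m_category": rec.n_sex_partners_6m_category,
            "sdu_6m": rec.sdu_6m,
            "syphilis_dx_12m": rec.syphilis_dx_12m,
            "gonorrhea_dx_12m": rec.gonorrhea_dx_12m,
            "chlamydia_dx_12m": rec.chlamydia_dx_12m,
            "hepatitis_c_dx_12m": rec.hepatitis_c_dx_12m,
            "satisfaction_sex_life": rec.satisfaction_sex_life,
            "school_qualification": rec.school_qualification,
        }
        for g in ("male", "female", "non-binary"):
            row[f"partner_{g}"] = "yes" if g in rec.sex_partner_genders else "no"
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ColumnMeta:
    source_variable: str
    category: str
    is_missing_indicator: bool = False

    @property
    def name(self) -> str:
        return f"{self.source_variable}={self.category}"


@dataclass
class DesignMatrix:
    y: np.ndarray
    X: pd.DataFrame
    columns: list[ColumnMeta]
    reference: dict[str, str]
    missing_mode: str = "separate_category"

    @property
    def n(self) -> int:
        return len(self.y)


def build_design_matrix(
    frame: pd.DataFrame,
    grouping_spec: Mapping[str, Sequence[str]] | None = None,
    missing_mode: str = "separate_category",
) -> DesignMatrix:
    """Encode grouped categories into binary indicators.

    Per variable: the most frequent category becomes the reference (ties
    broken by schema order); each remaining category present in the data
    gets an indicator; missing values get their own indicator
    (``separate_category``) or contribute to no indicator (``reference``).
    Constant columns are excluded.
    """
    if frame.empty:
        raise SchemaError("cannot encode an empty cohort")
    if missing_mode not in MISSING_MODES:
        raise SchemaError(f"unknown missing_mode {missing_mode!r}")
    grouping_spec = grouping_spec or {
        v: cats for v, cats in DEFAULT_GROUPING.items() if v in frame.columns
    }

    y = frame["outcome"].to_numpy(dtype=int)
    cols: dict[str, np.ndarray] = {}
    metas: list[ColumnMeta] = []
    reference: dict[str, str] = {}

    for var, categories in grouping_spec.items():
        values = frame[var].astype(str)
        known = set(categories) | {MISSING}
        bad = sorted(set(values) - known)
        if bad:
            raise SchemaError(f"variable {var!r} has unknown value {bad[0]!r}")
        counts = values[values != MISSING].value_counts()
        if counts.empty:
            continue  # fully missing variable: nothing estimable
        top = counts.max()
        ref = next(c for c in categories if counts.get(c, 0) == top)
        reference[var] = ref
        for cat in categories:
            if cat == ref:
                continue
            ind = (values == cat).to_numpy(dtype=np.int8)
            if 0 < ind.sum() < len(ind):
                meta = ColumnMeta(var, cat)
                cols[meta.name] = ind
                metas.append(meta)
        if missing_mode == "separate_category":
            ind = (values == MISSING).to_numpy(dtype=np.int8)
            if 0 < ind.sum() < len(ind):
                meta = ColumnMeta(var, MISSING, is_missing_indicator=True)
                cols[meta.name] = ind
                metas.append(meta)

    X = pd.DataFrame(cols, index=frame.index)
    return DesignMatrix(y=y, X=X, columns=metas, reference=reference, missing_mode=missing_mode)


def decode_design_matrix(matrix: DesignMatrix) -> pd.DataFrame:
    """Invert ``separate_category`` encoding back to grouped categories.

    Rows that are all-zero for a variable decode to its reference category.
    Only meaningful when no non-reference category was dropped as constant.
    """
    out = {}
    for var, ref in matrix.reference.items():
        decoded = np.full(matrix.n, ref, dtype=object)
        for meta in matrix.columns:
            if meta.source_variable != var:
                continue
            hit = matrix.X[meta.name].to_numpy() == 1
            decoded[hit] = MISSING if meta.is_missing_indicator else meta.category
        out[var] = decoded
    return pd.DataFrame(out, index=matrix.X.index)
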