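"""Synthetic survey cohort generator.

The real microdata behind the analysis are not public, so the generator
produces cohorts with the statistical structure the downstream stages assume:
independently sampled categorical covariates with configurable marginals, a
PrEP-use outcome drawn from a logistic model on those covariates,
multi-select reasons for non-use with stratum-specific citation
probabilities, and per-field missingness.

Covariates are sampled independently across variables; the published study
reports only marginal distributions, so no dependence structure is imposed
by default.  Each variable draws from its own RNG stream (seeded from the
master seed and a stable per-variable key), so adding a variable to a config
does not perturb the draws of the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import yaml

from .records import (
    MISSING,
    AGE_BANDS,
    REASONS,
    SEX_PARTNER_GENDERS,
    ParticipantRecord,
)


class ConfigError(ValueError):
    """Raised when a cohort configuration violates its invariants."""


#: record fields that may never be masked by missingness injection
PROTECTED_FIELDS = frozenset({"participant_id", "prep_status", "age_years"})

#: scalar categorical fields eligible for missingness injection
MASKABLE_FIELDS = (
    "gender_identity",
    "sex_assigned_at_birth",
    "country_of_origin",
    "household_income_category",
    "household_size",
    "federal_state",
    "urban_rural",
    "condom_use_category",
    "n_sex_partners_6m_category",
    "sdu_6m",
    "syphilis_dx_12m",
    "gonorrhea_dx_12m",
    "chlamydia_dx_12m",
    "hepatitis_c_dx_12m",
    "hiv_status_confirmed_negative",
    "prior_wave_participation",
    "survey_completed",
    "satisfaction_sex_life",
    "school_qualification",
)

# sampled variables that are not stored verbatim on the record
_DERIVED_VARIABLES = {"age_band", "partner_male", "partner_female", "partner_non-binary"}

_AGE_BAND_RANGES = {
    "18-29": (18, 29),
    "30-39": (30, 39),
    "40-49": (40, 49),
    "50-80": (50, 80),
}


def _stream(seed: int, name: str) -> np.random.Generator:
    """One RNG stream per named draw source, stable across config edits."""
    return np.random.default_rng([int(seed), zlib.crc32(name.encode("utf8"))])


@dataclass
class CohortConfig:
    """Everything needed to synthesize one cohort.

    ``outcome_effects`` maps ``(variable, category)`` to a log-odds shift on
    the probability of being a current PrEP user; ``outcome_intercept`` is
    the baseline log-odds.  ``reason_probs`` maps each reason to citation
    probabilities keyed by the value of ``reason_stratum_variable`` (with a
    ``"default"`` fallback), and applies only to PrEP non-users.
    """

    n_participants: int
    covariate_marginals: dict = field(default_factory=dict)
    outcome_intercept: float = 0.0
    outcome_effects: dict = field(default_factory=dict)
    reason_probs: dict = field(default_factory=dict)
    reason_stratum_variable: str = "sdu_6m"
    missing_rate: dict = field(default_factory=dict)
    former_rate: float = 0.0
    unspecified_prep_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 0:
            raise ConfigError("n_participants must be >= 0")
        samplable = set(MASKABLE_FIELDS) | _DERIVED_VARIABLES
        for var, marginal in self.covariate_marginals.items():
            if var not in samplable:
                raise ConfigError(f"unknown covariate {var!r} in marginals")
            probs = np.asarray(list(marginal.values()), dtype=float)
            if np.any(probs < 0) or np.any(probs > 1):
                raise ConfigError(f"probabilities for {var!r} outside [0, 1]")
            if abs(probs.sum() - 1.0) > 1e-9:
                raise ConfigError(
                    f"category probabilities for {var!r} sum to {probs.sum():.12f}, not 1"
                )
        for reason, strata in self.reason_probs.items():
            for stratum, p in strata.items():
                if not 0.0 <= float(p) <= 1.0:
                    raise ConfigError(
                        f"reason probability for ({reason!r}, {stratum!r}) outside [0, 1]"
                    )
        for var, rate in self.missing_rate.items():
            if var in PROTECTED_FIELDS:
                raise ConfigError(f"missingness configured for protected field {var!r}")
            if var not in MASKABLE_FIELDS:
                raise ConfigError(f"missingness configured for unknown field {var!r}")
            if not 0.0 <= float(rate) < 1.0:
                raise ConfigError(f"missing rate for {var!r} outside [0, 1)")
        for rate_name in ("former_rate", "unspecified_prep_rate"):
            if not 0.0 <= float(getattr(self, rate_name)) < 1.0:
                raise ConfigError(f"{rate_name} outside [0, 1)")


def _sample_categorical(
    marginal: Mapping, n: int, rng: np.random.Generator
) -> np.ndarray:
    cats = list(marginal.keys())
    probs = np.asarray([marginal[c] for c in cats], dtype=float)
    idx = rng.choice(len(cats), size=n, p=probs)
    return np.asarray(cats, dtype=object)[idx]


def generate_cohort(config: CohortConfig) -> list[ParticipantRecord]:
    """Draw ``config.n_participants`` synthetic survey responses.

    Sampling order per record: covariates first, then PrEP status from the
    logistic outcome model evaluated on the *true* (pre-missingness)
    covariate values, then reasons for non-users, then missingness.
    """
    config.validate()
    n = config.n_participants
    if n == 0:
        return []

    columns: dict[str, np.ndarray] = {}
    for var in config.covariate_marginals:
        columns[var] = _sample_categorical(
            config.covariate_marginals[var], n, _stream(config.seed, f"cov:{var}")
        )

    if "age_band" in columns:
        rng_age = _stream(config.seed, "age_years")
        ages = np.empty(n, dtype=int)
        for band, (lo, hi) in _AGE_BAND_RANGES.items():
            mask = columns["age_band"] == band
            ages[mask] = rng_age.integers(lo, hi + 1, size=int(mask.sum()))
        columns["age_years"] = ages
        columns["age_band"] = columns["age_band"]
    else:
        columns["age_years"] = np.full(n, 30)

    # logistic outcome: current PrEP user vs never-user
    eta = np.full(n, float(config.outcome_intercept))
    for key, beta in config.outcome_effects.items():
        var, cat = key if isinstance(key, tuple) else tuple(key)
        if var not in columns:
            raise ConfigError(f"outcome effect references unsampled variable {var!r}")
        eta += float(beta) * (columns[var].astype(str) == str(cat))
    p_user = 1.0 / (1.0 + np.exp(-eta))
    rng_outcome = _stream(config.seed, "outcome")
    is_user = rng_outcome.random(n) < p_user
    prep_status = np.where(is_user, "current", "never").astype(object)

    if config.former_rate > 0:
        former = _stream(config.seed, "former").random(n) < config.former_rate
        prep_status[former] = "former"
    if config.unspecified_prep_rate > 0:
        unspec = (
            _stream(config.seed, "prep_unspecified").random(n)
            < config.unspecified_prep_rate
        )
        prep_status[unspec] = MISSING

    # reasons for non-use: independent Bernoulli per reason, stratum-specific
    strat_var = config.reason_stratum_variable
    strat_values = (
        columns[strat_var].astype(str)
        if strat_var in columns
        else np.full(n, "default", dtype=object)
    )
    reasons_per_record: list[list[str]] = [[] for _ in range(n)]
    for reason in REASONS:
        strata = config.reason_probs.get(reason)
        if not strata:
            continue
        rng_reason = _stream(config.seed, f"reason:{reason}")
        draws = rng_reason.random(n)
        for i in range(n):
            if prep_status[i] != "never":
                continue
            p = strata.get(str(strat_values[i]), strata.get("default", 0.0))
            if draws[i] < float(p):
                reasons_per_record[i].append(reason)

    records: list[ParticipantRecord] = []
    for i in range(n):
        genders = tuple(
            g
            for g in SEX_PARTNER_GENDERS
            if columns.get(f"partner_{g}", np.full(n, "no"))[i] == "yes"
        )
        kwargs = {
            var: columns[var][i]
            for var in columns
            if var not in _DERIVED_VARIABLES and var != "age_years"
        }
        records.append(
            ParticipantRecord(
                participant_id=i,
                age_years=int(columns["age_years"][i]),
                prep_status=str(prep_status[i]),
                reasons_not_taking_prep=tuple(reasons_per_record[i]),
                sex_partner_genders=genders,
                **{k: (v if isinstance(v, (int, np.integer)) else str(v)) for k, v in kwargs.items()},
            )
        )

    return inject_missingness(records, config.missing_rate, config.seed)


def inject_missingness(
    records: Sequence[ParticipantRecord],
    missing_rate_map: Mapping[str, float],
    seed: int,
) -> list[ParticipantRecord]:
    """Independently replace eligible fields with the missing sentinel.

    Masking is positional (field x record index), so re-applying the same
    map and seed is idempotent: already-missing entries stay missing.
    """
    for var, rate in missing_rate_map.items():
        if var in PROTECTED_FIELDS:
            raise ConfigError(f"cannot mask protected field {var!r}")
        if var not in MASKABLE_FIELDS:
            raise ConfigError(f"cannot mask unknown field {var!r}")
        if not 0.0 <= float(rate) < 1.0:
            raise ConfigError(f"missing rate for {var!r} outside [0, 1)")
    if not records:
        return []
    n = len(records)
    masks = {
        var: _stream(seed, f"missing:{var}").random(n) < float(rate)
        for var, rate in missing_rate_map.items()
        if rate > 0
    }
    out = []
    for i, rec in enumerate(records):
        updates = {var: MISSING for var, mask in masks.items() if mask[i]}
        out.append(replace(rec, **updates) if updates else rec)
    return out


def _parse_effects(raw: Mapping) -> dict:
    effects = {}
    for var, cats in raw.items():
        for cat, beta in cats.items():
            effects[(str(var), str(cat))] = float(beta)
    return effects


def config_from_dict(data: Mapping) -> CohortConfig:
    outcome = data.get("outcome_model", {})
    cfg = CohortConfig(
        n_participants=int(data.get("n_participants", 0)),
        covariate_marginals={
            str(v): dict(m) for v, m in data.get("covariate_marginals", {}).items()
        },
        outcome_intercept=float(outcome.get("intercept", 0.0)),
        outcome_effects=_parse_effects(outcome.get("effects", {})),
        reason_probs={
            str(r): {str(s): float(p) for s, p in strata.items()}
            for r, strata in data.get("reason_probs", {}).items()
        },
        reason_stratum_variable=str(data.get("reason_stratum_variable", "sdu_6m")),
        missing_rate={str(v): float(r) for v, r in data.get("missing_rate", {}).items()},
        former_rate=float(data.get("former_rate", 0.0)),
        unspecified_prep_rate=float(data.get("unspecified_prep_rate", 0.0)),
        seed=int(data.get("seed", 0)),
    )
    cfg.validate()
    return cfg


def load_config(path) -> CohortConfig:
    with open(path, "r", encoding="utf8") as fh:
        return config_from_dict(yaml.safe_load(fh))


def default_config(n_participants: int = 1458, seed: int = 0) -> CohortConfig:
    """Packaged default: marginals transcribed from the published cohort
    summary table, with plausible values for fields the publication does not
    tabulate.  Defaults, not assertions."""
    ref = resources.files("prapp.data").joinpath("default_cohort.yaml")
    with ref.open("r", encoding="utf8") as fh:
        data = yaml.safe_load(fh)
    cfg = config_from_dict(data)
    cfg.n_participants = n_participants
    cfg.seed = seed
    cfg.validate()
    return cfg
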