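"""Published summary tables of the PrApp survey, used as in-package fixtures.

The underlying microdata are not public, but the study report prints the
per-state participation counts, per-state user counts and the stratified
reasons-for-non-use citation counts.  Those printed aggregates are
sufficient inputs for the univariate analyses (contingency tests, Wilson
intervals, user proportions) and are transcribed here verbatim.
"""

from __future__ import annotations

#: estimated gay population (EMIS 2017) and indicated participants per state
PARTICIPATION = {
    "Baden-Wuerttemberg": (44651, 115),
    "Bavaria": (54061, 212),
    "Berlin": (59394, 282),
    "Brandenburg": (8395, 20),
    "Bremen": (3930, 9),
    "Hamburg": (17713, 78),
    "Hesse": (31422, 134),
    "Mecklenburg Western Pomerania": (6329, 19),
    "Lower Saxony": (28175, 79),
    "North Rhine-Westphalia": (79376, 301),
    "Rhineland-Palatinate": (13156, 57),
    "Saarland": (4520, 12),
    "Saxony": (20499, 57),
    "Saxony-Anhalt": (7454, 15),
    "Schleswig-Holstein": (13395, 16),
    "Thuringia": (6956, 12),
}

#: (participants, PrEP users) per state among those with a PrEP indication
USER_COUNTS = {
    "Baden-Wuerttemberg": (115, 72),
    "Bavaria": (212, 155),
    "Berlin": (282, 218),
    "Brandenburg": (20, 12),
    "Bremen": (9, 8),
    "Hamburg": (78, 62),
    "Hesse": (134, 99),
    "Mecklenburg Western Pomerania": (19, 14),
    "Lower Saxony": (79, 56),
    "North Rhine-Westphalia": (301, 198),
    "Rhineland-Palatinate": (57, 43),
    "Saarland": (12, 8),
    "Saxony": (57, 36),
    "Saxony-Anhalt": (15, 6),
    "Schleswig-Holstein": (16, 12),
    "Thuringia": (12, 6),
}

#: reasons cited by non-users, stratified by indication subgroup.
#: columns: (both, partners/STI/HCV, SDU-only) citing counts
REASONS_BY_INDICATION_N = {"both": 63, "partners_sti_hcv": 301, "sdu_only": 67}
REASONS_BY_INDICATION = {
    "risk_too_low": (13, 75, 22),
    "no_doctor": (19, 55, 14),
    "effort_doctor_visits": (24, 109, 15),
    "discuss_sex_life": (19, 83, 14),
    "negative_reactions": (7, 25, 1),
    "side_effects": (27, 171, 37),
    "daily_pill": (15, 51, 23),
    "medical_reasons": (0, 4, 0),
}

#: reasons cited by non-users, stratified by HIV-specialist density.
#: columns: (low-density, high-density) citing counts
REASONS_BY_DENSITY_N = {"low": 332, "high": 81}
REASONS_BY_DENSITY = {
    "risk_too_low": (80, 29),
    "no_doctor": (70, 12),
    "effort_doctor_visits": (122, 23),
    "discuss_sex_life": (98, 13),
    "negative_reactions": (27, 3),
    "side_effects": (172, 55),
    "daily_pill": (65, 21),
    "medical_reasons": (3, 1),
}


def indication_test_counts() -> dict[str, tuple[int, int, int, int]]:
    """(citing, total) pairs for the tested strata: partners/STI/HCV vs SDU.

    The "both" column is descriptive only and excluded from the 2x2 test.
    """
    n1 = REASONS_BY_INDICATION_N["partners_sti_hcv"]
    n2 = REASONS_BY_INDICATION_N["sdu_only"]
    return {
        reason: (partners, n1, sdu, n2)
        for reason, (_, partners, sdu) in REASONS_BY_INDICATION.items()
    }


def density_test_counts() -> dict[str, tuple[int, int, int, int]]:
    n1 = REASONS_BY_DENSITY_N["low"]
    n2 = REASONS_BY_DENSITY_N["high"]
    return {
        reason: (low, n1, high, n2)
        for reason, (low, high) in REASONS_BY_DENSITY.items()
    }
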