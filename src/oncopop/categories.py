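"""Canonical category spellings and orderings.

Category orderings are fixed so that inverse-CDF sampling is reproducible
across platforms; every probability map is re-ordered to these tuples before
sampling.
"""

from __future__ import annotations

TUMORS: tuple[str, ...] = (
    "breast",
    "colon",
    "endometrial",
    "gastric",
    "hepatic",
    "lung",
    "ovarian",
    "pancreatic",
    "sarcoma",
)

#: Tumor locations that occur only in females; the conditional probability of
#: male given one of these is structurally zero.
FEMALE_ONLY_TUMORS: frozenset[str] = frozenset({"breast", "endometrial", "ovarian"})

#: Tumor group sharing one indicator in the albumin and platelet-lymphocyte
#: ratio equations.
PHG_TUMORS: frozenset[str] = frozenset({"pancreatic", "hepatic", "gastric"})

ORIGINS: tuple[str, ...] = ("European", "Sub-Saharan African", "East Asian")

SEXES: tuple[str, ...] = ("male", "female")

ECOG_LEVELS: tuple[int, ...] = (0, 1, 2)

#: Primary-variable columns of a cohort table (always present, sampled first).
PRIMARY_COLUMNS: tuple[str, ...] = (
    "patient_id",
    "tumor",
    "sex",
    "origin",
    "ecog",
    "age_years",
)

#: Secondary (simulated) variables in network order, by output column name.
RESPONSE_COLUMNS: tuple[str, ...] = (
    "height_cm",
    "weight_kg",
    "aag_mg_dl",
    "albumin_g_dl",
    "hb_g_dl",
    "nl_ratio",
    "pl_ratio",
    "crp_mg_l",
    "ldh_u_l",
    "htc_pct",
)

#: Full documented column order of an emitted cohort table.
COHORT_COLUMNS: tuple[str, ...] = (
    "patient_id",
    "tumor",
    "sex",
    "origin",
    "ecog",
    "age_years",
    "height_cm",
    "weight_kg",
    "bsa_m2",
    "bmi_kg_m2",
    "aag_mg_dl",
    "albumin_g_dl",
    "hb_g_dl",
    "nl_ratio",
    "pl_ratio",
    "crp_mg_l",
    "ldh_u_l",
    "htc_pct",
)
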