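"""The scenario library: reference population and eight extrapolation cohorts.

The reference population reproduces the composition of the source training
cohort (primary-variable marginals and sex-by-tumor conditionals derived
from its printed counts).  Each extrapolation scenario overrides a subset of
the reference fields — every unspecified field inherits the reference value
exactly — and defaults to 1200 patients.
"""

from __future__ import annotations

import zlib
from typing import Iterable

import numpy as np
import pandas as pd

from .categories import RESPONSE_COLUMNS
from .errors import ConfigurationError
from .metrics import DensitySummary, density_summary
from .network import (
    CoefficientSet,
    ResidualSpec,
    default_coefficient_set,
    default_residual_spec,
    simulate_cohort,
)
from .primaries import MomentTarget, PopulationSpec, sample_primaries

#: Probability of male given tumor type, from the cohort's printed
#: sex-by-tumor counts (e.g. 513 of 865 lung cancers in males).
REFERENCE_SEX_GIVEN_TUMOR: dict[str, float] = {
    "breast": 0.0,
    "colon": 12 / 22,
    "endometrial": 0.0,
    "gastric": 5 / 7,
    "hepatic": 9 / 16,
    "lung": 513 / 865,
    "ovarian": 0.0,
    "pancreatic": 43 / 66,
    "sarcoma": 33 / 70,
}

_REFERENCE_FIELDS: dict = {
    "tumor_probs": {
        "breast": 0.07, "colon": 0.01, "endometrial": 0.07, "gastric": 0.01,
        "hepatic": 0.01, "lung": 0.48, "ovarian": 0.28, "pancreatic": 0.04,
        "sarcoma": 0.03,
    },
    "sex_given_tumor": REFERENCE_SEX_GIVEN_TUMOR,
    "origin_probs": {"European": 0.96, "Sub-Saharan African": 0.02, "East Asian": 0.02},
    # printed 35/55/5 (sums to 95%); renormalized at validation
    "ecog_probs": {0: 0.35, 1: 0.55, 2: 0.05},
    "age_targets": {
        "male_nonsarcoma": MomentTarget(mean=62.3, sd=9.3),
        "male_sarcoma": MomentTarget(mean=62.3, sd=9.3),
        "female_nonsarcoma": MomentTarget(mean=59.1, sd=11.2),
        "female_sarcoma": MomentTarget(mean=59.1, sd=11.2),
    },
}

_MALE_TUMOR_MIX = {
    "colon": 0.02, "gastric": 0.02, "hepatic": 0.03, "lung": 0.76,
    "pancreatic": 0.11, "sarcoma": 0.06,
}

_FEMALE_TUMOR_MIX = {
    "breast": 0.10, "colon": 0.02, "endometrial": 0.10, "gastric": 0.01,
    "hepatic": 0.01, "lung": 0.30, "ovarian": 0.40, "pancreatic": 0.03,
    "sarcoma": 0.03,
}

#: Field overrides per scenario; anything absent inherits the reference.
_SCENARIO_OVERRIDES: dict[str, dict] = {
    "reference": {},
    "only_east_asians": {"origin_probs": {"East Asian": 1.0}},
    "only_sub_saharan_africans": {"origin_probs": {"Sub-Saharan African": 1.0}},
    "only_europeans": {"origin_probs": {"European": 1.0}},
    "only_males": {
        "tumor_probs": _MALE_TUMOR_MIX,
        "sex_given_tumor": {t: 1.0 for t in _MALE_TUMOR_MIX},
    },
    "only_females": {
        "tumor_probs": _FEMALE_TUMOR_MIX,
        "sex_given_tumor": {t: 0.0 for t in _FEMALE_TUMOR_MIX},
    },
    "only_ecog2": {"ecog_probs": {2: 1.0}},
    "only_pancreatic": {"tumor_probs": {"pancreatic": 1.0}},
    "only_ovarian": {"tumor_probs": {"ovarian": 1.0}},
}

SCENARIO_NAMES: tuple[str, ...] = tuple(_SCENARIO_OVERRIDES)

#: The eight extrapolation cohorts (everything but the reference).
EXTRAPOLATION_NAMES: tuple[str, ...] = tuple(
    name for name in SCENARIO_NAMES if name != "reference"
)


def reference_population(n: int = 1259, seed: int = 0) -> PopulationSpec:
    """The reference population spec (training-cohort composition)."""
    return PopulationSpec(n=n, seed=seed, **_REFERENCE_FIELDS)


def build_scenario(name: str, n: int | None = None, seed: int = 0) -> PopulationSpec:
    """Resolve a scenario name to a fully specified population.

    ``n`` defaults to 1259 for the reference and 1200 for the extrapolation
    cohorts.
    """
    if name not in _SCENARIO_OVERRIDES:
        raise ConfigurationError(
            f"unknown scenario '{name}'; valid names: {list(SCENARIO_NAMES)}"
        )
    if n is None:
        n = 1259 if name == "reference" else 1200
    fields = {**_REFERENCE_FIELDS, **_SCENARIO_OVERRIDES[name]}
    return PopulationSpec(n=n, seed=seed, **fields)


def scenario_rng(master_seed: int, name: str) -> np.random.Generator:
    """Deterministic per-scenario generator, independent across scenarios.

    The stream is seeded from (master seed, CRC-32 of the scenario name), so
    adding or reordering scenarios never perturbs another scenario's draws.
    """
    return np.random.default_rng(
        np.random.SeedSequence([int(master_seed), zlib.crc32(name.encode())])
    )


def run_extrapolation(
    names: Iterable[str] | None = None,
    n: int = 1200,
    coefs: CoefficientSet | None = None,
    residuals: ResidualSpec | None = None,
    seed: int = 0,
) -> dict[str, tuple[pd.DataFrame, dict[str, DensitySummary]]]:
    """Simulate each scenario and summarize every modeled variable.

    Returns a map from scenario name to (cohort table, per-variable density
    summaries).  Fully reproducible under the master seed.
    """
    if names is None:
        names = EXTRAPOLATION_NAMES
    coefs = coefs if coefs is not None else default_coefficient_set()
    residuals = residuals if residuals is not None else default_residual_spec()
    results: dict[str, tuple[pd.DataFrame, dict[str, DensitySummary]]] = {}
    for name in names:
        spec = build_scenario(name, n=n, seed=seed)
        rng = scenario_rng(seed, name)
        profiles = sample_primaries(spec, rng)
        table = simulate_cohort(profiles, coefs, residuals, rng)
        summaries = {
            var: density_summary(table, var)
            for var in RESPONSE_COLUMNS if var in table.columns
        }
        results[name] = (table, summaries)
    return results
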