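"""Sampling of primary (fixed) patient variables.

Primary variables — tumor type, sex, biogeographic origin, ECOG performance
status and age — are drawn directly from specified distributions and act only
as predictors downstream.  Categorical primaries are multinomial draws over a
fixed category ordering; sex is conditional on tumor type (some tumor
locations occur only in females); age follows a Weibull distribution with a
(sex, sarcoma) group structure, truncated to an adult range by rejection
sampling.

Where Weibull shape/scale values are not supplied directly, they are obtained
by matching the distribution's analytic mean and standard deviation
(one-dimensional root-finding on the coefficient of variation), so that age
groups can be calibrated from published summary statistics.
"""

from __future__ import annotations

import logging
import math
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy.optimize import brentq
from scipy.special import gamma as gamma_fn
from scipy.stats import weibull_min

from .categories import (
    ECOG_LEVELS,
    FEMALE_ONLY_TUMORS,
    ORIGINS,
    PRIMARY_COLUMNS,
    TUMORS,
)
from .errors import ConfigurationError, DomainError

logger = logging.getLogger(__name__)

_PROB_TOL = 1e-9

#: The four (sex, sarcoma) age groups, in sampling order.
AGE_GROUPS: tuple[str, ...] = (
    "male_nonsarcoma",
    "male_sarcoma",
    "female_nonsarcoma",
    "female_sarcoma",
)


def age_group_key(sex: str, sarcoma: bool) -> str:
    return f"{sex}_{'sarcoma' if sarcoma else 'nonsarcoma'}"


class WeibullParams(BaseModel):
    """Weibull shape/scale for one (sex, sarcoma) age group, in years."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    shape: float = Field(gt=0)
    scale: float = Field(gt=0)
    group: str | None = None


class MomentTarget(BaseModel):
    """Mean/SD target (years) resolved to Weibull parameters at sampling time."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    mean: float = Field(gt=0)
    sd: float = Field(gt=0)


AgeTarget = Union[WeibullParams, MomentTarget]


def _normalize_map(
    probs: Mapping, allowed: Sequence, what: str
) -> dict:
    """Validate and renormalize a probability map onto the canonical ordering.

    Missing categories are filled with probability zero; a sum differing from
    one by more than 1e-9 is renormalized with a logged notice (printed
    population tables frequently sum to slightly less than 100% through
    rounding).
    """
    if not probs:
        raise ConfigurationError(f"{what}: empty probability map")
    unknown = set(probs) - set(allowed)
    if unknown:
        raise ConfigurationError(
            f"{what}: unknown categories {sorted(map(str, unknown))}; "
            f"allowed: {list(allowed)}"
        )
    full = {cat: float(probs.get(cat, 0.0)) for cat in allowed}
    for cat, p in full.items():
        if not math.isfinite(p) or p < 0.0:
            raise ConfigurationError(f"{what}[{cat}]: invalid probability {p}")
    total = sum(full.values())
    if total <= 0.0:
        raise ConfigurationError(f"{what}: probabilities sum to zero")
    if abs(total - 1.0) > _PROB_TOL:
        logger.info("%s: probabilities sum to %.6g; renormalizing to 1", what, total)
        full = {cat: p / total for cat, p in full.items()}
    return full


class PopulationSpec(BaseModel):
    """Complete specification of a virtual population's primary variables.

    Probability maps are renormalized to sum to one at validation time and
    re-ordered onto the canonical category orderings.  ``sex_given_tumor``
    holds the probability of *male* conditional on each tumor type and is
    structurally zero for the female-only tumor locations (breast,
    endometrial, ovarian).
    """

    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    n: int = Field(ge=1)
    seed: int = 0
    tumor_probs: dict[str, float]
    sex_given_tumor: dict[str, float]
    origin_probs: dict[str, float]
    ecog_probs: dict[int, float]
    age_targets: dict[str, AgeTarget]
    age_bounds: tuple[float, float] = (18.0, 95.0)

    @model_validator(mode="after")
    def _validate(self) -> "PopulationSpec":
        self.__dict__["tumor_probs"] = _normalize_map(self.tumor_probs, TUMORS, "tumor_probs")
        self.__dict__["origin_probs"] = _normalize_map(self.origin_probs, ORIGINS, "origin_probs")
        self.__dict__["ecog_probs"] = _normalize_map(self.ecog_probs, ECOG_LEVELS, "ecog_probs")

        sgt = {t: float(self.sex_given_tumor.get(t, 0.0)) for t in TUMORS}
        unknown = set(self.sex_given_tumor) - set(TUMORS)
        if unknown:
            raise ValueError(f"sex_given_tumor: unknown tumor categories {sorted(unknown)}")
        for tumor, p_male in sgt.items():
            if not 0.0 <= p_male <= 1.0:
                raise ValueError(f"sex_given_tumor[{tumor}]: {p_male} outside [0, 1]")
            if tumor in FEMALE_ONLY_TUMORS and p_male != 0.0:
                raise ValueError(
                    f"sex_given_tumor[{tumor}] must be 0 (female-only tumor location)"
                )
        self.__dict__["sex_given_tumor"] = sgt

        missing = set(AGE_GROUPS) - set(self.age_targets)
        extra = set(self.age_targets) - set(AGE_GROUPS)
        if missing or extra:
            raise ValueError(
                f"age_targets must cover exactly the groups {list(AGE_GROUPS)}; "
                f"missing={sorted(missing)}, unknown={sorted(extra)}"
            )
        low, high = self.age_bounds
        if not low < high:
            raise ValueError(f"age_bounds: low {low} must be < high {high}")
        return self

    def resolved_age_params(self) -> dict[str, WeibullParams]:
        """Age targets with moment targets converted to Weibull parameters."""
        out: dict[str, WeibullParams] = {}
        for group in AGE_GROUPS:
            target = self.age_targets[group]
            if isinstance(target, MomentTarget):
                params = weibull_from_moments(target.mean, target.sd)
                out[group] = WeibullParams(shape=params.shape, scale=params.scale, group=group)
            else:
                out[group] = target
        return out


def weibull_moments(shape: float, scale: float) -> tuple[float, float]:
    """Analytic (mean, sd) of a Weibull(shape, scale) distribution."""
    g1 = gamma_fn(1.0 + 1.0 / shape)
    g2 = gamma_fn(1.0 + 2.0 / shape)
    mean = scale * g1
    var = scale**2 * (g2 - g1**2)
    return mean, math.sqrt(max(var, 0.0))


def _weibull_cv(shape: float) -> float:
    g1 = gamma_fn(1.0 + 1.0 / shape)
    g2 = gamma_fn(1.0 + 2.0 / shape)
    return math.sqrt(max(g2 / g1**2 - 1.0, 0.0))


def weibull_from_moments(mean: float, sd: float) -> WeibullParams:
    """Solve for Weibull (shape, scale) matching a target mean and SD.

    The coefficient of variation sd/mean depends on the shape alone and is
    strictly decreasing in it, so the shape is found by bracketed
    root-finding and the scale follows from the mean identity
    ``mean = scale * gamma(1 + 1/shape)``.

    Raises
    ------
    DomainError
        If mean or sd is non-positive, or the coefficient of variation
        exceeds 5 (outside any plausible age distribution and close to the
        numerically degenerate regime of sub-unit shapes).
    """
    if not (mean > 0.0 and math.isfinite(mean)):
        raise DomainError(f"mean must be positive, got {mean}")
    if not (sd > 0.0 and math.isfinite(sd)):
        raise DomainError(f"sd must be positive, got {sd}")
    cv = sd / mean
    if cv > 5.0:
        raise DomainError(f"coefficient of variation {cv:.3g} > 5 is not supported")

    lo, hi = 0.15, 1000.0
    if not _weibull_cv(hi) < cv < _weibull_cv(lo):
        raise DomainError(f"coefficient of variation {cv:.3g} outside solvable range")
    shape = brentq(lambda a: _weibull_cv(a) - cv, lo, hi, xtol=1e-13, rtol=1e-14)
    scale = mean / gamma_fn(1.0 + 1.0 / shape)
    return WeibullParams(shape=float(shape), scale=float(scale))


def sample_categories(
    probs: Mapping, n: int, rng: np.random.Generator
) -> list:
    """Draw ``n`` categories by inverse-CDF over the map's key order.

    The map is validated and renormalized first; categories are consumed in
    the order given (specs built through :class:`PopulationSpec` arrive in
    canonical order), making draws reproducible across platforms.
    """
    if n < 1:
        raise ConfigurationError(f"n must be >= 1, got {n}")
    checked = _normalize_map(probs, list(probs), "probability map")
    cats = list(checked)
    cum = np.cumsum([checked[c] for c in cats])
    cum[-1] = 1.0  # guard against rounding in the last bin
    idx = np.searchsorted(cum, rng.random(n), side="right")
    return [cats[i] for i in idx]


def sample_sex_given_tumor(
    tumors: Sequence[str],
    sex_given_tumor: Mapping[str, float],
    rng: np.random.Generator,
) -> list[str]:
    """Draw sex per patient from the probability of male given tumor type."""
    unknown = set(tumors) - set(sex_given_tumor)
    if unknown:
        raise ConfigurationError(
            f"sex_given_tumor: no entry for tumor categories {sorted(unknown)}"
        )
    p_male = np.array([sex_given_tumor[t] for t in tumors], dtype=float)
    male = rng.random(len(tumors)) < p_male
    return ["male" if m else "female" for m in male]


def sample_age(
    params: WeibullParams,
    n: int,
    bounds: tuple[float, float] | None,
    rng: np.random.Generator,
    max_attempts: int = 1000,
) -> np.ndarray:
    """Sample ``n`` ages, truncated to ``bounds`` by rejection resampling.

    Out-of-bounds draws are redrawn up to ``max_attempts`` rounds; any still
    outside afterwards are clamped to the bounds (practically unreachable for
    bounds retaining >= 1% of the mass, which is enforced).
    """
    if n < 1:
        raise ConfigurationError(f"n must be >= 1, got {n}")
    if bounds is None:
        return rng.weibull(params.shape, size=n) * params.scale
    low, high = bounds
    if not low < high:
        raise ConfigurationError(f"bounds: low {low} must be < high {high}")
    dist = weibull_min(params.shape, scale=params.scale)
    mass = dist.cdf(high) - dist.cdf(low)
    if mass < 0.01:
        raise ConfigurationError(
            f"age bounds ({low}, {high}) retain only {mass:.2%} of the "
            f"Weibull(shape={params.shape:.3g}, scale={params.scale:.3g}) mass"
        )
    ages = rng.weibull(params.shape, size=n) * params.scale
    out = (ages < low) | (ages > high)
    attempts = 0
    while out.any() and attempts < max_attempts:
        k = int(out.sum())
        ages[out] = rng.weibull(params.shape, size=k) * params.scale
        out = (ages < low) | (ages > high)
        attempts += 1
    if out.any():
        ages = np.clip(ages, low, high)
    return ages


def sample_primaries(
    spec: PopulationSpec, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Sample a full table of primary profiles for a population.

    Sampling order is tumor, then sex conditional on tumor, then origin and
    ECOG (independent of the rest), then age with Weibull parameters chosen
    by the (sex, sarcoma) group.  Given the spec's seed (or an explicit
    generator) the output is fully reproducible.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = spec.n
    tumors = sample_categories(spec.tumor_probs, n, rng)
    sexes = sample_sex_given_tumor(tumors, spec.sex_given_tumor, rng)
    origins = sample_categories(spec.origin_probs, n, rng)
    ecogs = sample_categories(spec.ecog_probs, n, rng)

    age_params = spec.resolved_age_params()
    tumors_arr = np.array(tumors)
    sexes_arr = np.array(sexes)
    ages = np.empty(n, dtype=float)
    for group in AGE_GROUPS:
        sex, sarcoma_tag = group.split("_")
        mask = (sexes_arr == sex) & ((tumors_arr == "sarcoma") == (sarcoma_tag == "sarcoma"))
        k = int(mask.sum())
        if k:
            ages[mask] = sample_age(age_params[group], k, spec.age_bounds, rng)

    return pd.DataFrame(
        {
            "patient_id": np.arange(1, n + 1),
            "tumor": tumors,
            "sex": sexes,
            "origin": origins,
            "ecog": np.array(ecogs, dtype=int),
            "age_years": ages,
        },
        columns=list(PRIMARY_COLUMNS),
    )
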