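"""The hierarchical simulation network: ten ordered regression stages.

Each stage models one secondary variable as a linear function of primaries
and of secondary variables from strictly earlier stages, on either the
natural scale or the natural-log scale, plus Gaussian residual noise on the
modeled scale.  Stages are evaluated in a fixed order so that every covariate
is available when needed; the default coefficients encode the published
network:

1.  height (cm)         <- age, sex, origin
2.  log weight (kg)     <- height, sex, origin, height x female interaction
3.  log AAG (mg/dL)     <- ECOG, origin, ovarian tumor
4.  albumin (g/dL)      <- age, log AAG, ECOG, origin, panc/hep/gastric tumor
5.  Hb (g/dL)           <- albumin, log AAG, sex
6.  log N-L ratio       <- log AAG, albumin
7.  log P-L ratio       <- Hb, AAG (raw), N-L ratio (raw), panc/hep/gastric
8.  log CRP (mg/L)      <- P-L ratio (raw), ECOG, breast tumor
9.  log LDH (U/L)       <- CRP (raw)
10. hematocrit (%)      <- log AAG, Hb

Mixed covariate scales (a stage using the log of an upstream variable while
another uses it raw) are represented per-term, exactly as published.  The
hematocrit stage is printed with a log-transformed response in the source
equations, but only a linear reading yields physiologic percentages; the
linear reading is the default and the literal one is available via
``default_coefficient_set(htc_log_scale=True)``.

Body surface area (Mosteller) and body mass index are derived, not modeled,
and are recomputed from the emitted height/weight columns.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Literal, Mapping, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .categories import PRIMARY_COLUMNS, RESPONSE_COLUMNS
from .errors import ConfigurationError, DomainError, EvaluationError

logger = logging.getLogger(__name__)

IndicatorLevel = Union[str, int, list]


class Term(BaseModel):
    """One additive term of a stage equation.

    ``scale`` selects how the covariate column enters the linear predictor:
    ``linear`` uses it raw, ``log`` takes its natural log, ``indicator``
    contributes 1 when the column equals ``level`` (or is a member of a list
    ``level``).  Reference levels of categorical covariates are simply
    omitted (implicit coefficient 0).
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    covariate: str
    scale: Literal["linear", "log", "indicator"]
    level: IndicatorLevel | None = None
    coefficient: float

    @model_validator(mode="after")
    def _check_level(self) -> "Term":
        if self.scale == "indicator" and self.level is None:
            raise ValueError(f"indicator term on {self.covariate} needs a level")
        if self.scale != "indicator" and self.level is not None:
            raise ValueError(f"{self.scale} term on {self.covariate} cannot have a level")
        return self

    @property
    def name(self) -> str:
        if self.scale == "indicator":
            lev = "+".join(map(str, self.level)) if isinstance(self.level, list) else self.level
            return f"{self.covariate}[{lev}]"
        if self.scale == "log":
            return f"log({self.covariate})"
        return self.covariate


class InteractionTerm(BaseModel):
    """A numeric covariate times an indicator (e.g. height x female)."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    covariate: str
    scale: Literal["linear", "log"] = "linear"
    by: str
    level: IndicatorLevel
    coefficient: float

    @property
    def name(self) -> str:
        base = f"log({self.covariate})" if self.scale == "log" else self.covariate
        lev = "+".join(map(str, self.level)) if isinstance(self.level, list) else self.level
        return f"{base}:{self.by}[{lev}]"


class EquationSpec(BaseModel):
    """One regression stage: response, scale, intercept and terms."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    id: int = Field(ge=1)
    response: str
    response_scale: Literal["linear", "log"]
    intercept: float
    terms: tuple[Term, ...] = ()
    interactions: tuple[InteractionTerm, ...] = ()

    def covariate_names(self) -> set[str]:
        names = {t.covariate for t in self.terms}
        names |= {t.covariate for t in self.interactions}
        names |= {t.by for t in self.interactions}
        return names

    def param_names(self) -> list[str]:
        return ["intercept"] + [t.name for t in self.terms] + [t.name for t in self.interactions]

    def coefficients(self) -> np.ndarray:
        return np.array(
            [self.intercept]
            + [t.coefficient for t in self.terms]
            + [t.coefficient for t in self.interactions]
        )

    def with_coefficients(self, beta: Iterable[float]) -> "EquationSpec":
        """Copy of this equation with a new coefficient vector (intercept first)."""
        beta = list(map(float, beta))
        expected = 1 + len(self.terms) + len(self.interactions)
        if len(beta) != expected:
            raise ConfigurationError(
                f"stage {self.id}: expected {expected} coefficients, got {len(beta)}"
            )
        terms = tuple(
            t.model_copy(update={"coefficient": b})
            for t, b in zip(self.terms, beta[1 : 1 + len(self.terms)])
        )
        inter = tuple(
            t.model_copy(update={"coefficient": b})
            for t, b in zip(self.interactions, beta[1 + len(self.terms) :])
        )
        return self.model_copy(update={"intercept": beta[0], "terms": terms, "interactions": inter})


def _column(df: pd.DataFrame | Mapping, name: str, stage: int) -> np.ndarray:
    try:
        col = df[name]
    except KeyError:
        raise EvaluationError(f"stage {stage}: missing covariate '{name}'") from None
    return np.asarray(col)


def _term_values(
    term: Term | InteractionTerm, data: pd.DataFrame | Mapping, stage: int
) -> np.ndarray:
    col = _column(data, term.covariate, stage)
    if isinstance(term, InteractionTerm):
        base = np.log(col.astype(float)) if term.scale == "log" else col.astype(float)
        by = _column(data, term.by, stage)
        ind = np.isin(by, term.level) if isinstance(term.level, list) else (by == term.level)
        return base * ind.astype(float)
    if term.scale == "indicator":
        ind = np.isin(col, term.level) if isinstance(term.level, list) else (col == term.level)
        return ind.astype(float)
    col = col.astype(float)
    return np.log(col) if term.scale == "log" else col


def design_matrix(
    eq: EquationSpec, data: pd.DataFrame | Mapping
) -> tuple[np.ndarray, list[str]]:
    """Design matrix (intercept column first) for a stage on a data table."""
    n = len(next(iter(data.values()))) if isinstance(data, Mapping) else len(data)
    cols = [np.ones(n)]
    for term in list(eq.terms) + list(eq.interactions):
        cols.append(np.atleast_1d(_term_values(term, data, eq.id)).astype(float))
    return np.column_stack([np.broadcast_to(c, (n,)) for c in cols]), eq.param_names()


def stage_mean(eq: EquationSpec, covariates: Mapping | pd.DataFrame) -> np.ndarray | float:
    """Deterministic linear predictor of a stage, on its modeled scale.

    Accepts either a cohort table or a single-patient mapping of scalars;
    returns an array or a scalar accordingly.  Pure function, no randomness.
    """
    scalar = False
    if isinstance(covariates, Mapping) and not isinstance(covariates, pd.DataFrame):
        covariates = {k: np.atleast_1d(v) for k, v in covariates.items()}
        scalar = all(v.shape == (1,) for v in covariates.values())
    X, _ = design_matrix(eq, covariates)
    mu = X @ eq.coefficients()
    return float(mu[0]) if scalar and mu.shape == (1,) else mu


class ResidualStage(BaseModel):
    """Residual model for one stage: Gaussian sd on the modeled scale plus a
    bounds policy applied on the natural scale."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    sd: float = Field(ge=0, default=0.0)
    policy: Literal["resample", "clamp", "none"] = "resample"
    bounds: tuple[float, float] = (0.0, math.inf)

    @model_validator(mode="after")
    def _check(self) -> "ResidualStage":
        if not self.bounds[0] < self.bounds[1]:
            raise ValueError(f"bounds {self.bounds}: low must be < high")
        return self


class ResidualSpec(BaseModel):
    """Residual models for the network, keyed by response column."""

    model_config = ConfigDict(extra="forbid")

    stages: dict[str, ResidualStage] = {}

    def stage(self, response: str) -> ResidualStage:
        return self.stages.get(response, ResidualStage(sd=0.0))

    def with_sd(self, response: str, sd: float) -> "ResidualSpec":
        stages = dict(self.stages)
        stages[response] = self.stage(response).model_copy(update={"sd": float(sd)})
        return ResidualSpec(stages=stages)


class CoefficientSet(BaseModel):
    """The full ordered network of stage equations."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    equations: tuple[EquationSpec, ...]

    @model_validator(mode="after")
    def _check_acyclic(self) -> "CoefficientSet":
        available = set(PRIMARY_COLUMNS)
        for eq in self.equations:
            missing = eq.covariate_names() - available
            if missing:
                raise ValueError(
                    f"stage {eq.id} ({eq.response}): covariates {sorted(missing)} "
                    "are neither primaries nor responses of earlier stages"
                )
            if eq.response in available:
                raise ValueError(f"stage {eq.id}: response {eq.response} already defined")
            available.add(eq.response)
        return self

    def responses(self) -> list[str]:
        return [eq.response for eq in self.equations]

    def stage_for(self, response: str) -> EquationSpec:
        for eq in self.equations:
            if eq.response == response:
                return eq
        raise ConfigurationError(f"no stage models response '{response}'")


def _apply_noise(
    eq: EquationSpec,
    mu: np.ndarray,
    residual: ResidualStage,
    rng: np.random.Generator | None,
    max_attempts: int = 1000,
) -> np.ndarray:
    """Add residual noise on the modeled scale, back-transform, apply bounds."""

    def natural(values_model: np.ndarray) -> np.ndarray:
        return np.exp(values_model) if eq.response_scale == "log" else values_model

    if residual.sd == 0.0 or rng is None:
        # zero noise reduces to the (back-transformed) mean exactly
        return natural(np.array(mu, dtype=float))

    y = natural(mu + rng.normal(0.0, residual.sd, size=mu.shape))
    if residual.policy == "none":
        return y
    low, high = residual.bounds
    if residual.policy == "resample":
        out = (y < low) | (y > high)
        attempts = 0
        while out.any() and attempts < max_attempts:
            k = int(out.sum())
            y[out] = natural(mu[out] + rng.normal(0.0, residual.sd, size=k))
            out = (y < low) | (y > high)
            attempts += 1
        if out.any():
            logger.warning(
                "stage %d (%s): %d draws still outside %s after %d resampling "
                "rounds; clamping",
                eq.id, eq.response, int(out.sum()), residual.bounds, max_attempts,
            )
    return np.clip(y, low, high)


def stage_sample(
    eq: EquationSpec,
    covariates: Mapping | pd.DataFrame,
    residual: ResidualStage,
    rng: np.random.Generator | None,
) -> np.ndarray | float:
    """Draw the stage response on its natural scale (mean + residual)."""
    scalar = False
    if isinstance(covariates, Mapping) and not isinstance(covariates, pd.DataFrame):
        covariates = {k: np.atleast_1d(v) for k, v in covariates.items()}
        scalar = all(v.shape == (1,) for v in covariates.values())
    mu = np.atleast_1d(stage_mean(eq, covariates))
    y = _apply_noise(eq, mu, residual, rng)
    return float(y[0]) if scalar and y.shape == (1,) else y


def derive_bsa(height_cm, weight_kg):
    """Body surface area (m^2) by the Mosteller formula,
    sqrt(height_cm * weight_kg / 3600)."""
    height_cm = np.asarray(height_cm, dtype=float)
    weight_kg = np.asarray(weight_kg, dtype=float)
    if np.any(height_cm <= 0) or np.any(weight_kg <= 0):
        raise DomainError("height and weight must be positive")
    out = np.sqrt(height_cm * weight_kg / 3600.0)
    return float(out) if out.ndim == 0 else out


def derive_bmi(height_cm, weight_kg):
    """Body mass index (kg/m^2): weight over squared height in meters."""
    height_cm = np.asarray(height_cm, dtype=float)
    weight_kg = np.asarray(weight_kg, dtype=float)
    if np.any(height_cm <= 0) or np.any(weight_kg <= 0):
        raise DomainError("height and weight must be positive")
    out = weight_kg / (height_cm / 100.0) ** 2
    return float(out) if out.ndim == 0 else out


def simulate_cohort(
    profiles: pd.DataFrame,
    coefs: CoefficientSet,
    residuals: ResidualSpec,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Propagate primary profiles through every network stage.

    Stages run in network order, each consuming previously simulated values;
    derived metrics (BSA, BMI) are appended from the simulated height and
    weight.  With all residual sds zero the output is a deterministic
    function of the primaries.
    """
    required = set(PRIMARY_COLUMNS) - {"patient_id"}
    missing = required - set(profiles.columns)
    if missing:
        raise EvaluationError(f"profiles table missing columns {sorted(missing)}")
    table = profiles.reset_index(drop=True).copy()
    if "patient_id" not in table.columns:
        table.insert(0, "patient_id", np.arange(1, len(table) + 1))
    for eq in coefs.equations:
        mu = np.atleast_1d(stage_mean(eq, table))
        table[eq.response] = _apply_noise(eq, mu, residuals.stage(eq.response), rng)
    if {"height_cm", "weight_kg"} <= set(table.columns):
        table["bsa_m2"] = derive_bsa(table["height_cm"], table["weight_kg"])
        table["bmi_kg_m2"] = derive_bmi(table["height_cm"], table["weight_kg"])
    ordered = [c for c in _cohort_column_order(coefs) if c in table.columns]
    return table[ordered]


def _cohort_column_order(coefs: CoefficientSet) -> list[str]:
    order = list(PRIMARY_COLUMNS)
    for resp in coefs.responses():
        order.append(resp)
        if resp == "weight_kg":
            order += ["bsa_m2", "bmi_kg_m2"]
    return order


# ---------------------------------------------------------------------------
# Default network: the published ten-stage equation table.
# ---------------------------------------------------------------------------

def _ind(covariate: str, level, coefficient: float) -> Term:
    return Term(covariate=covariate, scale="indicator", level=level, coefficient=coefficient)


def _lin(covariate: str, coefficient: float) -> Term:
    return Term(covariate=covariate, scale="linear", coefficient=coefficient)


def _log(covariate: str, coefficient: float) -> Term:
    return Term(covariate=covariate, scale="log", coefficient=coefficient)


PHG = ["pancreatic", "hepatic", "gastric"]


def default_coefficient_set(htc_log_scale: bool = False) -> CoefficientSet:
    """The shipped network coefficients.

    Reference levels (implicit zero coefficients): male, East Asian origin,
    ECOG 0, and tumor locations outside each stage's named group.  The
    height slope of the log-weight stage is 0.012 for males and 0.008 for
    females, encoded as a base slope plus a -0.004 height x female
    interaction.
    """
    equations = (
        EquationSpec(
            id=1, response="height_cm", response_scale="linear", intercept=179.9,
            terms=(
                _lin("age_years", -0.16),
                _ind("sex", "female", -12.81),
                _ind("origin", "Sub-Saharan African", 6.42),
                _ind("origin", "European", 3.83),
            ),
        ),
        EquationSpec(
            id=2, response="weight_kg", response_scale="log", intercept=2.10,
            terms=(
                _lin("height_cm", 0.012),
                _ind("sex", "female", 0.562),
                _ind("origin", "Sub-Saharan African", 0.262),
                _ind("origin", "European", 0.144),
            ),
            interactions=(
                InteractionTerm(covariate="height_cm", by="sex", level="female",
                                coefficient=-0.004),
            ),
        ),
        EquationSpec(
            id=3, response="aag_mg_dl", response_scale="log", intercept=4.32,
            terms=(
                _ind("ecog", 1, 0.161),
                _ind("ecog", 2, 0.449),
                _ind("origin", "Sub-Saharan African", 0.634),
                _ind("origin", "European", 0.370),
                _ind("tumor", "ovarian", 0.622),
            ),
        ),
        EquationSpec(
            id=4, response="albumin_g_dl", response_scale="linear", intercept=5.546,
            terms=(
                _lin("age_years", -0.004),
                _log("aag_mg_dl", -0.292),
                _ind("ecog", 1, -0.128),
                _ind("ecog", 2, -0.429),
                _ind("origin", "Sub-Saharan African", 0.276),
                _ind("origin", "European", 0.248),
                _ind("tumor", PHG, -0.339),
            ),
        ),
        EquationSpec(
            id=5, response="hb_g_dl", response_scale="linear", intercept=12.35,
            terms=(
                _lin("albumin_g_dl", 0.575),
                _log("aag_mg_dl", -0.793),
                _ind("sex", "female", -0.680),
            ),
        ),
        EquationSpec(
            id=6, response="nl_ratio", response_scale="log", intercept=1.47,
            terms=(
                _log("aag_mg_dl", -0.0073),
                _lin("albumin_g_dl", -0.16),
            ),
        ),
        EquationSpec(
            id=7, response="pl_ratio", response_scale="log", intercept=5.52,
            terms=(
                _lin("hb_g_dl", -0.057),
                _lin("aag_mg_dl", 0.0016),
                _lin("nl_ratio", 0.0622),
                _ind("tumor", PHG, -0.204),
            ),
        ),
        EquationSpec(
            id=8, response="crp_mg_l", response_scale="log", intercept=1.394,
            terms=(
                _lin("pl_ratio", 0.002),
                _ind("ecog", 1, 0.368),
                _ind("ecog", 2, 0.598),
                _ind("tumor", "breast", -2.22),
            ),
        ),
        EquationSpec(
            id=9, response="ldh_u_l", response_scale="log", intercept=5.709,
            terms=(_lin("crp_mg_l", 0.001),),
        ),
        EquationSpec(
            id=10, response="htc_pct",
            response_scale="log" if htc_log_scale else "linear",
            intercept=5.93,
            terms=(
                _log("aag_mg_dl", 0.04),
                _lin("hb_g_dl", 2.515),
            ),
        ),
    )
    return CoefficientSet(equations=equations)


def default_residual_spec(htc_sd: float = 3.0) -> ResidualSpec:
    """Shipped residual models: documented sds with physiologic bounds.

    Log-scale stages use sd 0.1 on the log scale; linear stages use 4 cm
    (height), 0.3 g/dL (albumin), 1.0 g/dL (Hb) and ``htc_sd`` percent
    (hematocrit).  Bounds are applied on the natural scale with the
    resample policy.
    """
    pos = (0.0, math.inf)
    stages = {
        "height_cm": ResidualStage(sd=4.0, bounds=pos),
        "weight_kg": ResidualStage(sd=0.1, bounds=pos),
        "aag_mg_dl": ResidualStage(sd=0.1, bounds=pos),
        "albumin_g_dl": ResidualStage(sd=0.3, bounds=(1.0, 6.0)),
        "hb_g_dl": ResidualStage(sd=1.0, bounds=(5.0, 20.0)),
        "nl_ratio": ResidualStage(sd=0.1, bounds=pos),
        "pl_ratio": ResidualStage(sd=0.1, bounds=pos),
        "crp_mg_l": ResidualStage(sd=0.1, bounds=pos),
        "ldh_u_l": ResidualStage(sd=0.1, bounds=pos),
        "htc_pct": ResidualStage(sd=htc_sd, bounds=(15.0, 60.0)),
    }
    return ResidualSpec(stages=stages)
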