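"""Network refitting: train/validation splitting, stage-wise OLS, stepwise
covariate selection, and residual calibration.

The module-level functions are thin wrappers over
:class:`~oncopop.estimator.CovariateNetworkModel`; they exist so that the
fitting path can be scripted without touching estimator state.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ConfigurationError
from .estimator import CovariateNetworkModel, _ols_stage
from .network import (
    CoefficientSet,
    EquationSpec,
    ResidualSpec,
    design_matrix,
    simulate_cohort,
)
from .primaries import PopulationSpec, sample_primaries

logger = logging.getLogger(__name__)


@dataclass
class FitResult:
    """Stage-wise OLS fit: coefficients, uncertainty and fit quality."""

    stage_id: int
    equation: EquationSpec  # template shape, fitted coefficient values
    residual_sd: float
    std_errors: dict[str, float]
    n_used: int
    n_dropped: int
    r_squared: float


@dataclass
class NetworkFit:
    """Ordered stage fits plus the row split used, if any."""

    stages: list[FitResult]
    train_indices: np.ndarray | None = None
    validation_indices: np.ndarray | None = None

    def to_coefficient_set(self) -> CoefficientSet:
        return CoefficientSet(equations=tuple(s.equation for s in self.stages))

    def stage_for(self, response: str) -> FitResult:
        for s in self.stages:
            if s.equation.response == response:
                return s
        raise ConfigurationError(f"no fitted stage for response '{response}'")


def split_train_validation(
    table: pd.DataFrame, fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Random disjoint/exhaustive train-validation split of row positions.

    The training size is ``round(fraction * n)`` (banker's rounding, the
    Python built-in); indices within each set are returned sorted.
    """
    n = len(table)
    if n < 10:
        raise ConfigurationError(f"refusing to split a table of {n} < 10 rows")
    if not 0.0 < fraction < 1.0:
        raise ConfigurationError(f"fraction must be in (0, 1), got {fraction}")
    n_train = int(round(fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    perm = np.random.default_rng(seed).permutation(n)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def fit_stage(table: pd.DataFrame, eq_template: EquationSpec) -> FitResult:
    """OLS fit of one stage on its modeled scale (complete-case rows)."""
    fitted, sd, bse, n_used, r2, dropped, _ = _ols_stage(eq_template, table)
    if dropped:
        logger.info("stage %d: dropped %d incomplete rows", eq_template.id, dropped)
    return FitResult(
        stage_id=eq_template.id,
        equation=fitted,
        residual_sd=sd,
        std_errors=bse,
        n_used=n_used,
        n_dropped=dropped,
        r_squared=r2,
    )


def fit_network(
    table: pd.DataFrame,
    network_template: CoefficientSet | None = None,
    train_indices: np.ndarray | None = None,
    validation_indices: np.ndarray | None = None,
) -> NetworkFit:
    """Fit all stages in network order on observed covariates."""
    est = CovariateNetworkModel(coefficients=network_template)
    sub = table.iloc[train_indices] if train_indices is not None else table
    est.fit(sub)
    stages = [
        FitResult(
            stage_id=info["stage"],
            equation=eq,
            residual_sd=info["residual_sd"],
            std_errors=info["std_errors"],
            n_used=info["n_used"],
            n_dropped=info["n_dropped"],
            r_squared=info["r_squared"],
        )
        for eq, info in zip(est.coefficients_.equations, est.stage_results_)
    ]
    return NetworkFit(stages=stages, train_indices=train_indices,
                      validation_indices=validation_indices)


# ---------------------------------------------------------------------------
# Stepwise covariate selection
# ---------------------------------------------------------------------------

def _term_groups(eq: EquationSpec) -> list[tuple[str, list[int], list[int]]]:
    """Candidate units for stepwise moves.

    Indicator terms sharing a covariate (e.g. the two ECOG levels) enter and
    leave together, as a factor would; each interaction is its own unit.
    Returns (label, term indices, interaction indices) triples.
    """
    groups: dict[str, tuple[list[int], list[int]]] = {}
    order: list[str] = []
    for i, t in enumerate(eq.terms):
        key = t.covariate if t.scale == "indicator" else t.name
        if key not in groups:
            groups[key] = ([], [])
            order.append(key)
        groups[key][0].append(i)
    for j, t in enumerate(eq.interactions):
        key = t.name
        groups[key] = ([], [j])
        order.append(key)
    return [(k, groups[k][0], groups[k][1]) for k in order]


def _subset_equation(eq: EquationSpec, groups, included: frozenset[str]) -> EquationSpec:
    terms = tuple(
        eq.terms[i] for label, t_idx, _ in groups if label in included for i in t_idx
    )
    inter = tuple(
        eq.interactions[j] for label, _, i_idx in groups if label in included for j in i_idx
    )
    return eq.model_copy(update={"terms": terms, "interactions": inter})


def stepwise_select(
    table: pd.DataFrame,
    eq_template: EquationSpec,
    criterion: str = "aic",
    p_enter: float = 0.05,
    p_remove: float = 0.10,
) -> EquationSpec:
    """Bidirectional stepwise selection over the template's candidate terms.

    ``criterion`` is ``"aic"`` (default), ``"bic"``, or ``"pvalue"``
    (F-test entry below ``p_enter``, removal above ``p_remove``).  Returns
    the selected equation with fitted coefficients; if nothing improves on
    the intercept-only model, that model is returned with a logged notice.
    """
    if criterion not in {"aic", "bic", "pvalue"}:
        raise ConfigurationError(f"unknown criterion '{criterion}'")
    groups = _term_groups(eq_template)
    labels = [g[0] for g in groups]

    def ols(included: frozenset[str]):
        eq = _subset_equation(eq_template, groups, included)
        X, names = design_matrix(eq, table)
        y = np.asarray(table[eq_template.response], dtype=float)
        if eq_template.response_scale == "log":
            y = np.log(y)
        return eq, sm.OLS(y, pd.DataFrame(X, columns=names)).fit()

    def ic(res) -> float:
        return float(res.aic if criterion == "aic" else res.bic)

    included: frozenset[str] = frozenset()
    eq_cur, res_cur = ols(included)

    if criterion == "pvalue":
        improved = True
        while improved:
            improved = False
            # forward: add the most significant excluded group
            best = None
            for label in labels:
                if label in included:
                    continue
                eq_try, res_try = ols(included | {label})
                f, p = _group_f_test(res_cur, res_try)
                if p < p_enter and (best is None or p < best[0]):
                    best = (p, label, eq_try, res_try)
            if best is not None:
                included |= {best[1]}
                eq_cur, res_cur = best[2], best[3]
                improved = True
            # backward: drop the least significant included group
            worst = None
            for label in included:
                eq_try, res_try = ols(included - {label})
                f, p = _group_f_test(res_try, res_cur)
                if p > p_remove and (worst is None or p > worst[0]):
                    worst = (p, label, eq_try, res_try)
            if worst is not None:
                included -= {worst[1]}
                eq_cur, res_cur = worst[2], worst[3]
                improved = True
    else:
        best_ic = ic(res_cur)
        improved = True
        while improved:
            improved = False
            moves = [included | {l} for l in labels if l not in included]
            moves += [included - {l} for l in included]
            for cand in moves:
                eq_try, res_try = ols(cand)
                if ic(res_try) < best_ic - 1e-9:
                    best_ic, included, eq_cur, res_cur = ic(res_try), cand, eq_try, res_try
                    improved = True
    if not included:
        logger.info(
            "stage %d (%s): no candidate improves on intercept-only",
            eq_template.id, eq_template.response,
        )
    return eq_cur.with_coefficients(res_cur.params.to_numpy())


def _group_f_test(res_small, res_big) -> tuple[float, float]:
    """F-test of the smaller (nested) model against the larger."""
    from scipy.stats import f as f_dist

    df_num = res_small.df_resid - res_big.df_resid
    if df_num <= 0:
        return 0.0, 1.0
    f = ((res_small.ssr - res_big.ssr) / df_num) / (res_big.ssr / res_big.df_resid)
    p = float(f_dist.sf(f, df_num, res_big.df_resid))
    return float(f), p


# ---------------------------------------------------------------------------
# Residual calibration
# ---------------------------------------------------------------------------

def calibrate_residuals(
    coefs: CoefficientSet,
    spec: PopulationSpec,
    targets: dict[str, float],
    n_sim: int = 10000,
    base_residuals: ResidualSpec | None = None,
    seed: int = 0,
    rel_tol: float = 0.02,
    max_iter: int = 60,
) -> ResidualSpec:
    """Solve per-stage residual sds so simulated marginal sds hit targets.

    ``targets`` maps response columns to marginal standard deviations on the
    stage's modeled scale (natural scale for linear stages, log scale for
    log stages).  Stages are processed in network order so that calibrated
    upstream noise feeds the downstream stages.  For each target the stage
    sd is found by bisection on the simulated marginal sd under common
    random numbers; a target already exceeded by upstream variability alone
    is reported as saturated and assigned sd 0.
    """
    if n_sim < 1000:
        raise ConfigurationError(f"n_sim must be >= 1000, got {n_sim}")
    unknown = set(targets) - set(coefs.responses())
    if unknown:
        raise ConfigurationError(f"targets for unmodeled variables: {sorted(unknown)}")

    residuals = base_residuals if base_residuals is not None else ResidualSpec(stages={})
    profiles = sample_primaries(spec.model_copy(update={"n": int(n_sim)}),
                                np.random.default_rng(seed))

    def marginal_sd(res_spec: ResidualSpec, response: str) -> float:
        table = simulate_cohort(profiles, coefs, res_spec,
                                np.random.default_rng(seed + 1))
        values = np.asarray(table[response], dtype=float)
        if coefs.stage_for(response).response_scale == "log":
            values = np.log(values)
        return float(values.std(ddof=1))

    for eq in coefs.equations:
        response = eq.response
        if response not in targets:
            continue
        target = float(targets[response])
        if target < 0:
            raise ConfigurationError(f"target sd for {response} must be >= 0")
        base_sd = marginal_sd(residuals.with_sd(response, 0.0), response)
        if base_sd >= target * (1.0 - rel_tol):
            if base_sd > target * (1.0 + rel_tol):
                logger.warning(
                    "%s: upstream variability alone gives sd %.4g > target %.4g; "
                    "stage saturated, sd set to 0", response, base_sd, target,
                )
            residuals = residuals.with_sd(response, 0.0)
            continue
        # additive variance on the modeled scale: good starting bracket
        lo, hi = 0.0, 2.0 * np.sqrt(max(target**2 - base_sd**2, 0.0)) + target
        sd = np.sqrt(max(target**2 - base_sd**2, 0.0))
        for _ in range(max_iter):
            got = marginal_sd(residuals.with_sd(response, sd), response)
            if abs(got - target) <= rel_tol * target:
                break
            if got < target:
                lo = sd
            else:
                hi = sd
            sd = 0.5 * (lo + hi)
        residuals = residuals.with_sd(response, sd)
    return residuals
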