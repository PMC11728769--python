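"""Scikit-learn style estimator wrapping the covariate network.

``CovariateNetworkModel`` is a generative model in the mold of estimators
with a ``sample`` method (mixture models, kernel density estimators): ``fit``
refits every stage of the network by ordinary least squares on an observed
patient table, ``predict`` propagates primaries through the network at zero
noise (the verification/validation path), ``sample`` draws complete noisy
virtual patients, and ``score`` returns the mean observed-vs-predicted
R-squared across the modeled variables.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .categories import PRIMARY_COLUMNS
from .errors import ConfigurationError, EvaluationError
from .network import (
    CoefficientSet,
    EquationSpec,
    ResidualSpec,
    ResidualStage,
    default_coefficient_set,
    default_residual_spec,
    design_matrix,
    simulate_cohort,
    stage_mean,
)


def _ols_stage(eq_template: EquationSpec, table: pd.DataFrame):
    """Complete-case OLS of one stage on its modeled scale.

    Returns (fitted EquationSpec, residual sd, std-error map, n used, R^2,
    statsmodels results object).  Uses *observed* upstream covariates, never
    model-predicted ones, so each stage's fit is independent of the others.
    """
    needed = sorted(eq_template.covariate_names() | {eq_template.response})
    missing = [c for c in needed if c not in table.columns]
    if missing:
        raise EvaluationError(
            f"stage {eq_template.id} ({eq_template.response}): table missing "
            f"column(s) {missing}"
        )
    sub = table[needed]
    numeric = sub.select_dtypes(include=[np.number])
    keep = np.ones(len(sub), dtype=bool)
    if len(numeric.columns):
        keep &= np.isfinite(numeric.to_numpy(dtype=float)).all(axis=1)
    keep &= ~sub.isna().any(axis=1).to_numpy()
    dropped = int((~keep).sum())
    sub = sub.loc[keep]

    X, names = design_matrix(eq_template, sub)
    y = np.asarray(sub[eq_template.response], dtype=float)
    if eq_template.response_scale == "log":
        y = np.log(y)
    p = X.shape[1]
    if len(sub) < p + 5:
        raise ConfigurationError(
            f"stage {eq_template.id}: {len(sub)} complete rows < {p + 5} required"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        _, sv, vt = np.linalg.svd(X - X.mean(axis=0), full_matrices=False)
        worst = np.argsort(np.abs(vt[-1]))[::-1][:3]
        raise ConfigurationError(
            f"stage {eq_template.id}: rank-deficient design (rank {rank} < {p}); "
            f"near-collinear columns: {[names[i] for i in worst]}"
        )
    res = sm.OLS(y, pd.DataFrame(X, columns=names)).fit()
    sd = float(np.sqrt(res.ssr / max(res.df_resid, 1)))
    fitted = eq_template.with_coefficients(res.params.to_numpy())
    std_errors = dict(zip(names, map(float, res.bse)))
    return fitted, sd, std_errors, len(sub), float(res.rsquared), dropped, res


class CovariateNetworkModel(BaseEstimator):
    """Hierarchical regression-network model of oncology covariates.

    Parameters
    ----------
    coefficients : CoefficientSet, optional
        Network template.  Before ``fit`` its coefficient values drive
        ``predict``/``sample``; during ``fit`` its structure (responses,
        terms, scales) defines the stage-wise regressions.  Defaults to the
        shipped published network.
    residuals : ResidualSpec, optional
        Residual models for ``sample``.  Defaults to the shipped residual
        spec; ``fit`` re-estimates the per-stage sds.

    Attributes
    ----------
    coefficients_ : CoefficientSet
        Stage equations with fitted coefficients.
    residuals_ : ResidualSpec
        Residual spec with fitted per-stage sds (bounds/policy inherited).
    stage_results_ : list of dict
        Per-stage diagnostics: standard errors, n used, rows dropped, R^2.
    """

    def __init__(self, coefficients: CoefficientSet | None = None,
                 residuals: ResidualSpec | None = None):
        self.coefficients = coefficients
        self.residuals = residuals

    # -- helpers ----------------------------------------------------------
    def _template(self) -> CoefficientSet:
        return self.coefficients if self.coefficients is not None else default_coefficient_set()

    def _residual_template(self) -> ResidualSpec:
        return self.residuals if self.residuals is not None else default_residual_spec()

    def _active(self) -> tuple[CoefficientSet, ResidualSpec]:
        if hasattr(self, "coefficients_"):
            return self.coefficients_, self.residuals_
        return self._template(), self._residual_template()

    # -- estimator API ----------------------------------------------------
    def fit(self, X: pd.DataFrame, y=None) -> "CovariateNetworkModel":
        """Refit every network stage by OLS on an observed patient table."""
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a patient table (pandas DataFrame)")
        template = self._template()
        res_template = self._residual_template()
        equations = []
        residual_stages = dict(res_template.stages)
        self.stage_results_ = []
        for eq in template.equations:
            fitted, sd, bse, n_used, r2, dropped, _ = _ols_stage(eq, X)
            equations.append(fitted)
            base = res_template.stage(eq.response)
            residual_stages[eq.response] = ResidualStage(
                sd=sd, policy=base.policy, bounds=base.bounds
            )
            self.stage_results_.append(
                {
                    "stage": eq.id,
                    "response": eq.response,
                    "std_errors": bse,
                    "n_used": n_used,
                    "n_dropped": dropped,
                    "r_squared": r2,
                    "residual_sd": sd,
                }
            )
        self.coefficients_ = CoefficientSet(equations=tuple(equations))
        self.residuals_ = ResidualSpec(stages=residual_stages)
        self.n_samples_seen_ = len(X)
        return self

    def predict(self, X: pd.DataFrame) -> pd.DataFrame:
        """Zero-noise propagation of primary profiles through the network."""
        coefs, _ = self._active()
        zero = ResidualSpec(stages={})
        return simulate_cohort(X[[c for c in PRIMARY_COLUMNS if c in X.columns]],
                               coefs, zero, rng=None)

    def sample(
        self,
        X: pd.DataFrame | None = None,
        n: int | None = None,
        population=None,
        random_state=None,
    ) -> pd.DataFrame:
        """Draw complete virtual patients.

        Either pass primary profiles ``X`` directly, or a
        :class:`~oncopop.primaries.PopulationSpec` as ``population`` (with
        optional ``n`` override) to sample primaries first.
        """
        from .primaries import sample_primaries

        rng = np.random.default_rng(random_state)
        if X is None:
            if population is None:
                raise ConfigurationError("sample() needs primary profiles or a population spec")
            if n is not None:
                population = population.model_copy(update={"n": int(n)})
            X = sample_primaries(population, rng)
        coefs, residuals = self._active()
        return simulate_cohort(X, coefs, residuals, rng)

    def score(self, X: pd.DataFrame, y=None) -> float:
        """Mean observed-vs-predicted R^2 across modeled variables.

        Computed on each stage's modeled scale (log for log stages), using
        zero-noise predictions from the table's own primaries.
        """
        from .metrics import gof_r2

        coefs, _ = self._active()
        pred = self.predict(X)
        scores = []
        for eq in coefs.equations:
            if eq.response not in X.columns:
                continue
            obs = np.asarray(X[eq.response], dtype=float)
            est = np.asarray(pred[eq.response], dtype=float)
            if eq.response_scale == "log":
                obs, est = np.log(obs), np.log(est)
            scores.append(gof_r2(obs, est).r_squared)
        if not scores:
            raise EvaluationError("table contains none of the modeled responses")
        return float(np.mean(scores))
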