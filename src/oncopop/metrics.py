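"""Verification and validation metrics.

Observed-vs-predicted goodness of fit is summarized by R-squared with
qualitative bands (excellent above 0.9; good on [0.4, 0.9]; modest on
[0.1, 0.4); poor below 0.1).  Normality is assessed by a one-sample
Kolmogorov-Smirnov test with estimated parameters (with a Lilliefors option)
and an automatic log-transform retry, mirroring the standard workflow of
testing raw values first and re-testing the log when normality is rejected.
Distribution comparisons between cohorts are reduced to quantile grids,
normalized histograms and two-sample KS statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DomainError, EvaluationError

Band = Literal["excellent", "good", "modest", "poor"]


def classify_r2_band(r_squared: float) -> Band:
    """Qualitative band for an observed-vs-predicted R-squared.

    Boundary cases are assigned to the closed side of each printed range:
    0.9 and 0.4 belong to "good", 0.1 to "modest".
    """
    if r_squared > 0.9:
        return "excellent"
    if r_squared >= 0.4:
        return "good"
    if r_squared >= 0.1:
        return "modest"
    return "poor"


@dataclass(frozen=True)
class GOFResult:
    r_squared: float
    band: Band
    n: int


def gof_r2(observed, predicted) -> GOFResult:
    """R-squared between observed and predicted values, 1 - SSE/SST.

    The caller chooses the scale (pass log values for log-modeled
    variables).  Invariant to reordering of the pairs.  A constant observed
    vector leaves R-squared undefined and raises.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ConfigurationError(f"length mismatch: {obs.shape} vs {pred.shape}")
    if obs.size < 3:
        raise ConfigurationError(f"need at least 3 pairs, got {obs.size}")
    sst = float(((obs - obs.mean()) ** 2).sum())
    if sst == 0.0:
        raise DomainError("observed vector is constant; R-squared undefined")
    sse = float(((obs - pred) ** 2).sum())
    r2 = 1.0 - sse / sst
    return GOFResult(r_squared=r2, band=classify_r2_band(r2), n=int(obs.size))


@dataclass(frozen=True)
class NormalityResult:
    statistic: float
    pvalue: float
    scale: Literal["raw", "log", "neither"]
    raw_statistic: float
    raw_pvalue: float
    log_statistic: float | None = None
    log_pvalue: float | None = None


def _ks_estimated(values: np.ndarray, lilliefors: bool) -> tuple[float, float]:
    if lilliefors:
        from statsmodels.stats.diagnostic import lilliefors as _lf

        stat, p = _lf(values, dist="norm")
        return float(stat), float(p)
    stat, p = stats.kstest(values, "norm", args=(values.mean(), values.std(ddof=1)))
    return float(stat), float(p)


def ks_normality(
    values, try_log: bool = True, alpha: float = 0.05, lilliefors: bool = False
) -> NormalityResult:
    """One-sample KS normality test with optional log-transform retry.

    Parameters are estimated from the data; without the Lilliefors
    correction the test is conservative (it under-rejects), which is
    acceptable for a screening use.  When the raw scale is rejected at
    ``alpha`` and ``try_log`` is set, the test is repeated on the logs and
    the result reports which scale passed ("neither" if both fail).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 20:
        raise ConfigurationError(f"need at least 20 values, got {x.size}")
    if x.std(ddof=1) == 0.0:
        raise DomainError("constant vector; normality test degenerate")
    if try_log and np.any(x <= 0.0):
        raise DomainError("log retry requested but values are not all positive")
    stat, p = _ks_estimated(x, lilliefors)
    if p >= alpha or not try_log:
        scale = "raw" if p >= alpha else "neither"
        return NormalityResult(stat, p, scale, stat, p)
    lx = np.log(x)
    lstat, lp = _ks_estimated(lx, lilliefors)
    scale = "log" if lp >= alpha else "neither"
    return NormalityResult(
        lstat if scale == "log" else stat,
        lp if scale == "log" else p,
        scale, stat, p, lstat, lp,
    )


@dataclass
class GroupDensity:
    group: str
    n: int
    quantile_probs: np.ndarray
    quantiles: np.ndarray
    bin_edges: np.ndarray
    masses: np.ndarray
    ks_statistic: float | None = None
    ks_pvalue: float | None = None


@dataclass
class DensitySummary:
    """Quantile/histogram summary of one variable, optionally per group and
    against a reference cohort (two-sample KS)."""

    variable: str
    group_by: str | None
    groups: dict[str, GroupDensity] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Long-format export (variable, group, bin_low, bin_high, mass)."""
        rows = []
        for g in self.groups.values():
            for lo, hi, m in zip(g.bin_edges[:-1], g.bin_edges[1:], g.masses):
                rows.append(
                    {"variable": self.variable, "group": g.group,
                     "bin_low": lo, "bin_high": hi, "mass": m}
                )
        return pd.DataFrame(rows)


def density_summary(
    table: pd.DataFrame,
    variable: str,
    group_by: str | None = None,
    reference: pd.DataFrame | None = None,
    bins: int = 30,
) -> DensitySummary:
    """Summarize a variable's distribution: 1%..99% quantiles, a normalized
    histogram, and (if a reference table is given) a two-sample KS per group."""
    if variable not in table.columns:
        raise EvaluationError(f"unknown variable '{variable}'")
    if group_by is not None and group_by not in table.columns:
        raise EvaluationError(f"unknown grouping column '{group_by}'")
    if reference is not None and variable not in reference.columns:
        raise EvaluationError(f"reference table lacks variable '{variable}'")

    out = DensitySummary(variable=variable, group_by=group_by)
    probs = np.arange(1, 100) / 100.0
    items = (
        [("all", table)] if group_by is None
        else [(str(k), g) for k, g in table.groupby(group_by, observed=True)]
    )
    for name, sub in items:
        x = np.asarray(sub[variable], dtype=float)
        x = x[np.isfinite(x)]
        if x.size == 0:
            raise EvaluationError(f"group '{name}' has no finite values of {variable}")
        edges = np.histogram_bin_edges(x, bins=bins)
        counts, edges = np.histogram(x, bins=edges)
        masses = counts / counts.sum()
        ks_stat = ks_p = None
        if reference is not None:
            ref = np.asarray(reference[variable], dtype=float)
            ref = ref[np.isfinite(ref)]
            stat, p = stats.ks_2samp(x, ref)
            ks_stat, ks_p = float(stat), float(p)
        out.groups[name] = GroupDensity(
            group=name, n=int(x.size), quantile_probs=probs,
            quantiles=np.quantile(x, probs), bin_edges=edges, masses=masses,
            ks_statistic=ks_stat, ks_pvalue=ks_p,
        )
    return out


def percent_elevation(group_mean: float, reference_mean: float) -> float:
    """Percent difference of a group mean from a reference mean,
    100 * (group/reference - 1); unrounded."""
    if not reference_mean > 0:
        raise DomainError(f"reference mean must be positive, got {reference_mean}")
    return 100.0 * (float(group_mean) / float(reference_mean) - 1.0)
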