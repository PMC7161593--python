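"""Outcome regressions: conventional adjustment vs weighted MSM fits.

Model 1 is the conventional linear regression of the final-wave outcome on
the cumulative exposure count, adjusting for the time-invariant covariates,
the first-wave values of the time-varying covariates, and the other two
practices' cumulative counts.  Models 2 and 3 are the marginal structural
fits: the same linear form with time-invariant covariates only, estimated by
weighted least squares under the stabilized combined (treatment x attrition)
weights — Model 3 differing from Model 2 only through the weights.

All fits report heteroskedasticity-consistent (sandwich) standard errors;
weights are treated as probability weights, so the sandwich is taken on the
weighted estimating equations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .panel_io import Cohort
from .sleep_metrics import DEFAULT_CUTOFFS, ExposureSeries, derive_exposures
from .weights import WeightSpec, WeightTable, _dummies, compute_weights

OUTCOME_COLUMN = {"cigarette": "outcome_cig", "alcohol": "outcome_alc"}


@dataclass(frozen=True)
class EffectEstimate:
    """Slope of the outcome frequency per additional exposed wave."""

    model: int
    outcome: str
    practice: str
    cutoff: float
    beta: float
    se: float
    n_used: int

    @property
    def ci95(self) -> tuple[float, float]:
        return (self.beta - 1.96 * self.se, self.beta + 1.96 * self.se)

    @property
    def z(self) -> float:
        return self.beta / self.se

    @property
    def pvalue(self) -> float:
        from scipy.stats import norm
        return float(2 * norm.sf(abs(self.z)))

    def stars(self) -> str:
        p = self.pvalue
        return "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""


def _check_full_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # name the aliased columns via pivoted QR
        from scipy.linalg import qr
        _, r, piv = qr(arr, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(arr.shape) * np.finfo(float).eps
        aliased = [X.columns[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
        aliased += [str(c) for c in X.columns[len(diag):]]
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient; aliased columns: {aliased}")


def _baseline_block(cohort: Cohort, covariates) -> pd.DataFrame:
    w1 = cohort.wave_frame(cohort.wave_order[0]).reindex(cohort.persons)
    parts = [_dummies(w1[c], c) for c in covariates]
    return pd.concat(parts, axis=1) if parts \
        else pd.DataFrame(index=cohort.persons)


def _outcome_vector(cohort: Cohort, outcome: str) -> pd.Series:
    col = OUTCOME_COLUMN[outcome]
    w9 = cohort.wave_frame(cohort.outcome_wave).reindex(cohort.persons)
    return w9[col].astype(float)


def fit_conventional(cohort: Cohort, exposure: ExposureSeries, outcome: str,
                     other_exposures: dict[str, ExposureSeries],
                     baseline_covariates=("gender",),
                     wave1_covariates=("depression",)) -> EffectEstimate:
    """Model 1: unweighted OLS with covariate adjustment, robust SE."""
    y = _outcome_vector(cohort, outcome)
    X = pd.DataFrame({"cumulative": exposure.cumulative})
    for p, series in other_exposures.items():
        if p != exposure.practice:
            X[f"cum_{p}"] = series.cumulative
    X = pd.concat([X, _baseline_block(cohort, baseline_covariates),
                   _baseline_block(cohort, wave1_covariates)], axis=1)
    X = sm.add_constant(X, has_constant="add")

    mask = y.notna() & X.notna().all(axis=1)
    Xm, ym = X[mask], y[mask]
    _check_full_rank(Xm)
    res = sm.OLS(ym, Xm).fit(cov_type="HC1")
    return EffectEstimate(1, outcome, exposure.practice, exposure.cutoff,
                          float(res.params["cumulative"]),
                          float(res.bse["cumulative"]), int(mask.sum()))


def fit_msm(cohort: Cohort, exposure: ExposureSeries, outcome: str,
            weight_table: WeightTable, model: int = 2,
            baseline_covariates=("gender",),
            weight_column: str = "truncated") -> EffectEstimate:
    """Models 2/3: weighted least squares of the marginal structural model.

    The formula deliberately omits every time-varying covariate — the
    weights, not the regression, remove the time-varying confounding.
    """
    y = _outcome_vector(cohort, outcome)
    w = weight_table.table[weight_column]
    if not w.index.equals(y.index):
        raise ValueError("weight table and cohort persons do not match")
    if (w <= 0).any() or w.isna().any():
        raise ValueError("weights must be strictly positive")

    X = pd.DataFrame({"cumulative": exposure.cumulative})
    X = pd.concat([X, _baseline_block(cohort, baseline_covariates)], axis=1)
    X = sm.add_constant(X, has_constant="add")

    mask = y.notna() & X.notna().all(axis=1)
    _check_full_rank(X[mask])
    res = sm.WLS(y[mask], X[mask], weights=w[mask]).fit(cov_type="HC1")
    return EffectEstimate(model, outcome, exposure.practice, exposure.cutoff,
                          float(res.params["cumulative"]),
                          float(res.bse["cumulative"]), int(mask.sum()))


# ---------------------------------------------------------------------------
# full analysis grid
# ---------------------------------------------------------------------------

PRACTICE_GRID = {
    "disturbance": (0.0,),
    "short_sleep": (8.0, 7.0, 6.0),
    "social_jetlag": (2.0, 1.0, 0.5),
}


def run_table(cohort: Cohort, practices=PRACTICE_GRID, models=(1, 2, 3),
              outcomes=("cigarette", "alcohol"),
              baseline_covariates=("gender",),
              wave1_covariates=("depression",),
              confounder_covariates=("depression",),
              covariate_cutoffs=DEFAULT_CUTOFFS,
              truncation=None) -> pd.DataFrame:
    """Estimate the full practice x cutoff x model x outcome grid.

    Returns a tidy frame (one row per combination) with the slope, robust
    95% CI, and significance stars, mirroring the usual report layout.
    """
    covariate_series = {
        p: derive_exposures(cohort, p, c, strict_cutoffs=False)
        for p, c in covariate_cutoffs.items()}
    rows = []
    for practice, cutoffs in practices.items():
        for cutoff in cutoffs:
            exposure = derive_exposures(cohort, practice, cutoff,
                                        strict_cutoffs=False)
            weight_tables = {}
            for model in (m for m in models if m in (2, 3)):
                spec = WeightSpec(baseline_covariates=tuple(baseline_covariates),
                                  confounder_covariates=tuple(confounder_covariates),
                                  model=model, truncation=truncation)
                weight_tables[model] = compute_weights(
                    cohort, exposure, spec, covariate_series)
            for outcome in outcomes:
                for model in models:
                    if model == 1:
                        est = fit_conventional(
                            cohort, exposure, outcome, covariate_series,
                            baseline_covariates, wave1_covariates)
                    else:
                        est = fit_msm(cohort, exposure, outcome,
                                      weight_tables[model], model,
                                      baseline_covariates)
                    lo, hi = est.ci95
                    rows.append({
                        "practice": practice, "cutoff": cutoff,
                        "model": model, "outcome": outcome,
                        "beta": est.beta, "se": est.se,
                        "ci_low": lo, "ci_high": hi, "n": est.n_used,
                        "stars": est.stars(),
                    })
    return pd.DataFrame(rows)


def format_table(table: pd.DataFrame) -> pd.DataFrame:
    """Compact 'beta (lo, hi)stars' rendering of a run_table result."""
    out = table.copy()
    out["estimate"] = [
        f"{r.beta:.3f}({r.ci_low:.3f},{r.ci_high:.3f}){r.stars}"
        for r in table.itertuples()]
    return out[["practice", "cutoff", "model", "outcome", "estimate"]]
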