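"""Stabilized inverse-probability weights for treatment and attrition.

Per-wave logistic models are fitted separately at every assessment wave
(waves are unequally spaced, so no pooling over time):

- treatment denominator: P(A_t | A_{t-1}, cum A_{<t}, L_t, V), where L_t are
  the current time-varying covariates (and, for the "adjusted" Model-3
  weights, the other two sleep practices' current indicators);
- treatment numerator: the same model without the time-varying covariates
  (baseline V and exposure history only) — the standard stabilization;
- attrition ("response") models: P(observed at t | A_{t-1}, L_{t-1}, V),
  with the previous wave's covariates carried forward from the last
  observed wave.  Attrition is handled as per-wave response models rather
  than monotone censoring, so persons who return (the final wave is fully
  ascertained) still contribute.

A person's stabilized treatment weight multiplies the numerator/denominator
ratio of the probability of the exposure value actually received over the
waves at which they were observed; the attrition weight multiplies the
ratio of observation probabilities over the same waves.  The combined weight
is their product.  Predicted probabilities are floored/ceiled at ``eps`` to
keep weights finite (a clipped fit is logged, not fatal).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .panel_io import Cohort, MISSING_LEVEL
from .sleep_metrics import ExposureSeries

logger = logging.getLogger(__name__)


class SeparationError(RuntimeError):
    """Raised when an exposure or response model cannot be identified."""


@dataclass
class WeightSpec:
    """Covariate sets and numerical knobs for the weight models.

    ``model=2`` uses the time-varying confounders in the denominator;
    ``model=3`` additionally conditions on the other two sleep practices'
    current-wave indicators ("adjusted" stabilized weights).
    """

    baseline_covariates: tuple[str, ...] = ("gender",)
    confounder_covariates: tuple[str, ...] = ("depression",)
    model: int = 2
    eps: float = 1e-6
    truncation: tuple[float, float] | None = None
    #: waves with fewer dropouts than this are treated as non-informative
    #: (their stabilized attrition factor is exactly 1): a response model on
    #: a handful of events is pure noise.
    min_attrition_events: int = 5

    def __post_init__(self):
        if self.model not in (2, 3):
            raise ValueError("model must be 2 or 3")
        if not (0 < self.eps < 0.5):
            raise ValueError("eps must lie in (0, 0.5)")


@dataclass
class WeightTable:
    """Per-person probabilities and weights defining the pseudo-population."""

    probabilities: pd.DataFrame   # per-wave p_num/p_den/c_num/c_den columns
    table: pd.DataFrame           # iptw, ipaw, combined, truncated

    @property
    def combined(self) -> pd.Series:
        return self.table["combined"]

    @property
    def truncated(self) -> pd.Series:
        return self.table["truncated"]


# ---------------------------------------------------------------------------
# design-matrix helpers
# ---------------------------------------------------------------------------

def _dummies(series: pd.Series, prefix: str) -> pd.DataFrame:
    """Reference-coded dummies; missing values get their own level first."""
    col = series.astype("object").where(series.notna(), MISSING_LEVEL)
    dums = pd.get_dummies(col, prefix=prefix, dtype=float)
    dums = dums.reindex(sorted(dums.columns), axis=1)
    return dums.iloc[:, 1:]  # drop first level as reference


def _drop_degenerate(X: pd.DataFrame) -> pd.DataFrame:
    keep = [c for c in X.columns if c == "const" or X[c].nunique() > 1]
    return X[keep]


def _fit_logit(y: np.ndarray, X: pd.DataFrame, label: str):
    """Fit a logistic regression, translating degeneracy into SeparationError."""
    if len(np.unique(y)) < 2:
        raise SeparationError(
            f"{label}: response takes a single value; model unidentifiable")
    try:
        with np.errstate(all="ignore"):
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100)
    except Exception as exc:  # pragma: no cover - statsmodels internals
        raise SeparationError(f"{label}: logistic fit failed ({exc})") from exc
    if not np.all(np.isfinite(res.params)):
        bad = X.columns[~np.isfinite(res.params)].tolist()
        raise SeparationError(f"{label}: non-finite coefficients for {bad}")
    if np.abs(res.params).max() > 30:
        bad = X.columns[np.argmax(np.abs(res.params.to_numpy()))]
        raise SeparationError(f"{label}: apparent separation on {bad!r}")
    return res


def _baseline_design(cohort: Cohort, spec: WeightSpec) -> pd.DataFrame:
    """Time-invariant covariate dummies, person-indexed."""
    w1 = cohort.wave_frame(cohort.wave_order[0]).reindex(cohort.persons)
    parts = [_dummies(w1[c], c) for c in spec.baseline_covariates]
    return pd.concat(parts, axis=1) if parts else pd.DataFrame(index=cohort.persons)


def _confounder_design(frame: pd.DataFrame, persons: pd.Index,
                       spec: WeightSpec) -> pd.DataFrame:
    parts = [_dummies(frame[c].reindex(persons), c)
             for c in spec.confounder_covariates]
    return pd.concat(parts, axis=1) if parts else pd.DataFrame(index=persons)


def _history_columns(exposure: ExposureSeries, t: int) -> pd.DataFrame:
    """Exposure history: previous-wave indicator and prior cumulative count
    (missing waves count as unexposed, mirroring the cumulative-sum rule)."""
    ind = exposure.indicators
    filled = ind.fillna(0.0)
    prev = filled.iloc[:, t - 1] if t > 0 else pd.Series(0.0, index=ind.index)
    out = pd.DataFrame({"a_prev": prev})
    # the cumulative count is collinear with a_prev until two waves of history
    if t >= 2:
        out["cum_prev"] = filled.iloc[:, :t].sum(axis=1)
    return out


# ---------------------------------------------------------------------------
# treatment models
# ---------------------------------------------------------------------------

def fit_exposure_models(cohort: Cohort, exposure: ExposureSeries,
                        spec: WeightSpec,
                        other_exposures: dict[str, ExposureSeries] | None = None
                        ) -> pd.DataFrame:
    """Per-wave numerator/denominator probabilities of the observed exposure.

    Returns a person-indexed frame with ``p_num_w{wave}`` / ``p_den_w{wave}``
    columns; NaN where the person does not contribute at that wave
    (unobserved or indicator missing).
    """
    if spec.model == 3 and not other_exposures:
        raise ValueError("model 3 requires the other practices' exposures")
    persons = cohort.persons
    base = _baseline_design(cohort, spec)
    out = pd.DataFrame(index=persons)

    for t, wave in enumerate(cohort.exposure_waves):
        a = exposure.indicators.iloc[:, t]
        contribute = a.notna()
        hist = _history_columns(exposure, t)
        conf = _confounder_design(cohort.wave_frame(wave), persons, spec)

        X_num = pd.concat([hist, base], axis=1)
        X_den = pd.concat([hist, conf, base], axis=1)
        if spec.model == 3:
            for p, series in other_exposures.items():
                if p == exposure.practice:
                    continue
                X_den[f"other_{p}"] = series.indicators.iloc[:, t].fillna(0.0)

        rows = contribute.to_numpy()
        y = a[rows].to_numpy(dtype=float)
        label = f"exposure wave {wave}"
        num = _fit_logit(y, _drop_degenerate(
            sm.add_constant(X_num[rows], has_constant="add")), label + " (numerator)")
        den = _fit_logit(y, _drop_degenerate(
            sm.add_constant(X_den[rows], has_constant="add")), label + " (denominator)")

        p1_num = np.clip(num.predict(), spec.eps, 1 - spec.eps)
        p1_den = np.clip(den.predict(), spec.eps, 1 - spec.eps)
        if np.any(den.predict() < spec.eps) or np.any(den.predict() > 1 - spec.eps):
            logger.warning("%s: predicted probabilities clipped at eps", label)

        out.loc[rows, f"p_num_w{wave}"] = np.where(y == 1, p1_num, 1 - p1_num)
        out.loc[rows, f"p_den_w{wave}"] = np.where(y == 1, p1_den, 1 - p1_den)
    return out


def stabilized_iptw(probabilities: pd.DataFrame) -> pd.Series:
    """Product over contributed waves of numerator/denominator probabilities."""
    num_cols = [c for c in probabilities.columns if c.startswith("p_num")]
    den_cols = [c for c in probabilities.columns if c.startswith("p_den")]
    ratio = probabilities[num_cols].to_numpy() / probabilities[den_cols].to_numpy()
    w = np.nanprod(ratio, axis=1)
    return pd.Series(w, index=probabilities.index, name="iptw")


# ---------------------------------------------------------------------------
# attrition models
# ---------------------------------------------------------------------------

def _carried_confounders(cohort: Cohort, spec: WeightSpec) -> dict[int, pd.DataFrame]:
    """Last-observed covariate values before each exposure wave."""
    persons = cohort.persons
    carried = {}
    last = cohort.wave_frame(cohort.wave_order[0])[
        list(spec.confounder_covariates)].reindex(persons)
    for wave in cohort.exposure_waves:
        carried[wave] = last.copy()
        frame = cohort.wave_frame(wave).reindex(persons)
        obs = frame["observed"].fillna(False).astype(bool)
        for c in spec.confounder_covariates:
            vals = frame[c]
            update = obs & vals.notna()
            last.loc[update, c] = vals[update]
    return carried


def fit_attrition_models(cohort: Cohort, exposure: ExposureSeries,
                         spec: WeightSpec) -> pd.DataFrame:
    """Per-wave stabilized observation ("response") probabilities.

    A wave with no attrition contributes probabilities identically 1 (no
    model is fitted, so a fully retained cohort gets weights exactly 1).
    """
    persons = cohort.persons
    base = _baseline_design(cohort, spec)
    carried_all = _carried_confounders(cohort, spec)
    out = pd.DataFrame(index=persons)

    for t, wave in enumerate(cohort.exposure_waves):
        frame = cohort.wave_frame(wave).reindex(persons)
        r = frame["observed"].fillna(False).astype(bool).to_numpy(dtype=float)
        n_dropped = int((r == 0).sum())
        if n_dropped < spec.min_attrition_events:
            if n_dropped:
                logger.info("attrition wave %s: only %d dropouts; treated as "
                            "non-informative", wave, n_dropped)
            out[f"c_num_w{wave}"] = np.where(r == 1, 1.0, np.nan)
            out[f"c_den_w{wave}"] = np.where(r == 1, 1.0, np.nan)
            continue

        hist = _history_columns(exposure, t)
        carried = carried_all[wave]
        conf_parts = [_dummies(carried[c], f"prev_{c}")
                      for c in spec.confounder_covariates]
        conf = pd.concat(conf_parts, axis=1) if conf_parts \
            else pd.DataFrame(index=persons)

        X_num = pd.concat([hist, base], axis=1)
        X_den = pd.concat([hist, conf, base], axis=1)
        label = f"attrition wave {wave}"
        num = _fit_logit(r, _drop_degenerate(
            sm.add_constant(X_num, has_constant="add")), label + " (numerator)")
        den = _fit_logit(r, _drop_degenerate(
            sm.add_constant(X_den, has_constant="add")), label + " (denominator)")

        c_num = np.clip(num.predict(), spec.eps, 1 - spec.eps)
        c_den = np.clip(den.predict(), spec.eps, 1 - spec.eps)
        observed = r == 1
        out.loc[observed, f"c_num_w{wave}"] = c_num[observed]
        out.loc[observed, f"c_den_w{wave}"] = c_den[observed]
        # unobserved waves contribute no factor
    return out


def stabilized_ipaw(probabilities: pd.DataFrame) -> pd.Series:
    num_cols = [c for c in probabilities.columns if c.startswith("c_num")]
    den_cols = [c for c in probabilities.columns if c.startswith("c_den")]
    if not num_cols:
        return pd.Series(1.0, index=probabilities.index, name="ipaw")
    ratio = probabilities[num_cols].to_numpy() / probabilities[den_cols].to_numpy()
    w = np.nanprod(ratio, axis=1)
    return pd.Series(w, index=probabilities.index, name="ipaw")


# ---------------------------------------------------------------------------
# combination, truncation, diagnostics
# ---------------------------------------------------------------------------

def combine_and_truncate(iptw: pd.Series, ipaw: pd.Series,
                         truncation: tuple[float, float] | None = None
                         ) -> pd.DataFrame:
    """Combined = IPTW x IPAW; optional clamping at sample percentiles."""
    if not iptw.index.equals(ipaw.index):
        raise ValueError("IPTW and IPAW indices do not match")
    combined = iptw * ipaw
    table = pd.DataFrame({"iptw": iptw, "ipaw": ipaw, "combined": combined})
    if truncation is None:
        table["truncated"] = combined
    else:
        lo, hi = truncation
        if not (0 < lo < 50 < hi < 100):
            raise ValueError(
                f"truncation percentiles must satisfy 0 < lo < 50 < hi < 100, "
                f"got ({lo}, {hi})")
        qlo, qhi = np.percentile(combined, [lo, hi])
        table["truncated"] = combined.clip(qlo, qhi)
    return table


def compute_weights(cohort: Cohort, exposure: ExposureSeries, spec: WeightSpec,
                    other_exposures: dict[str, ExposureSeries] | None = None
                    ) -> WeightTable:
    """Full weight pipeline: treatment + attrition models -> WeightTable."""
    p_exp = fit_exposure_models(cohort, exposure, spec, other_exposures)
    p_att = fit_attrition_models(cohort, exposure, spec)
    probs = pd.concat([p_exp, p_att], axis=1)
    iptw = stabilized_iptw(probs)
    ipaw = stabilized_ipaw(probs)
    table = combine_and_truncate(iptw, ipaw, spec.truncation)
    if (table["combined"] <= 0).any():
        raise ValueError("non-positive combined weight encountered")
    return WeightTable(probs, table)


def weight_diagnostics(table: pd.DataFrame, column: str = "combined",
                       mean_tolerance: float = 0.05) -> dict:
    """Moments and percentiles of the stabilized weights.

    A mean far from 1 flags numerator/denominator misspecification."""
    w = table[column].to_numpy()
    pct = np.percentile(w, [1, 5, 25, 50, 75, 95, 99])
    summary = {
        "mean": float(w.mean()), "sd": float(w.std(ddof=1)),
        "min": float(w.min()), "max": float(w.max()),
        **{f"p{q}": float(v) for q, v in zip((1, 5, 25, 50, 75, 95, 99), pct)},
        "mean_ok": bool(abs(w.mean() - 1.0) <= mean_tolerance),
    }
    if not summary["mean_ok"]:
        logger.warning("stabilized-weight mean %.3f deviates from 1 by more "
                       "than %.2f", summary["mean"], mean_tolerance)
    return summary


def balance_diagnostics(cohort: Cohort, exposure: ExposureSeries,
                        weights: pd.Series, spec: WeightSpec) -> pd.DataFrame:
    """Weighted confounder-exposure association in the pseudo-population.

    For each wave, fits a weighted logistic regression of the exposure on the
    current time-varying covariates *plus the stabilization covariates*
    (exposure history and baseline), and reports robust z-statistics for the
    time-varying covariate coefficients.  Stabilized weights remove the
    exposure's dependence on the current confounders only conditional on the
    numerator covariates (the history remains in the pseudo-population by
    construction), so that conditional coefficient is the quantity that
    should vanish under correct weighting.
    """
    persons = cohort.persons
    base = _baseline_design(cohort, spec)
    rows = []
    for t, wave in enumerate(cohort.exposure_waves):
        a = exposure.indicators.iloc[:, t]
        mask = a.notna().to_numpy()
        conf = _confounder_design(cohort.wave_frame(wave), persons, spec)
        hist = _history_columns(exposure, t)
        X = pd.concat([conf, hist, base], axis=1)
        X = _drop_degenerate(sm.add_constant(X[mask], has_constant="add"))
        y = a.to_numpy(dtype=float)[mask]
        w = weights[mask].to_numpy()
        res = sm.GLM(y, X, family=sm.families.Binomial(),
                     freq_weights=w).fit(cov_type="HC0")
        for name in conf.columns:
            if name not in X.columns:
                continue
            rows.append({"wave": wave, "covariate": name,
                         "coef": res.params[name], "se": res.bse[name],
                         "z": res.params[name] / res.bse[name]})
    return pd.DataFrame(rows)
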