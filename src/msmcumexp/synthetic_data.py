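"""Synthetic longitudinal cohorts with exposure-confounder feedback.

The generator emulates a six-wave adolescent sleep survey: a binary baseline
covariate ``V`` (emitted as gender, alongside five further time-invariant
survey covariates), a binary time-varying confounder ``L`` (emitted as the
four-band depression score), three per-wave binary sleep practices, interior
wave attrition, item non-response, and continuous substance-use frequency
outcomes at the final wave.

Causal structure (the quantity of interest is the marginal dose-response of
the cumulative count of the *primary* practice):

- ``L_t = 1{ U < lam0 + lam * L_{t-1} + delta * A_{t-1} }`` — a uniform-noise
  threshold, i.e. the confounder responds *linearly in probability* to its
  own past and to the previous exposure.  The linear response keeps the
  counterfactual outcome mean exactly (for ``lam = 0``) or very nearly linear
  in the number of exposed waves, so the dose-response slope is a clean
  estimand.
- ``A_t ~ Bernoulli(expit(a0_t + a_lag A_{t-1} + a_conf L_t + a_base V))`` —
  exposure depends on the *current* confounder, which itself carries the
  feedback from past exposure: L is simultaneously confounder and mediator.
- After the last exposure wave a post-exposure confounder state ``M`` is
  generated the same way (latent; never emitted — the survey does not
  measure depression concurrently with the outcome), so that every exposure
  wave has a downstream mediated path.
- ``Y = th0 + th1 * sum(A) + th_conf * mean(L_2..L_T, M) + th_base V + eps``.

The two nuisance practices follow their own logistic processes driven by
``L`` and their own lag; by default they carry no weight in the primary
exposure's propensity and no outcome effect.

Every latent indicator is emitted as raw survey fields (bed/wake clock
times, disturbance items) such that re-deriving the indicator from the
emitted fields reproduces the latent value exactly (integer-minute
arithmetic with a guard margin around each cutoff).
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit
from scipy.stats import norm

from .panel_io import Cohort, DEFAULT_WAVES, DEPRESSION_BANDS

logger = logging.getLogger(__name__)

PRACTICE_ORDER = ("short_sleep", "social_jetlag", "disturbance")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OutcomeParams:
    """Structural coefficients of one continuous frequency outcome."""

    intercept: float
    slope: float          # effect per exposed wave (direct part)
    confounder: float     # coefficient on the mean mediator/confounder state
    baseline: float       # coefficient on V
    sd: float             # residual noise SD

    def __post_init__(self):
        if self.sd <= 0:
            raise ValueError("outcome noise SD must be positive")


@dataclass(frozen=True)
class AttritionParams:
    """Interior-wave observation process (the final wave is always observed)."""

    base_logit: tuple[float, ...]      # one per interior exposure wave
    on_lag_exposure: float = 0.0
    on_lag_confounder: float = 0.0
    on_baseline: float = 0.0
    monotone: bool = True


@dataclass(frozen=True)
class DGPConfig:
    """Structural parameters of the synthetic cohort.

    Defaults emulate the study conditions of the motivating six-wave survey:
    2,690 entrants; interior-wave retention matching the reported attrition
    pattern (essentially none at the second and third waves, roughly 20% and
    18% at the fourth and fifth); ~7% item non-response on covariates;
    baseline substance users and final-wave outcome non-responders at the
    reported exclusion rates; and per-wave exposure prevalences near the
    published descriptive table for each practice.
    """

    n: int = 2690
    waves: tuple[int, ...] = DEFAULT_WAVES
    primary_practice: str = "short_sleep"
    cutoffs: dict = field(default_factory=lambda: {
        "short_sleep": 8.0, "social_jetlag": 1.0, "disturbance": 0.0})

    # baseline covariate and confounder initialization
    p_baseline: float = 0.5
    p_l0: float = 0.3

    # confounder process (uniform-noise threshold; linear in probability)
    conf_intercept: float = 0.2
    conf_autocorr: float = 0.25
    conf_feedback: float = 0.25

    # primary exposure process (logistic)
    exp_intercepts: tuple[float, ...] = (-0.45, -0.10, 0.22, -0.78, -0.91)
    exp_on_lag: float = 0.5
    exp_on_confounder: float = 1.3
    exp_on_baseline: float = 0.3
    exp_on_others: float = 0.0

    # nuisance practices (logistic on own lag and current confounder)
    other_intercepts: dict = field(default_factory=lambda: {
        "social_jetlag": (0.40, -0.27, -0.73, -0.38, -0.62),
        "disturbance": (-0.43, -0.38, -0.88, -0.21, -0.48)})
    other_on_lag: float = 0.8
    other_on_confounder: float = 0.6

    # outcomes
    outcomes: dict = field(default_factory=lambda: {
        "cigarette": OutcomeParams(0.0, 0.30, 1.5, 0.25, 1.4),
        "alcohol": OutcomeParams(0.3, 0.12, 1.0, 0.20, 1.45)})
    ordinal_outcome: bool = False

    # observation processes
    attrition: AttritionParams | None = AttritionParams(
        base_logit=(6.05, 4.95, 1.56, 1.79),
        on_lag_exposure=-0.2, on_lag_confounder=-0.4, on_baseline=0.0)
    miss_rate: float = 0.07
    baseline_use_rate: float = 206 / 2690
    outcome_missing_rate: float = 806 / 2690

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not (0.0 <= self.miss_rate < 1.0):
            raise ValueError("miss_rate must be in [0, 1)")
        hi = self.conf_intercept + self.conf_autocorr + self.conf_feedback
        lo = self.conf_intercept
        if not (0.0 <= lo and hi <= 1.0):
            raise ValueError(
                "confounder threshold probabilities leave [0, 1]: "
                f"range [{lo}, {hi}]")
        if len(self.exp_intercepts) != self.n_exposure_waves:
            raise ValueError("need one exposure intercept per exposure wave")
        if self.attrition is not None and \
                len(self.attrition.base_logit) != self.n_exposure_waves - 1:
            raise ValueError("need one attrition logit per interior wave")
        if self.primary_practice not in PRACTICE_ORDER:
            raise ValueError(f"unknown practice {self.primary_practice!r}")

    @property
    def n_exposure_waves(self) -> int:
        return len(self.waves) - 1

    @property
    def causal_slope_closed_form(self) -> dict:
        """Per-outcome causal slope th1 + th_conf*delta/T, exact when the
        confounder autocorrelation is zero."""
        T = self.n_exposure_waves
        return {name: p.slope + p.confounder * self.conf_feedback / T
                for name, p in self.outcomes.items()}


def _coerce_config(raw: dict) -> DGPConfig:
    raw = dict(raw)
    if "waves" in raw:
        raw["waves"] = tuple(raw["waves"])
    if "exp_intercepts" in raw:
        raw["exp_intercepts"] = tuple(raw["exp_intercepts"])
    if "other_intercepts" in raw:
        raw["other_intercepts"] = {k: tuple(v)
                                   for k, v in raw["other_intercepts"].items()}
    if "outcomes" in raw:
        raw["outcomes"] = {k: OutcomeParams(**v) if isinstance(v, dict) else v
                           for k, v in raw["outcomes"].items()}
    att = raw.get("attrition", "unset")
    if isinstance(att, dict):
        att = dict(att)
        att["base_logit"] = tuple(att["base_logit"])
        raw["attrition"] = AttritionParams(**att)
    elif att is None:
        raw["attrition"] = None
    return DGPConfig(**raw)


def load_config(path) -> DGPConfig:
    """Load a DGP configuration from a YAML file."""
    with open(path, "r", encoding="utf-8") as fh:
        return _coerce_config(yaml.safe_load(fh) or {})


def load_preset(name: str) -> DGPConfig:
    """Load one of the packaged scenario presets by name.

    Available: ``survey`` (full realism, the defaults), ``confounded``
    (clean recovery scenario: feedback and confounding on, no attrition or
    non-response), ``null`` (no effect, no feedback), ``attrition_informative``,
    ``attrition_noninformative``, and ``twowave`` (small two-exposure-wave
    scenario for exact-oracle checks).
    """
    ref = importlib.resources.files("msmcumexp.presets").joinpath(f"{name}.yaml")
    with ref.open("r", encoding="utf-8") as fh:
        return _coerce_config(yaml.safe_load(fh) or {})


# ---------------------------------------------------------------------------
# raw-field emission
# ---------------------------------------------------------------------------

def emit_raw_sleep(rng: np.random.Generator, short: np.ndarray,
                   jetlag: np.ndarray, disturb: np.ndarray,
                   cutoffs: dict) -> dict:
    """Emit raw survey fields reproducing the three latent indicators exactly.

    Integer-minute construction: the weekly average equals the drawn target
    exactly ((5*(m-2u) + 2*(m+5u))/7 = m), and the bedtime difference equals
    the drawn jetlag exactly, so re-derivation cannot flip an indicator.  A
    6-minute guard separates every draw from its cutoff.
    """
    n = short.shape[0]
    c_sleep = int(round(cutoffs["short_sleep"] * 60))
    c_jet = int(round(cutoffs["social_jetlag"] * 60))
    if c_sleep - 150 < 200 or c_jet < 30:
        raise ValueError("infeasible emission bounds for the given cutoffs")

    # target weekly average sleep, minutes
    m_exp = rng.integers(c_sleep - 150, c_sleep - 5, size=n)
    m_une = rng.integers(c_sleep + 6, c_sleep + 91, size=n)
    m = np.where(short == 1, m_exp, m_une)
    u = rng.integers(0, 13, size=n)          # weekend-weekday split, x7 minutes
    d_wd, d_we = m - 2 * u, m + 5 * u

    wd_bed = rng.integers(1320, 1470, size=n)        # 22:00-24:29
    j_exp = rng.integers(c_jet, c_jet + 121, size=n)
    j_une = rng.integers(-30, c_jet - 5, size=n)
    j = np.where(jetlag == 1, j_exp, j_une)
    we_bed = wd_bed + j

    items = np.zeros((n, 3), dtype=float)
    pos = disturb == 1
    items[pos, 0] = 1 + rng.binomial(3, 0.3, size=int(pos.sum()))
    items[pos, 1] = rng.binomial(2, 0.25, size=int(pos.sum()))
    items[pos, 2] = rng.binomial(2, 0.25, size=int(pos.sum()))

    return {
        "wd_bed": (wd_bed % 1440).astype(float),
        "wd_wake": ((wd_bed + d_wd) % 1440).astype(float),
        "we_bed": (we_bed % 1440).astype(float),
        "we_wake": ((we_bed + d_we) % 1440).astype(float),
        "dist_insomnia": items[:, 0],
        "dist_early_wake": items[:, 1],
        "dist_night_wake": items[:, 2],
    }


_TI_LEVELS = {
    "school_urbanization": (("Taipei City", "New Taipei City", "Yilan County"),
                            (0.377, 0.379, 0.244)),
    "township_type": (("core city", "general city", "emerging towns",
                       "general towns", "aging towns"),
                      (0.482, 0.275, 0.135, 0.081, 0.027)),
    "pubertal_timing": (("early", "on-time", "late"), (0.068, 0.346, 0.586)),
    "expected_achievement": (("below college", "college or above"),
                             (0.246, 0.754)),
    "father_ethnicity": (("Weinan Islanders", "Hakka", "mainlanders",
                          "original residents", "others"),
                         (0.776, 0.081, 0.119, 0.008, 0.016)),
}


def _emit_depression(rng, high: np.ndarray) -> np.ndarray:
    """Map the binary latent confounder onto the four depression bands.

    Low maps into the two low bands, high into the two high bands, so the
    latent value is exactly recoverable from the band."""
    n = high.shape[0]
    low_band = np.where(rng.random(n) < 0.42, DEPRESSION_BANDS[0],
                        DEPRESSION_BANDS[1])
    high_band = np.where(rng.random(n) < 0.92, DEPRESSION_BANDS[2],
                         DEPRESSION_BANDS[3])
    return np.where(high == 1, high_band, low_band)


def depression_to_binary(band: pd.Series) -> pd.Series:
    """Recover the binary high/low confounder from the depression bands."""
    return band.isin([DEPRESSION_BANDS[2], DEPRESSION_BANDS[3]]).astype(float) \
        .where(band.notna() & (band != "MISSING"))


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class Truth:
    """Latent bookkeeping for one simulated cohort (test-only oracle data)."""

    frame: pd.DataFrame                  # wide per-person latent variables
    injected_missing: dict               # variable -> count of injected NAs

    def latent_exposures(self, practice: str, waves) -> pd.DataFrame:
        cols = [f"{practice}_w{w}" for w in waves]
        return self.frame[cols]


def simulate_cohort(config: DGPConfig, seed) -> tuple[Cohort, Truth]:
    """Generate one cohort plus its latent truth; reproducible given seed."""
    rng = np.random.default_rng(seed)
    n, T = config.n, config.n_exposure_waves
    exposure_waves = config.waves[1:]

    V = (rng.random(n) < config.p_baseline).astype(float)
    L0 = (rng.random(n) < config.p_l0).astype(float)

    L = np.zeros((T, n))
    lat = {p: np.zeros((T, n)) for p in PRACTICE_ORDER}
    R = np.ones((T, n), dtype=bool)

    L_prev, A_prev = L0, np.zeros(n)
    other_prev = {p: np.zeros(n) for p in PRACTICE_ORDER
                  if p != config.primary_practice}
    R_prev = np.ones(n, dtype=bool)

    for t in range(T):
        p_l = config.conf_intercept + config.conf_autocorr * L_prev \
            + config.conf_feedback * A_prev
        L[t] = (rng.random(n) < p_l).astype(float)

        others_sum = np.zeros(n)
        for p in PRACTICE_ORDER:
            if p == config.primary_practice:
                continue
            logit = config.other_intercepts[p][t] \
                + config.other_on_lag * other_prev[p] \
                + config.other_on_confounder * L[t]
            lat[p][t] = (rng.random(n) < expit(logit)).astype(float)
            other_prev[p] = lat[p][t]
            others_sum += lat[p][t]

        logit = config.exp_intercepts[t] + config.exp_on_lag * A_prev \
            + config.exp_on_confounder * L[t] + config.exp_on_baseline * V \
            + config.exp_on_others * others_sum
        lat[config.primary_practice][t] = (rng.random(n) < expit(logit)).astype(float)

        if t < T - 1 and config.attrition is not None:
            att = config.attrition
            g = att.base_logit[t] + att.on_lag_exposure * A_prev \
                + att.on_lag_confounder * L_prev + att.on_baseline * V
            R[t] = rng.random(n) < expit(g)
            if att.monotone:
                R[t] &= R_prev
        R_prev = R[t]

        A_prev, L_prev = lat[config.primary_practice][t], L[t]

    # post-exposure confounder state (latent mediator of the last wave)
    p_m = config.conf_intercept + config.conf_autocorr * L[T - 1] \
        + config.conf_feedback * lat[config.primary_practice][T - 1]
    M = (rng.random(n) < p_m).astype(float)

    cum = lat[config.primary_practice].sum(axis=0)
    mediator_mean = (L[1:].sum(axis=0) + M) / T
    Y = {}
    for name, par in config.outcomes.items():
        y = par.intercept + par.slope * cum + par.confounder * mediator_mean \
            + par.baseline * V + rng.normal(0.0, par.sd, size=n)
        if config.ordinal_outcome:
            y = np.clip(np.round(y), 0, 7)
        Y[name] = y

    # ----- survey emission -------------------------------------------------
    pid = np.array([f"p{i:06d}" for i in range(n)])
    ti = {"gender": np.where(V == 1, "male", "female")}
    for col, (levels, probs) in _TI_LEVELS.items():
        pr = np.asarray(probs) / np.sum(probs)
        ti[col] = rng.choice(levels, size=n, p=pr)

    ever = np.where(rng.random(n) < config.baseline_use_rate, "yes", "no")
    outcome_missing = rng.random(n) < config.outcome_missing_rate

    injected = {"depression": 0, "self_rated_health": 0, "cram_school": 0}
    rows = []

    # wave 1: covariates only (sleep assessed from the second wave on)
    w1 = {"pid": pid, "wave": config.waves[0], "observed": True, **ti,
          "ever_substance": ever,
          "depression": _emit_depression(rng, L0),
          "self_rated_health": np.where(
              rng.random(n) < 0.05 + 0.08 * L0, "bad", "good"),
          "cram_school": np.where(rng.random(n) < 0.65, "yes", "no")}
    rows.append(pd.DataFrame(w1))

    for t, wave in enumerate(exposure_waves):
        fields = emit_raw_sleep(rng, lat["short_sleep"][t],
                                lat["social_jetlag"][t], lat["disturbance"][t],
                                config.cutoffs)
        depression = _emit_depression(rng, L[t])
        srh = np.where(rng.random(n) < 0.05 + 0.08 * L[t], "bad", "good")
        cram = np.where(rng.random(n) < max(0.65 - 0.1 * t, 0.1), "yes", "no")
        frame = pd.DataFrame({"pid": pid, "wave": wave, "observed": R[t], **ti,
                              **fields, "depression": depression,
                              "self_rated_health": srh, "cram_school": cram})
        # item non-response on covariates at observed waves
        if config.miss_rate > 0:
            for col in ("depression", "self_rated_health", "cram_school"):
                hit = (rng.random(n) < config.miss_rate) & R[t]
                frame.loc[hit, col] = np.nan
                injected[col] += int(hit.sum())
        if wave == config.waves[-1]:
            for name, col in (("cigarette", "outcome_cig"),
                              ("alcohol", "outcome_alc")):
                y = Y[name].copy()
                y[outcome_missing] = np.nan
                frame[col] = y
        # unobserved waves carry no wave-specific fields
        wave_cols = [c for c in frame.columns
                     if c not in ("pid", "wave", "observed", *ti.keys())]
        frame.loc[~R[t], wave_cols] = np.nan
        rows.append(frame)

    data = pd.concat(rows, ignore_index=True)
    data = data.sort_values(["pid", "wave"], kind="stable").reset_index(drop=True)
    cohort = Cohort(data, wave_order=tuple(config.waves))

    truth_cols = {"pid": pid, "V": V, "L_w1": L0, "M_post": M,
                  "ever_substance": ever, "outcome_missing": outcome_missing}
    for t, wave in enumerate(exposure_waves):
        truth_cols[f"L_w{wave}"] = L[t]
        truth_cols[f"R_w{wave}"] = R[t].astype(float)
        for p in PRACTICE_ORDER:
            truth_cols[f"{p}_w{wave}"] = lat[p][t]
    for name in config.outcomes:
        truth_cols[f"Y_{name}"] = Y[name]
    truth = pd.DataFrame(truth_cols).set_index("pid")
    truth[f"cum_{config.primary_practice}"] = cum

    return cohort, Truth(truth, injected)


# ---------------------------------------------------------------------------
# g-formula oracle
# ---------------------------------------------------------------------------

def _mediator_means_under_regime(config: DGPConfig, regime) -> np.ndarray:
    """E[L_t(a-bar)] for t = 1..T plus the post-exposure state, by forward
    recursion (exact, because the confounder responds linearly)."""
    regime = np.asarray(regime, dtype=float)
    T = config.n_exposure_waves
    if regime.shape != (T,):
        raise ValueError(f"regime must have length {T}")
    el = np.empty(T + 1)
    prev, a_prev = config.p_l0, 0.0
    for t in range(T):
        prev = config.conf_intercept + config.conf_autocorr * prev \
            + config.conf_feedback * a_prev
        el[t] = prev
        a_prev = regime[t]
    el[T] = config.conf_intercept + config.conf_autocorr * el[T - 1] \
        + config.conf_feedback * regime[T - 1]
    return el


def counterfactual_mean(config: DGPConfig, regime, outcome: str = "cigarette",
                        method: str = "auto") -> float:
    """E[Y(a-bar)]: expected outcome had everyone followed regime ``a-bar``.

    For the continuous outcome this is available in closed form by forward
    recursion of the confounder means.  For the ordinal (rounded/clamped)
    outcome the expectation is taken by exact enumeration over all latent
    confounder branches, with the rounding handled through the normal CDF.
    """
    par = config.outcomes[outcome]
    regime = np.asarray(regime, dtype=float)
    T = config.n_exposure_waves
    if method == "auto":
        method = "ordinal" if config.ordinal_outcome else "linear"

    if method == "linear":
        el = _mediator_means_under_regime(config, regime)
        mediator = (el[1:T].sum() + el[T]) / T
        return float(par.intercept + par.slope * regime.sum()
                     + par.confounder * mediator
                     + par.baseline * config.p_baseline)

    # exact branch enumeration (V, L_1..L_T, M); 2^(T+2) branches
    states = np.array(np.meshgrid(*([[0.0, 1.0]] * (T + 2)),
                                  indexing="ij")).reshape(T + 2, -1).T
    total = 0.0
    for v in (0.0, 1.0):
        pv = config.p_baseline if v == 1 else 1 - config.p_baseline
        for branch in states:
            l_chain, m_state = branch[:T + 1], branch[T + 1]
            # l_chain[0] is the first-wave baseline state L_w1
            prob = config.p_l0 if l_chain[0] == 1 else 1 - config.p_l0
            a_prev = 0.0
            for t in range(T):
                p_l = config.conf_intercept + config.conf_autocorr * l_chain[t] \
                    + config.conf_feedback * a_prev
                prob *= p_l if l_chain[t + 1] == 1 else 1 - p_l
                a_prev = regime[t]
            p_m = config.conf_intercept + config.conf_autocorr * l_chain[T] \
                + config.conf_feedback * regime[T - 1]
            prob *= p_m if m_state == 1 else 1 - p_m
            if prob == 0.0:
                continue
            mediator = (l_chain[2:].sum() + m_state) / T
            mu = par.intercept + par.slope * regime.sum() \
                + par.confounder * mediator + par.baseline * v
            if config.ordinal_outcome:
                ks = np.arange(1, 8)
                ey = np.sum(1 - norm.cdf((ks - 0.5 - mu) / par.sd))
            else:
                ey = mu
            total += pv * prob * ey
    return float(total)

    # NOTE: l_chain indexing — l_chain[0] = L at wave 1 (pre-exposure),
    # l_chain[1..T] = L at the T exposure waves; the mediator mean excludes
    # l_chain[1] (the first exposure wave's confounder has no upstream
    # exposure) and includes the post-exposure state.


def all_regimes(T: int) -> np.ndarray:
    """All 2^T fixed exposure regimes, one per row."""
    return np.array(np.meshgrid(*([[0, 1]] * T), indexing="ij")) \
        .reshape(T, -1).T.astype(float)


def oracle_slope(config: DGPConfig, outcome: str = "cigarette",
                 method: str = "auto") -> float:
    """Marginal dose-response slope: the least-squares slope of E[Y(a-bar)]
    on sum(a-bar) over all 2^T regimes (the MSM estimand)."""
    regimes = all_regimes(config.n_exposure_waves)
    means = np.array([counterfactual_mean(config, r, outcome, method)
                      for r in regimes])
    dose = regimes.sum(axis=1)
    X = np.column_stack([np.ones_like(dose), dose])
    beta, *_ = np.linalg.lstsq(X, means, rcond=None)
    return float(beta[1])


def marginal_exposure_prevalence(config: DGPConfig) -> np.ndarray:
    """Per-wave P(A_t = 1) for the primary practice by exact forward
    recursion over the joint (L_t, A_t) chain, averaged over V.

    Requires the primary propensity not to load on the nuisance practices.
    """
    if config.exp_on_others != 0.0:
        raise ValueError("prevalence recursion requires exp_on_others == 0")
    T = config.n_exposure_waves
    prev = np.empty(T)
    acc = np.zeros(T)
    for v, pv in ((0.0, 1 - config.p_baseline), (1.0, config.p_baseline)):
        # state distribution over (L, A)
        dist = {(l, a): 0.0 for l in (0, 1) for a in (0, 1)}
        dist[(1, 0)] = config.p_l0
        dist[(0, 0)] = 1 - config.p_l0
        for t in range(T):
            new = {(l, a): 0.0 for l in (0, 1) for a in (0, 1)}
            for (l_prev, a_prev), p in dist.items():
                if p == 0.0:
                    continue
                p_l = config.conf_intercept + config.conf_autocorr * l_prev \
                    + config.conf_feedback * a_prev
                for l in (0, 1):
                    pl = p_l if l == 1 else 1 - p_l
                    p_a = expit(config.exp_intercepts[t]
                                + config.exp_on_lag * a_prev
                                + config.exp_on_confounder * l
                                + config.exp_on_baseline * v)
                    for a in (0, 1):
                        new[(l, a)] += p * pl * (p_a if a == 1 else 1 - p_a)
            dist = new
            acc[t] += pv * (dist[(0, 1)] + dist[(1, 1)])
    return acc
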