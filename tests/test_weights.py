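"""Weight machinery: hand values, stabilization, attrition factors, errors."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import msmcumexp as mx
from msmcumexp.weights import combine_and_truncate, stabilized_iptw


def _prob_frame(**cols):
    return pd.DataFrame(cols, index=pd.Index(["p1"], name="pid"))


class TestHandValues:
    def test_single_wave_exposed(self):
        probs = _prob_frame(p_num_w2=[0.6], p_den_w2=[0.3])
        assert stabilized_iptw(probs).iloc[0] == pytest.approx(2.0)

    def test_single_wave_unexposed_complement(self):
        # probabilities stored are those of the observed value: 1-0.6, 1-0.3
        probs = _prob_frame(p_num_w2=[0.4], p_den_w2=[0.7])
        assert stabilized_iptw(probs).iloc[0] == pytest.approx(0.4 / 0.7)

    def test_two_wave_product(self):
        probs = _prob_frame(p_num_w2=[0.6], p_den_w2=[0.3],
                            p_num_w3=[0.2], p_den_w3=[0.4])
        assert stabilized_iptw(probs).iloc[0] == pytest.approx(1.0)

    def test_censored_wave_excluded_from_product(self):
        probs = _prob_frame(p_num_w2=[0.6], p_den_w2=[0.3],
                            p_num_w3=[np.nan], p_den_w3=[np.nan])
        assert stabilized_iptw(probs).iloc[0] == pytest.approx(2.0)


class TestCombineTruncate:
    def test_product(self):
        t = combine_and_truncate(pd.Series([2.0]), pd.Series([1.5]))
        assert t["combined"].iloc[0] == pytest.approx(3.0)
        assert t["truncated"].equals(t["combined"])

    def test_truncation_clamps_at_percentiles(self):
        rng = np.random.default_rng(3)
        w = pd.Series(rng.lognormal(0, 1, 500))
        ones = pd.Series(1.0, index=w.index)
        t = combine_and_truncate(w, ones, truncation=(1, 99))
        lo, hi = np.percentile(w, [1, 99])
        assert t["truncated"].min() == pytest.approx(lo)
        assert t["truncated"].max() == pytest.approx(hi)
        assert (t["combined"] == w).all()    # untruncated column retained

    @pytest.mark.parametrize("bad", [(99, 1), (0, 99), (40, 45), (1, 101)])
    def test_bad_percentile_pair(self, bad):
        with pytest.raises(ValueError, match="percentile"):
            combine_and_truncate(pd.Series([1.0]), pd.Series([1.0]),
                                 truncation=bad)


@pytest.fixture(scope="module")
def confounded_small():
    config = replace(mx.load_preset("confounded"), n=1200)
    cohort, truth = mx.simulate_cohort(config, 21)
    cohort = mx.encode_missing_indicator(cohort, ["depression"])
    exposure = mx.derive_exposures(cohort, "short_sleep", 8.0)
    others = mx.derive_all_exposures(cohort, config.cutoffs)
    return config, cohort, exposure, others


class TestExposureModels:
    def test_recovers_propensity_coefficient(self, confounded_small):
        """Denominator fit on the true (binary) confounder recovers the
        generator's logistic coefficient within 3 SE."""
        import statsmodels.api as sm
        from msmcumexp.synthetic_data import depression_to_binary

        config, cohort, exposure, _ = confounded_small
        wave = 3
        t = 1
        frame = cohort.wave_frame(wave).reindex(cohort.persons)
        l_bin = depression_to_binary(frame["depression"])
        a = exposure.indicators.iloc[:, t]
        a_prev = exposure.indicators.iloc[:, t - 1]
        v = (cohort.wave_frame(1).reindex(cohort.persons)["gender"]
             == "male").astype(float)
        mask = a.notna() & l_bin.notna()
        X = sm.add_constant(pd.DataFrame({
            "a_prev": a_prev[mask], "L": l_bin[mask], "V": v[mask]}))
        res = sm.GLM(a[mask], X, family=sm.families.Binomial()).fit()
        assert abs(res.params["L"] - config.exp_on_confounder) \
            < 3 * res.bse["L"]

    def test_all_zero_exposure_raises_separation(self, twowave_cohort):
        _, cohort, _ = twowave_cohort
        data = cohort.data.copy()
        obs = data["observed"].astype(bool) & (data["wave"] != 1)
        for col in ("dist_insomnia", "dist_early_wake", "dist_night_wake"):
            data.loc[obs, col] = 0.0
        zeroed = cohort.with_data(data)
        exposure = mx.derive_exposures(zeroed, "disturbance", 0.0,
                                       strict_cutoffs=False)
        with pytest.raises(mx.SeparationError, match="single value"):
            mx.fit_exposure_models(zeroed, exposure, mx.WeightSpec())

    def test_identical_covariate_sets_give_unit_weights(self, confounded_small):
        """With no time-varying covariates the numerator and denominator
        models coincide, so every weight is exactly 1."""
        _, cohort, exposure, others = confounded_small
        spec = mx.WeightSpec(confounder_covariates=())
        wt = mx.compute_weights(cohort, exposure, spec, others)
        assert np.allclose(wt.table["iptw"], 1.0, atol=1e-10)

    def test_model3_conditions_on_other_practices(self, confounded_small):
        _, cohort, exposure, others = confounded_small
        wt2 = mx.compute_weights(cohort, exposure,
                                 mx.WeightSpec(model=2), others)
        wt3 = mx.compute_weights(cohort, exposure,
                                 mx.WeightSpec(model=3), others)
        assert not np.allclose(wt2.table["iptw"], wt3.table["iptw"])
        with pytest.raises(ValueError, match="other"):
            mx.compute_weights(cohort, exposure, mx.WeightSpec(model=3), None)


class TestStabilization:
    def test_weight_mean_near_one(self, confounded_small):
        _, cohort, exposure, others = confounded_small
        wt = mx.compute_weights(cohort, exposure, mx.WeightSpec(), others)
        diag = mx.weight_diagnostics(wt.table)
        assert abs(diag["mean"] - 1.0) < 0.05
        assert diag["min"] > 0

    def test_null_process_gives_unit_weights_up_to_noise(self):
        config = replace(mx.load_preset("null"), n=1500)
        cohort, _ = mx.simulate_cohort(config, 8)
        cohort = mx.encode_missing_indicator(cohort, ["depression"])
        exposure = mx.derive_exposures(cohort, "short_sleep", 8.0)
        wt = mx.compute_weights(cohort, exposure, mx.WeightSpec(), None)
        assert abs(wt.table["combined"].mean() - 1.0) < 0.05
        assert wt.table["combined"].std() < 0.2


class TestAttritionWeights:
    def test_full_retention_gives_unit_ipaw(self, confounded_small):
        _, cohort, exposure, others = confounded_small
        wt = mx.compute_weights(cohort, exposure, mx.WeightSpec(), others)
        assert (wt.table["ipaw"] == 1.0).all()

    def test_noninformative_attrition_ipaw_near_one(self):
        config = replace(mx.load_preset("attrition_noninformative"), n=2000)
        cohort, _ = mx.simulate_cohort(config, 10)
        cohort = mx.encode_missing_indicator(cohort, ["depression"])
        exposure = mx.derive_exposures(cohort, "short_sleep", 8.0)
        wt = mx.compute_weights(cohort, exposure, mx.WeightSpec(), None)
        assert abs(wt.table["ipaw"].mean() - 1.0) < 0.05
        assert wt.table["ipaw"].std() < 0.15

    def test_informative_attrition_reweights_confounder_distribution(self):
        """Inverse response probabilities restore the uncensored confounder
        distribution at the wave where dropout depends on it (the stabilized
        numerator only rescales this, leaving history dependence in place,
        so the check uses the denominator probabilities directly)."""
        config = replace(mx.load_preset("attrition_informative"), n=20000)
        cohort, truth = mx.simulate_cohort(config, 12)
        cohort_e = mx.encode_missing_indicator(cohort, ["depression"])
        exposure = mx.derive_exposures(cohort_e, "short_sleep", 8.0)
        wt = mx.compute_weights(cohort_e, exposure, mx.WeightSpec(), None)

        wave = 6  # first wave with substantial dropout
        frame = cohort.wave_frame(wave).reindex(cohort.persons)
        obs = frame["observed"].astype(bool).to_numpy()
        full = truth.frame[f"L_w{wave}"].mean()          # uncensored marginal
        l_obs = truth.frame.loc[obs, f"L_w{wave}"]
        observed_raw = l_obs.mean()
        den_cols = [c for c in wt.probabilities.columns
                    if c.startswith("c_den") and int(c.split("_w")[1]) <= wave]
        w = 1.0 / wt.probabilities.loc[obs, den_cols].prod(axis=1, skipna=True)
        weighted = float(np.average(l_obs, weights=w))
        # weighting moves the observed mean back onto the full-cohort mean
        assert abs(weighted - full) < abs(observed_raw - full)
        assert abs(weighted - full) < 0.015
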