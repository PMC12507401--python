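import math

import numpy as np
import pandas as pd
import pytest

from guildaging.io import ValidationError
from guildaging.outcomes import (
    SurvivalFit,
    aalen_johansen,
    competing_risk_analysis,
    fit_parametric_survival,
    hli_microbial_age_regression,
    residual_life_expectancy,
    score_lifestyle,
)


def _behaviour_frame(rows):
    cols = [
        f"{b}_{w}"
        for b in ("exercise", "smoking", "drinking", "healthy_diet")
        for w in ("baseline", "recent")
    ]
    return pd.DataFrame(rows, columns=cols,
                        index=[f"s{i}" for i in range(len(rows))])


class TestLifestyleScore:
    def test_all_healthy_behaviours_score_four(self):
        m = _behaviour_frame([[True, True, False, False, False, False, True, True]])
        s = score_lifestyle(m)
        assert s["hli_baseline"].iloc[0] == 4
        assert s["hli_recent"].iloc[0] == 4
        assert s["group_recent"].iloc[0] == "high"

    def test_all_unhealthy_scores_zero_low(self):
        m = _behaviour_frame([[False, False, True, True, True, True, False, False]])
        s = score_lifestyle(m)
        assert s["hli_recent"].iloc[0] == 0
        assert s["group_recent"].iloc[0] == "low"

    def test_adherence_high_low(self):
        # baseline HLI 3 (high), recent HLI 2 (low) -> high-low
        m = _behaviour_frame([[True, True, False, True, False, False, False, False]])
        s = score_lifestyle(m)
        assert s["hli_baseline"].iloc[0] == 3
        assert s["hli_recent"].iloc[0] == 2
        assert s["adherence"].iloc[0] == "high-low"

    def test_boundary_hli_two_is_low(self):
        m = _behaviour_frame([[True, True, True, True, True, True, True, True]])
        s = score_lifestyle(m)  # exercise + diet healthy, smokes + drinks
        assert s["hli_recent"].iloc[0] == 2
        assert s["group_recent"].iloc[0] == "low"

    def test_chfp_quintile_or_fiber_route(self):
        m = _behaviour_frame(
            [[True, True, False, False, False, False, False, False]] * 10
        )
        chfp = pd.Series(np.arange(10, 60, 5), index=m.index)  # 10..55
        fiber = pd.Series([0.0] * 9 + [25.0], index=m.index)
        s = score_lifestyle(m, chfp_scores=chfp, fiber_g_per_day=fiber)
        # top two quintiles of chfp (>= 60th percentile) or fiber > 20 g/day
        cutoff = chfp.quantile(0.6)
        expect = ((chfp >= cutoff) | (fiber > 20)).astype(int) + 3
        np.testing.assert_array_equal(s["hli_recent"].to_numpy(), expect)

    def test_missing_behaviour_fields_listed(self):
        m = _behaviour_frame([[True] * 8]).drop(columns=["smoking_recent"])
        with pytest.raises(ValidationError, match="smoking_recent"):
            score_lifestyle(m)


class TestHliRegression:
    def _data(self, n=800, effect=-0.3, seed=0):
        rng = np.random.default_rng(seed)
        idx = [f"s{i}" for i in range(n)]
        meta = pd.DataFrame(
            {
                "age_years": rng.uniform(51, 89, n),
                "sex": rng.choice(["male", "female"], n),
                "bmi": rng.normal(23, 2, n),
                "education": rng.integers(1, 5, n),
            },
            index=idx,
        )
        hli_b = rng.integers(0, 5, n)
        hli_r = np.clip(hli_b + rng.integers(-1, 2, n), 0, 4)
        scores = pd.DataFrame({"hli_baseline": hli_b, "hli_recent": hli_r}, index=idx)
        for w in ("baseline", "recent"):
            scores[f"group_{w}"] = np.where(scores[f"hli_{w}"] <= 2, "low", "high")
        scores["adherence"] = scores["group_baseline"] + "-" + scores["group_recent"]
        ma = pd.DataFrame(
            {
                "microbial_age": 61.0 + 0.1 * meta["age_years"]
                + effect * hli_r + rng.normal(0, 1.5, n)
            },
            index=idx,
        )
        return scores, ma, meta

    def test_planted_effect_recovered(self):
        scores, ma, meta = self._data()
        out = hli_microbial_age_regression(scores, ma, meta)
        assert -0.45 <= out["hli_per_point"]["beta"] <= -0.15
        assert out["hli_per_point"]["ci_low"] < out["hli_per_point"]["beta"]
        assert "high-high" in out

    def test_null_effect_ci_coverage(self):
        covered = 0
        for seed in range(20):
            scores, ma, meta = self._data(n=300, effect=0.0, seed=seed)
            out = hli_microbial_age_regression(scores, ma, meta)
            r = out["hli_per_point"]
            covered += r["ci_low"] <= 0.0 <= r["ci_high"]
        assert covered >= 17

    def test_constant_hli_rejected(self):
        scores, ma, meta = self._data(n=50)
        scores["hli_recent"] = 3
        with pytest.raises(ValidationError, match="variation"):
            hli_microbial_age_regression(scores, ma, meta)

    def test_empty_reference_group_rejected(self):
        scores, ma, meta = self._data(n=50)
        scores["adherence"] = "high-high"
        with pytest.raises(ValidationError, match="low-low"):
            hli_microbial_age_regression(scores, ma, meta)


class TestParametricSurvival:
    def test_exponential_closed_form_and_mle(self):
        lam = 0.05
        rng = np.random.default_rng(0)
        n = 2000
        t_event = rng.exponential(1 / lam, n)
        censor = rng.uniform(40, 120, n)
        times = np.minimum(t_event, censor)
        events = t_event <= censor
        fit, rle = fit_parametric_survival(times, events, family="exponential")
        closed = (1 - math.exp(-lam * 55)) / lam  # 18.72 years
        assert closed == pytest.approx(18.7214, abs=1e-3)
        assert abs(rle - closed) < 0.5
        assert fit.params["rate"] == pytest.approx(lam, rel=0.1)

    def test_zero_hazard_limit_approaches_window_length(self):
        fit = SurvivalFit("exponential", {"rate": 1e-8}, {"rate": 0.0}, 0.0)
        assert residual_life_expectancy(fit) == pytest.approx(55.0, abs=1e-4)

    def test_weibull_shape_one_reduces_to_exponential(self):
        fit_w = SurvivalFit("weibull", {"shape": 1.0, "scale": 20.0}, {}, 0.0)
        fit_e = SurvivalFit("exponential", {"rate": 1.0 / 20.0}, {}, 0.0)
        assert residual_life_expectancy(fit_w) == pytest.approx(
            residual_life_expectancy(fit_e), abs=1e-6
        )

    def test_gompertz_mle_recovers_parameters(self):
        rng = np.random.default_rng(1)
        a, b = 1e-4, 0.09
        n = 3000
        # inverse-CDF sampling of a Gompertz
        u = rng.uniform(size=n)
        t = np.log(1 - b / a * np.log(u)) / b
        censor = rng.uniform(30, 90, n)
        times = np.minimum(t, censor)
        events = t <= censor
        fit, rle = fit_parametric_survival(times, events, family="gompertz")
        assert fit.params["shape"] == pytest.approx(b, rel=0.2)
        assert 0 < rle < 55

    def test_no_events_rejected(self):
        with pytest.raises(ValidationError):
            fit_parametric_survival([10.0, 20.0], [False, False], "exponential")

    def test_rle_monotone_in_hazard(self):
        rates = [0.01, 0.02, 0.05, 0.1]
        rles = [
            residual_life_expectancy(
                SurvivalFit("exponential", {"rate": r}, {}, 0.0)
            )
            for r in rates
        ]
        assert all(a > b for a, b in zip(rles, rles[1:]))


class TestAalenJohansen:
    def test_three_subject_hand_values(self):
        cif = aalen_johansen([1.0, 2.0, 3.0], ["t2dm", "death", "none"])
        at1 = cif[cif["time"] == 1.0].iloc[0]
        at2 = cif[cif["time"] == 2.0].iloc[0]
        assert at1["cif_t2dm"] == pytest.approx(1 / 3)
        assert at2["cif_death"] == pytest.approx(1 / 3)
        # sum of CIFs equals 1 - KM overall at t = 2
        assert at2["cif_t2dm"] + at2["cif_death"] == pytest.approx(2 / 3)

    def test_conservation_identity(self):
        rng = np.random.default_rng(2)
        n = 300
        times = rng.exponential(50, n)
        codes = rng.choice(["none", "t2dm", "death"], n, p=[0.5, 0.2, 0.3])
        cif = aalen_johansen(times, codes)
        total = cif["overall_survival"] + cif["cif_t2dm"] + cif["cif_death"]
        np.testing.assert_allclose(total.to_numpy(), 1.0, atol=1e-9)
        assert (cif["cif_t2dm"].diff().dropna() >= -1e-12).all()
        assert (cif["cif_death"].diff().dropna() >= -1e-12).all()


def _competing_cohort(n, loghr, seed):
    rng = np.random.default_rng(seed)
    x = rng.binomial(1, 0.5, n).astype(float)
    lam1 = 0.01 * np.exp(loghr * x)
    lam2 = 0.008
    t1 = rng.exponential(1 / lam1)
    t2 = rng.exponential(1 / lam2, n)
    censor = rng.uniform(40, 90, n)
    t = np.minimum.reduce([t1, t2, censor])
    event = np.where(t == t1, "t2dm", np.where(t == t2, "death", "none"))
    return pd.DataFrame({"followup_months": t, "event": event, "x": x})


class TestCompetingRisk:
    def test_cause_specific_loghr_recovered(self):
        df = _competing_cohort(1000, math.log(2), seed=3)
        res = competing_risk_analysis(df, covariates=["x"], n_permutations=29, seed=0)
        hr = math.exp(res.cox.set_index("covariate").loc["x", "log_hr"])
        assert 1.5 <= hr <= 2.7

    def test_group_contrast_p_detects_strong_effect(self):
        df = _competing_cohort(600, math.log(4), seed=4)
        df["grp"] = np.where(df["x"] > 0, "old", "young")
        res = competing_risk_analysis(
            df, covariates=[], group_col="grp", n_permutations=99, seed=0
        )
        assert res.gray_style_p is not None and res.gray_style_p < 0.05

    def test_no_cause_events_rejected(self):
        df = pd.DataFrame(
            {"followup_months": [1.0, 2.0], "event": ["none", "death"], "x": [0, 1]}
        )
        with pytest.raises(ValidationError):
            competing_risk_analysis(df, covariates=["x"])

    def test_matches_lifelines_aalen_johansen(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(5)
        n = 120
        times = rng.exponential(60, n).round(1) + 0.1
        codes = rng.choice(["none", "t2dm", "death"], n, p=[0.4, 0.3, 0.3])
        ours = aalen_johansen(times, codes)
        event_num = np.where(codes == "t2dm", 1, np.where(codes == "death", 2, 0))
        ajf = lifelines.AalenJohansenFitter(calculate_variance=False)
        ajf.fit(pd.Series(times), pd.Series(event_num), event_of_interest=1)
        ref = ajf.cumulative_density_.iloc[:, 0]
        for t_eval in ours["time"]:
            ref_val = float(ref[ref.index <= t_eval].iloc[-1]) if (ref.index <= t_eval).any() else 0.0
            our_val = float(ours.loc[ours["time"] == t_eval, "cif_t2dm"].iloc[0])
            assert our_val == pytest.approx(ref_val, abs=1e-9)
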