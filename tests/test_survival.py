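"""Parametric fitting, AIC selection, PH scaling and life-table blending."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import survecon as se
from survecon.survival import FAMILIES, FitError


def make_ipd(times, events):
    return se.PseudoIPD("OS", "x", tuple(zip(np.asarray(times, float), events)))


class TestFitParametric:
    def test_exponential_mle_closed_form(self):
        # uncensored: rate = events / total follow-up = 3/6
        fit = se.fit_parametric(make_ipd([1, 2, 3], [True] * 3), "exponential")
        assert fit.parameters["rate"] == pytest.approx(0.5, rel=1e-6)

    def test_aic_definition(self):
        fit = se.fit_parametric(make_ipd([1, 2, 3], [True] * 3), "exponential")
        assert fit.aic == pytest.approx(2 * 1 - 2 * fit.log_likelihood)

    @pytest.mark.parametrize("family", FAMILIES)
    def test_survival_function_is_valid(self, family):
        rng = np.random.default_rng(5)
        t = rng.gamma(2.0, 20.0, 400)
        fit = se.fit_parametric(make_ipd(t, [True] * 400), family)
        grid = np.linspace(0.01, 200, 500)
        s = np.asarray(fit.survival(grid))
        assert np.all(s > 0) and np.all(s <= 1)
        assert np.all(np.diff(s) <= 1e-12)  # non-increasing
        assert np.all(np.asarray(fit.hazard(grid)) >= 0)

    def test_weibull_parameter_recovery(self):
        # shape 1.4, scale 50, ~30% censoring
        rng = np.random.default_rng(14)
        n = 2000
        t = 50.0 * rng.weibull(1.4, n)
        c = rng.uniform(0, 150, n)
        fit = se.fit_parametric(make_ipd(np.minimum(t, c), t <= c), "weibull")
        assert 1.3 <= fit.parameters["shape"] <= 1.5

    def test_gamma_censored_mle_matches_truth(self):
        rng = np.random.default_rng(2)
        n = 2000
        t = rng.gamma(2.0, 15.0, n)
        c = np.full(n, 60.0)
        fit = se.fit_parametric(make_ipd(np.minimum(t, c), t <= c), "gamma")
        assert fit.parameters["shape"] == pytest.approx(2.0, rel=0.15)
        assert fit.parameters["scale"] == pytest.approx(15.0, rel=0.15)

    def test_zero_events_rejected(self):
        with pytest.raises(FitError):
            se.fit_parametric(make_ipd([1, 2], [False, False]), "exponential")

    def test_too_few_records_rejected(self):
        with pytest.raises(FitError):
            se.fit_parametric(make_ipd([1], [True]), "weibull")


class TestSelectByAIC:
    def _fit_with_aic(self, family, aic):
        return se.ParametricFit(family, {"rate": 0.1}, -aic / 2, aic, 10, 10)

    def test_argmin(self):
        fits = [self._fit_with_aic(f, a) for f, a in
                zip(("exponential", "weibull", "gamma"), (202, 199, 205))]
        assert se.select_by_aic(fits).aic == 199

    def test_tie_goes_to_fewer_parameters(self):
        fits = [self._fit_with_aic("weibull", 200.0), self._fit_with_aic("exponential", 200.0)]
        assert se.select_by_aic(fits).family == "exponential"

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            se.select_by_aic([])


class TestApplyHazardRatio:
    def test_identity_at_hr_one(self, exp_curves):
        S = exp_curves["OS"]
        ph = se.apply_hazard_ratio(S, 1.0)
        t = np.linspace(0, 100, 11)
        assert np.allclose(ph.survival(t), S.survival(t))

    def test_exponential_ph_closed_form(self, exp_curves):
        ph = se.apply_hazard_ratio(exp_curves["OS"], 2.0)  # rate 0.01 -> 0.02
        t = np.linspace(0, 100, 11)
        assert np.allclose(ph.survival(t), np.exp(-0.02 * t))

    def test_nivolumab_style_projection_matches_hazard_integration(self):
        # S_proj(t) = S_ref(t)^(1/0.8975), checked against exp(-H(t)/0.8975)
        rng = np.random.default_rng(3)
        t = rng.weibull(1.2, 500) * 80
        fit = se.fit_parametric(make_ipd(t, [True] * 500), "weibull")
        proj = se.apply_hazard_ratio(fit, 1 / 0.8975)
        for tt in (12.0, 36.0, 60.0):
            grid = np.linspace(1e-6, tt, 200001)
            h_int = np.trapezoid(np.asarray(proj.hazard(grid)), grid)
            assert float(proj.survival(tt)) == pytest.approx(np.exp(-h_int), abs=1e-4)

    def test_invalid_hr_rejected(self, exp_curves):
        with pytest.raises(ValueError):
            se.apply_hazard_ratio(exp_curves["OS"], 0.0)


class TestAICSelectionSimulation:
    def test_exponential_vs_weibull_distinguishable(self):
        # data from Weibull shape 1.5 should not select exponential
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            t = 40.0 * rng.weibull(1.5, 2000)
            ipd = make_ipd(t, [True] * 2000)
            fits = [se.fit_parametric(ipd, f) for f in ("exponential", "weibull")]
            if se.select_by_aic(fits).family == "weibull":
                wins += 1
        assert wins >= 8


class TestLifeTable:
    def test_monthly_hazard_conversion(self, life_table):
        q = life_table.q_at(70)
        assert life_table.monthly_hazard(70.4) == pytest.approx(-np.log(1 - q) / 12)

    def test_coverage_gap_names_ages(self, life_table):
        with pytest.raises(ValueError, match="age"):
            life_table.q_at(200)

    def test_non_contiguous_ages_rejected(self):
        with pytest.raises(ValueError):
            se.LifeTable((50, 52), (0.01, 0.02))


@pytest.fixture(scope="module")
def blended(life_table):
    rng = np.random.default_rng(8)
    t = 60.0 * rng.weibull(1.1, 1500)
    c = np.full(1500, 60.0)
    fit = se.fit_parametric(make_ipd(np.minimum(t, c), t <= c), "weibull")
    return se.blend_with_life_table(fit, life_table, 50.0, t_obs=60.0, t_conv=108.0)


class TestBlendedSurvival:
    def test_boundary_weights(self, blended, life_table):
        # w(t_obs)=0: blend hazard equals parametric; w(t_conv)=1: background
        assert blended.hazard(60.0) == pytest.approx(float(blended.base.hazard(60.0)))
        assert blended.hazard(108.0) == pytest.approx(life_table.monthly_hazard(59.0))

    def test_background_only_after_convergence(self, blended, life_table):
        for t in (120.0, 240.0, 480.0):
            assert blended.hazard(t) == pytest.approx(
                life_table.monthly_hazard(50.0 + t / 12.0)
            )

    def test_continuity_at_regime_boundaries(self, blended):
        eps = 1e-7
        for t0 in (60.0, 108.0):
            assert abs(blended.survival(t0 - eps) - blended.survival(t0 + eps)) < 1e-6
        assert abs(
            blended.survival(60.0) - float(np.exp(-blended.base.cumulative_hazard(60.0)))
        ) < 1e-9

    def test_survival_non_increasing(self, blended):
        grid = np.linspace(0, 500, 2000)
        s = np.asarray(blended.survival(grid))
        assert np.all(np.diff(s) <= 1e-12)

    def test_quadrature_oracle_at_120_months(self, blended):
        grid = np.linspace(0, 120.0, 480001)
        h = np.asarray(blended.hazard(grid))
        s_oracle = np.exp(-np.trapezoid(h, grid))
        assert float(blended.survival(120.0)) == pytest.approx(s_oracle, abs=1e-4)

    def test_fixed_point_when_parametric_equals_background(self, life_table):
        # constant hazard equal to the background at a fixed age: blend is exact
        class FlatBackground:
            def __init__(self, h): self.h = h
            def survival(self, t): return np.exp(-self.h * np.asarray(t, float))
            def hazard(self, t): return np.full_like(np.asarray(t, float), self.h)
            def cumulative_hazard(self, t): return self.h * np.asarray(t, float)

        flat_lt = se.LifeTable(
            tuple(range(0, 111)), tuple([1 - np.exp(-0.02 * 12)] * 111)
        )
        b = se.BlendedSurvival(FlatBackground(0.02), flat_lt, 50.0, t_obs=60, t_conv=108)
        t = np.linspace(1, 400, 50)
        assert np.allclose(b.hazard(t), 0.02, rtol=1e-9)

    def test_invalid_window_rejected(self, life_table, blended):
        with pytest.raises(ValueError):
            se.BlendedSurvival(blended.base, life_table, 50.0, t_obs=60, t_conv=60)

    def test_horizon_beyond_table_names_missing_ages(self, blended):
        short_lt = se.LifeTable(tuple(range(0, 81)), tuple([0.01] * 81))
        with pytest.raises(ValueError, match="missing"):
            se.BlendedSurvival(blended.base, short_lt, 50.0, t_obs=60, t_conv=108,
                               horizon=600.0)


@settings(derandomize=True, max_examples=30)
@given(
    hr=st.floats(min_value=0.1, max_value=5.0),
    rate=st.floats(min_value=1e-4, max_value=0.2),
    t=st.floats(min_value=0.0, max_value=200.0),
)
def test_ph_scaling_property(hr, rate, t):
    """S^hr stays a valid survival value and orders correctly with hr."""

    class E:
        def survival(self, tt): return np.exp(-rate * np.asarray(tt, float))
        def hazard(self, tt): return np.full_like(np.asarray(tt, float), rate)
        def cumulative_hazard(self, tt): return rate * np.asarray(tt, float)

    ph = se.apply_hazard_ratio(E(), hr)
    s = float(ph.survival(t))
    s0 = float(np.exp(-rate * t))
    assert 0.0 <= s <= 1.0
    if hr > 1:
        assert s <= s0 + 1e-12
    else:
        assert s >= s0 - 1e-12
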