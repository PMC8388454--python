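"""Circadian model evaluation, grid initialization, NLS fitting and patterns."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from heatrhythm import (
    REFERENCE_MODELS,
    CircadianModel,
    CircadianRegressor,
    GridConfig,
    adjusted_r2,
    compare_patterns,
    evaluate_model,
    fit_model,
    grid_initialize,
    model_mean,
    sample_from_model,
    summarize_pattern,
)

REST_NS = REFERENCE_MODELS["rest"]["NS"]
REST_HS = REFERENCE_MODELS["rest"]["HS"]
HB_HS = REFERENCE_MODELS["heavy_breathing"]["HS"]


class TestEvaluateModel:
    def test_zero_amplitude_is_flat(self):
        m = CircadianModel("single", mu=10.0, a=0.0, b=0.0)
        assert evaluate_model(m, 3.7) == 10.0
        assert evaluate_model(m, 21.0) == 10.0

    def test_reference_rest_model_at_midnight(self):
        # 16.247 - 2.466 * sin(-2.763)
        assert evaluate_model(REST_NS, 0.0) == pytest.approx(17.1585, abs=1e-3)

    def test_periodicity(self):
        m = CircadianModel("single", mu=5.0, a=2.0, b=1.0)
        for h in (0.0, 7.3, 13.9):
            assert evaluate_model(m, h) == pytest.approx(evaluate_model(m, h + 24.0),
                                                         abs=1e-9)

    def test_double_periodicity_at_lcm(self):
        m = CircadianModel("double", mu=5.0, a=2.0, b=1.0, period1=12.0,
                           c=1.0, d=0.5, period2=8.0)
        assert evaluate_model(m, 1.0) == pytest.approx(evaluate_model(m, 25.0), abs=1e-9)

    def test_single_form_rejects_second_wave(self):
        with pytest.raises(ValueError):
            CircadianModel("single", mu=1.0, a=1.0, b=0.0, c=1.0)


class TestModelMean:
    def test_single_form_mean_is_mu(self):
        # the 24-h harmonic averages to zero on any uniform full-period grid
        for m in (REST_NS, REST_HS, HB_HS):
            assert model_mean(m) == pytest.approx(m.mu, abs=1e-9)

    def test_harmonic_orthogonality_for_commensurate_double(self):
        m = CircadianModel("double", mu=9.0, a=3.0, b=0.7, period1=24.0,
                           c=2.0, d=0.2, period2=12.0)
        assert model_mean(m) == pytest.approx(9.0, abs=1e-9)

    def test_free_period_double_mean_differs_from_mu(self):
        # non-24h periods do not integrate to zero over one day
        m = REFERENCE_MODELS["rumination"]["NS"]
        assert model_mean(m) != pytest.approx(m.mu, abs=0.01)


class TestAdjustedR2:
    def test_perfect_fit(self):
        assert adjusted_r2(0.0, 100.0, 50, 3) == (1.0, 1.0)

    def test_single_parameter_collapse(self):
        r2, r2a = adjusted_r2(30.0, 100.0, 50, 1)
        assert r2 == pytest.approx(r2a)

    def test_hand_computed(self):
        r2, r2a = adjusted_r2(25.0, 100.0, 100, 3)
        assert r2 == pytest.approx(0.75)
        assert r2a == pytest.approx(1 - (99 / 97) * 0.25, abs=1e-12)  # 0.74485

    def test_penalty_monotone_in_p(self):
        vals = [adjusted_r2(25.0, 100.0, 100, p)[1] for p in range(1, 10)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            adjusted_r2(1.0, 0.0, 10, 3)
        with pytest.raises(ValueError):
            adjusted_r2(1.0, 10.0, 3, 3)


class TestGridInitialize:
    def test_noiseless_grid_member_recovered(self):
        hours = np.tile(np.arange(24.0), 5)
        truth = CircadianModel("single", mu=0.0, a=2.0, b=math.pi / 2)
        # mu on the grid is the sample mean; choose b on the default phase grid
        values = truth.evaluate(hours)
        got = grid_initialize(hours, values, "single",
                              GridConfig(phases=(0.0, math.pi / 2, math.pi),
                                         amplitude_fractions=(0.5, 1.0)))
        assert got.b == pytest.approx(math.pi / 2)
        assert got.a == pytest.approx(2.0)  # full half-range of a pure sine

    def test_tie_break_prefers_smaller_period(self):
        # constant data: every candidate has equal RSS; smallest period,
        # then smallest phases must win
        hours = np.arange(24.0)
        values = np.full(24, 5.0)
        grid = GridConfig(phases=(0.0, math.pi), amplitude_fractions=(1.0,),
                          periods=(8.0, 12.0, 24.0))
        got = grid_initialize(hours, values, "double", grid)
        assert (got.period1, got.period2) == (8.0, 8.0)
        assert (got.b, got.d) == (0.0, 0.0)

    def test_empty_grid_errors(self):
        with pytest.raises(ValueError, match="empty grid"):
            grid_initialize(np.arange(24.0), np.arange(24.0), "single",
                            GridConfig(phases=()))

    @pytest.mark.parametrize("form", ["single", "double"])
    def test_matches_exhaustive_enumeration_oracle(self, form):
        """Independent brute-force oracle over all candidates (< 1000)."""
        rng = np.random.default_rng(99)
        hours = np.tile(np.arange(24.0), 3)
        values = REST_HS.evaluate(hours) + rng.normal(0, 2, hours.size)
        grid = GridConfig(phases=(0.0, math.pi / 2, math.pi, 3 * math.pi / 2),
                          amplitude_fractions=(0.5, 1.0),
                          periods=(6.0, 8.0, 12.0, 24.0))
        mu = values.mean()
        half = (values.max() - values.min()) / 2

        best, best_rss = None, np.inf
        if form == "single":
            for b in grid.phases:
                for frac in grid.amplitude_fractions:
                    pred = mu + frac * half * np.sin(2 * np.pi / 24 * hours + b)
                    rss = np.sum((values - pred) ** 2)
                    if rss < best_rss:
                        best_rss, best = rss, (frac * half, b)
            got = grid_initialize(hours, values, "single", grid)
            assert (got.a, got.b) == pytest.approx(best)
        else:
            amp = 0.5 * half
            for i1, t1 in enumerate(grid.periods):
                for t2 in grid.periods[:i1 + 1]:
                    for b in grid.phases:
                        for d in grid.phases:
                            pred = (mu + amp * np.sin(2 * np.pi / t1 * hours + b)
                                    + amp * np.cos(2 * np.pi / t2 * hours + d))
                            rss = np.sum((values - pred) ** 2)
                            if rss < best_rss:
                                best_rss, best = rss, (t1, t2, b, d)
            grid = GridConfig(phases=grid.phases, amplitude_fractions=(0.5,),
                              periods=grid.periods)
            got = grid_initialize(hours, values, "double", grid)
            assert (got.period1, got.period2, got.b, got.d) == pytest.approx(best)


class TestFitModel:
    def test_noiseless_single_exact_recovery(self):
        hours = np.tile(np.arange(24.0), 3)
        truth = CircadianModel("single", mu=10.0, a=2.0, b=1.0)
        fit = fit_model(hours, truth.evaluate(hours), "single")
        assert fit.rss == pytest.approx(0.0, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0)
        norm = fit.model_normalized
        assert norm.mu == pytest.approx(10.0, abs=1e-6)
        assert norm.a == pytest.approx(2.0, abs=1e-6)
        assert norm.b == pytest.approx(1.0, abs=1e-6)

    def test_refinement_never_worse_than_grid_start(self):
        rng = np.random.default_rng(4)
        hours, values = sample_from_model(REST_NS, n_animals=5, n_days=2,
                                          noise_sd=5.0, rng=rng)
        start = grid_initialize(hours, values, "single")
        rss_start = float(np.sum((values - start.evaluate(hours)) ** 2))
        fit = fit_model(hours, values, "single")
        assert fit.rss <= rss_start + 1e-9

    def test_too_few_observations_error(self):
        with pytest.raises(ValueError, match="observations"):
            fit_model(np.arange(3.0), np.array([1.0, 2.0, 3.0]), "single")

    def test_median_mu_recovery_over_replicates(self):
        # over seeded replicates of the default study scale, the baseline of
        # every single-form behavior is recovered to < 0.1 min/h in the median
        for beh in ("rest", "activity", "heavy_breathing"):
            for grp in ("NS", "HS"):
                truth = REFERENCE_MODELS[beh][grp]
                errs = []
                for rep in range(5):
                    h, v = sample_from_model(truth, seed=1000 + rep)
                    errs.append(abs(fit_model(h, v, "single").model.mu - truth.mu))
                assert np.median(errs) < 0.1, (beh, grp)

    def test_fit_carries_rss_tss_bookkeeping(self):
        h, v = sample_from_model(REST_NS, n_animals=4, n_days=2, seed=8)
        fit = fit_model(h, v, "single")
        assert 0 <= fit.rss <= fit.tss
        assert fit.p == 3 and fit.n == h.size
        r2 = 1 - fit.rss / fit.tss
        assert fit.r2 == pytest.approx(r2)
        assert fit.r2_adj <= fit.r2

    def test_double_fit_parameter_count(self):
        h, v = sample_from_model(REFERENCE_MODELS["eating"]["NS"],
                                 n_animals=4, n_days=2, seed=9)
        fit = fit_model(h, v, "double")
        assert fit.p == 7

    def test_sklearn_estimator_interface(self):
        from sklearn.base import clone
        h, v = sample_from_model(REST_NS, n_animals=4, n_days=2, seed=10)
        reg = CircadianRegressor(form="single")
        assert clone(reg).get_params()["form"] == "single"
        reg.fit(h.reshape(-1, 1), v)
        pred = reg.predict(np.array([[0.0], [12.0]]))
        assert pred.shape == (2,)
        assert 0.0 <= reg.score(h.reshape(-1, 1), v) <= 1.0


class TestPhaseNormalization:
    @settings(derandomize=True, max_examples=40)
    @given(mu=st.floats(-10, 30), a=st.floats(-8, 8), b=st.floats(-200, 200))
    def test_single_pointwise_equivalence(self, mu, a, b):
        m = CircadianModel("single", mu=mu, a=a, b=b)
        n = m.normalized()
        assert n.a >= 0.0
        assert -math.pi < n.b <= math.pi
        hours = np.linspace(0, 24, 49)
        np.testing.assert_allclose(m.evaluate(hours), n.evaluate(hours), atol=1e-9)

    @settings(derandomize=True, max_examples=40)
    @given(a=st.floats(-8, 8), b=st.floats(-50, 50), c=st.floats(-8, 8),
           d=st.floats(-50, 50))
    def test_double_pointwise_equivalence(self, a, b, c, d):
        m = CircadianModel("double", mu=5.0, a=a, b=b, period1=18.0,
                           c=c, d=d, period2=11.0)
        n = m.normalized()
        assert n.a >= 0.0 and n.c >= 0.0
        hours = np.linspace(0, 24, 49)
        np.testing.assert_allclose(m.evaluate(hours), n.evaluate(hours), atol=1e-9)


class TestPatterns:
    def test_single_harmonic_has_one_peak(self):
        s = summarize_pattern(REST_NS)
        assert len(s.peak_hours) == 1 and len(s.trough_hours) == 1
        assert s.daily_range == pytest.approx(2 * abs(REST_NS.a), abs=1e-3)

    def test_heavy_breathing_hs_peaks_in_afternoon(self):
        s = summarize_pattern(HB_HS)
        assert len(s.peak_hours) == 1
        assert 12.0 <= s.peak_hours[0] <= 20.0

    def test_rumination_models_have_two_peaks(self):
        for grp in ("NS", "HS"):
            s = summarize_pattern(REFERENCE_MODELS["rumination"][grp])
            assert len(s.peak_hours) == 2, grp

    def test_compare_identical_fits_is_null(self):
        h, v = sample_from_model(REST_NS, n_animals=4, n_days=2, seed=11)
        fit = fit_model(h, v, "single", behavior="rest")
        cmp = compare_patterns(fit, fit)
        assert cmp.mean_difference == 0.0
        assert cmp.peak_shift_hours == 0.0
        np.testing.assert_allclose(cmp.hourly_difference_curve, 0.0)

    def test_reference_rest_pair_mean_difference(self):
        h, v = sample_from_model(REST_NS, n_animals=2, n_days=1, noise_sd=0, seed=0)
        fit_ns = fit_model(h, v, "single", behavior="rest")
        h, v = sample_from_model(REST_HS, n_animals=2, n_days=1, noise_sd=0, seed=0)
        fit_hs = fit_model(h, v, "single", behavior="rest")
        cmp = compare_patterns(fit_ns, fit_hs)
        assert cmp.mean_difference == pytest.approx(16.247 - 13.371, abs=1e-3)

    def test_heavy_breathing_range_contrast(self):
        ns = summarize_pattern(REFERENCE_MODELS["heavy_breathing"]["NS"])
        hs = summarize_pattern(HB_HS)
        assert ns.daily_range == pytest.approx(2 * 0.608, abs=1e-3)
        assert hs.daily_range == pytest.approx(2 * 4.492, abs=1e-3)

    def test_mismatched_behaviors_error(self):
        h, v = sample_from_model(REST_NS, n_animals=2, n_days=1, seed=1)
        f1 = fit_model(h, v, "single", behavior="rest")
        f2 = fit_model(h, v, "single", behavior="activity")
        with pytest.raises(ValueError, match="different behaviors"):
            compare_patterns(f1, f2)
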