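import numpy as np
import pytest

from cats_ards.errors import DomainError, SeparationError
from cats_ards.outcomes import (cumulative_incidence, fit_cox, fit_fine_gray,
                                fit_logistic, km_estimate, logrank_test,
                                mortality_model, subtype_design)
from cats_ards.synthetic import simulate_fine_gray_cohort


def table_2x2_data(a, b, c, d):
    """Binary exposure/outcome data realizing counts [[a, b], [c, d]]."""
    x = np.array([1] * (a + b) + [0] * (c + d), dtype=float)
    y = np.array([1] * a + [0] * b + [1] * c + [0] * d, dtype=float)
    return y, x


class TestLogistic:
    @pytest.mark.parametrize("a,b,c,d", [(8, 12, 5, 15), (10, 21, 3, 33),
                                         (7, 3, 9, 11)])
    def test_saturated_2x2_matches_cross_product_ratio(self, a, b, c, d):
        y, x = table_2x2_data(a, b, c, d)
        fit = fit_logistic(y, x[:, None], ["exposure"])
        assert fit.exp_coef[1] == pytest.approx(a * d / (b * c), rel=1e-6)
        # Wald SE closed form: sqrt(1/a + 1/b + 1/c + 1/d)
        assert fit.se[1] == pytest.approx(
            np.sqrt(1 / a + 1 / b + 1 / c + 1 / d), rel=1e-6)

    def test_null_covariate(self, rng):
        x = rng.normal(size=400)
        y = rng.binomial(1, 0.5, size=400).astype(float)
        fit = fit_logistic(y, x[:, None])
        assert abs(fit.coef[1]) < 3 * fit.se[1]

    def test_perfect_separation_detected(self):
        x = np.array([0, 0, 0, 1, 1, 1], dtype=float)
        y = np.array([0, 0, 0, 1, 1, 1], dtype=float)
        with pytest.raises(SeparationError):
            fit_logistic(y, x[:, None])

    def test_rank_deficiency_detected(self, rng):
        x = rng.normal(size=50)
        X = np.column_stack([x, 2 * x])
        y = rng.binomial(1, 0.5, 50).astype(float)
        with pytest.raises(DomainError, match="rank"):
            fit_logistic(y, X)


class TestCox:
    def test_null_covariate_hr_near_one(self, rng):
        n = 300
        x = rng.binomial(1, 0.5, n).astype(float)
        t = rng.exponential(5, n)
        e = (t < 8).astype(int)
        fit = fit_cox(np.minimum(t, 8), e, x[:, None])
        assert abs(fit.coef[0]) < 3 * fit.se[0]

    def test_tied_pair_closed_form(self):
        # two subjects, events tied at t=1, x = (0, 1): Breslow partial
        # likelihood beta - 2 log(1 + e^beta) is maximized at beta = 0
        fit = fit_cox([1.0, 1.0], [1, 1], np.array([[0.0], [1.0]]))
        assert fit.coef[0] == pytest.approx(0.0, abs=1e-6)


class TestFineGray:
    def test_reduces_to_cox_without_competing_events(self, rng):
        for seed in range(6):
            r = np.random.default_rng(seed)
            n = 120
            x = r.normal(size=(n, 2))
            t = r.exponential(10 * np.exp(-0.4 * x[:, 0]), n)
            e = np.where(t <= 28, 1, 0)
            t = np.clip(t, 1e-6, 28)
            fg = fit_fine_gray(t, e, x)
            cox = fit_cox(t, e, x)
            np.testing.assert_allclose(fg.coef, cox.coef, atol=1e-6)

    def test_matches_independent_crr_implementation(self):
        # reference values from cmprsk::crr on the identical dataset
        t, ev, X = simulate_fine_gray_cohort(150, [0.7, -0.3], seed=42,
                                             covariate="normal")
        fit = fit_fine_gray(t, ev, X)
        np.testing.assert_allclose(
            fit.coef, [0.7026209067, -0.2099247149], atol=1e-4)
        np.testing.assert_allclose(
            fit.se, [0.1315298009, 0.1204580295], atol=1e-4)

    def test_null_covariate_ci_covers_one(self):
        covered = 0
        for seed in range(40):
            t, ev, X = simulate_fine_gray_cohort(500, [0.0], seed=seed)
            fit = fit_fine_gray(t, ev, X)
            covered += fit.ci_low[0] <= 1.0 <= fit.ci_high[0]
        assert covered >= 35  # consistent with nominal 95% coverage

    def test_planted_shr_recovered(self):
        beta = np.log(2.0)
        ests = [fit_fine_gray(*simulate_fine_gray_cohort(800, [beta],
                                                         seed=s)).coef[0]
                for s in range(20)]
        assert np.mean(ests) == pytest.approx(beta, abs=0.06)

    def test_no_events_of_interest_rejected(self):
        with pytest.raises(DomainError, match="events of interest"):
            fit_fine_gray([1.0, 2.0], [0, 2], np.array([[0.0], [1.0]]))


class TestKaplanMeier:
    def test_no_events_survival_one(self):
        _, s = km_estimate([3.0, 5.0, 7.0], [0, 0, 0])
        assert np.all(s == 1.0)

    def test_hand_product_limit(self):
        t, s = km_estimate([1.0, 2.0, 3.0], [1, 1, 1])
        np.testing.assert_allclose(s[np.searchsorted(t, [1, 2, 3])],
                                   [2 / 3, 1 / 3, 0.0], atol=1e-12)

    def test_all_censored(self):
        t, s = km_estimate([5.0, 5.0], [0, 0])
        assert s[-1] == 1.0


class TestLogrank:
    def test_two_group_hand_calculation(self):
        # group A events at 1, 2; group B censored at 3, 3
        times = np.array([1.0, 2.0, 3.0, 3.0])
        events = np.array([1, 1, 0, 0])
        groups = np.array(["A", "A", "B", "B"])
        stat, p = logrank_test(times, events, groups)
        o_minus_e = 2 - (2 / 4 + 1 / 3)
        var = (1 * (2 / 4) * (2 / 4) * (4 - 1) / (4 - 1)
               + 1 * (1 / 3) * (2 / 3) * (3 - 1) / (3 - 1))
        assert stat == pytest.approx(o_minus_e**2 / var, rel=1e-9)

    def test_relabeling_symmetry(self, rng):
        times = rng.exponential(5, 60)
        events = rng.binomial(1, 0.7, 60)
        groups = np.repeat([0, 1], 30)
        s1, _ = logrank_test(times, events, groups)
        s2, _ = logrank_test(times, events, 1 - groups)
        assert s1 == pytest.approx(s2)

    def test_pairwise_table_has_all_pairs(self, rng):
        times = rng.exponential(5, 90)
        events = np.ones(90, dtype=int)
        groups = np.repeat([1, 2, 3], 30)
        _, _, table = logrank_test(times, events, groups, pairwise=True)
        assert len(table) == 3


class TestCumulativeIncidence:
    def test_single_cause_is_one_minus_km(self):
        times = np.array([1.0, 2.0, 4.0, 5.0, 6.0])
        events = np.array([1, 1, 0, 1, 0])
        jumps, cif, _ = cumulative_incidence(times, events)
        kt, ks = km_estimate(times, events)
        km_at_jumps = ks[np.searchsorted(kt, jumps)]
        np.testing.assert_allclose(cif[1], 1 - km_at_jumps, atol=1e-12)

    def test_no_events(self):
        jumps, cif, _ = cumulative_incidence([1.0, 2.0], [0, 0])
        assert len(jumps) == 0

    def test_two_cause_hand_aalen_johansen(self):
        times = np.array([1.0, 2.0, 3.0, 4.0])
        events = np.array([1, 2, 1, 0])
        jumps, cif, surv = cumulative_incidence(times, events)
        np.testing.assert_allclose(cif[1], [0.25, 0.25, 0.5], atol=1e-12)
        np.testing.assert_allclose(cif[2], [0.0, 0.25, 0.25], atol=1e-12)

    def test_sum_to_one_at_every_jump(self, rng):
        times = rng.exponential(5, 200)
        events = rng.choice([0, 1, 2], size=200, p=[0.2, 0.5, 0.3])
        jumps, cif, surv = cumulative_incidence(times, events)
        total = cif[1] + cif[2] + surv
        np.testing.assert_allclose(total, 1.0, atol=1e-12)


class TestSubtypeModels:
    def test_reference_level_excluded(self, small_cohort):
        labels = small_cohort.true_labels.to_numpy()
        clin = small_cohort.clinical.set_index("subject_id")
        X, names = subtype_design(labels, clin, "prism_immunocompromised")
        assert names == ["subtype_2", "subtype_3", "prism_iii",
                         "immunocompromised"]
        assert X.shape == (len(labels), 4)

    def test_unknown_preset_rejected(self, small_cohort):
        clin = small_cohort.clinical.set_index("subject_id")
        with pytest.raises(DomainError, match="preset"):
            subtype_design(small_cohort.true_labels.to_numpy(), clin, "nope")

    def test_mortality_model_runs_adjusted(self, small_cohort):
        clin = small_cohort.clinical.set_index("subject_id")
        died = np.array([not small_cohort.events[s].picu_survivor
                         for s in small_cohort.true_labels.index])
        fit = mortality_model(small_cohort.true_labels.to_numpy(), clin,
                              died.astype(float), adjust="prism")
        assert fit.converged
        assert np.all(fit.ci_low < fit.exp_coef)
        assert np.all(fit.exp_coef < fit.ci_high)
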