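"""Hyperbolic discounting: choice model, MAP-EM hierarchy, AUC, LOSO."""

import numpy as np
import pandas as pd
import pytest

from selfother import discounting as dc
from selfother.synthetic_cohort import (CohortConfig, sample_cohort,
                                        simulate_itc_choices)


@pytest.fixture(scope="module")
def battery():
    return dc.generate_battery(seed=3)


@pytest.fixture(scope="module")
def cohort40(battery):
    subs = sample_cohort(40, seed=11)
    choices = [simulate_itc_choices(s.itc_params, battery,
                                    seed=s.seeds["itc"]) for s in subs]
    return subs, choices


class TestBattery:
    def test_sixty_questions_with_coverage(self, battery):
        assert len(battery) == 60
        assert (battery["later_amt"] > battery["sooner_amt"]).all()
        assert set(battery["delay_days"]) == set(dc.DELAYS_DAYS)
        assert set(battery["sooner_amt"]) == set(range(1, 10))
        assert set(battery["later_amt"]) == set(range(2, 11))

    def test_deterministic(self):
        assert dc.generate_battery(seed=9).equals(dc.generate_battery(seed=9))


class TestChoiceModel:
    def test_hand_computed_value(self):
        assert dc.discounted_value(10, 10, 0.1, 1.0) == pytest.approx(5.0)

    def test_power_exponent_one_reduces_to_simple_hyperbola(self):
        for V, D, k in [(10, 5, 0.2), (3, 84, 0.01), (7, 1, 1.0)]:
            assert dc.discounted_value(V, D, k, 1.0) == \
                pytest.approx(V / (1 + k * D))

    def test_no_discounting_identities(self):
        assert dc.discounted_value(8, 0, 0.3, 1.2) == 8.0
        assert dc.discounted_value(8, 30, 0.0, 1.2) == 8.0

    def test_monotone_decreasing_in_delay(self):
        vals = [dc.discounted_value(10, d, 0.05, 0.8) for d in range(0, 90, 5)]
        assert np.all(np.diff(vals) < 0)

    def test_softmax_symmetry_and_indifference(self):
        assert dc.choice_probability(5.0, 5.0, 2.0) == pytest.approx(0.5)
        assert dc.choice_probability(9.0, 2.0, 0.0) == pytest.approx(0.5)

    def test_softmax_hand_value(self):
        # value difference 1 at beta = ln 3 gives P(later) = 3/4
        assert dc.choice_probability(4.0, 5.0, np.log(3)) == pytest.approx(0.75)

    def test_probability_strictly_inside_unit_interval(self):
        p = dc.choice_probability(0.0, 100.0, 5.0)
        assert 0.0 < p <= 1.0


class TestCrossEntropy:
    def test_chance_prediction(self):
        assert dc.cross_entropy(1, 0.5) == pytest.approx(np.log(2))

    def test_confident_correct_prediction(self):
        assert dc.cross_entropy(1, 1.0) == pytest.approx(0.0, abs=1e-10)

    def test_confident_wrong_prediction_is_large(self):
        assert dc.cross_entropy(0, 0.999) > 6.0


class TestPriorUpdate:
    def test_two_subject_hand_case(self):
        mu, var = dc.update_prior(np.array([[0.0], [2.0]]),
                                  np.array([[1.0], [1.0]]))
        assert mu[0] == pytest.approx(1.0)
        assert var[0] == pytest.approx(2.0)

    def test_single_subject(self):
        mu, var = dc.update_prior(np.array([[1.5]]), np.array([[0.3]]))
        assert mu[0] == pytest.approx(1.5)
        assert var[0] == pytest.approx(0.3)

    def test_degenerate_cohort_hits_floor(self):
        mu, var = dc.update_prior(np.array([[1.0], [1.0]]),
                                  np.array([[0.0], [0.0]]))
        assert var[0] == dc.PRIOR_VARIANCE_FLOOR


class TestMapEstimate:
    def test_tight_prior_pins_map(self, battery):
        choices = battery.copy()
        choices["choice"] = 1
        mean = np.array([-2.0, 0.1, 0.5])
        m, v, ok = dc.map_estimate(choices, mean, np.full(3, 1e-8))
        assert ok and m == pytest.approx(mean, abs=1e-3)

    def test_recovers_known_parameters_with_flat_prior(self, battery):
        truth = {"k": 0.05, "S": 1.0, "beta": 5.0}
        big = pd.concat([battery] * 5, ignore_index=True)
        choices = simulate_itc_choices(truth, big, seed=1)
        m, v, ok = dc.map_estimate(choices, np.zeros(3), np.full(3, 25.0))
        assert ok
        assert m[0] == pytest.approx(np.log(truth["k"]), abs=0.5)
        assert m[2] == pytest.approx(np.log(truth["beta"]), abs=0.6)

    def test_laplace_variance_shrinks_with_data(self, battery):
        truth = {"k": 0.05, "S": 1.0, "beta": 3.0}
        prior = (np.array([-3.0, 0.0, 1.0]), np.full(3, 4.0))
        small = simulate_itc_choices(truth, battery, seed=2)
        big = simulate_itc_choices(
            truth, pd.concat([battery] * 8, ignore_index=True), seed=2)
        _, v_small, _ = dc.map_estimate(small, *prior)
        _, v_big, _ = dc.map_estimate(big, *prior)
        assert np.all(v_big < v_small)


class TestEmFit:
    def test_two_parameter_model_wins_ibic(self, cohort40):
        _, choices = cohort40
        fit2 = dc.em_fit(choices, "hyper2", seed=5)
        fit1 = dc.em_fit(choices, "hyper1", seed=5)
        assert fit2.converged and fit1.converged
        assert fit2.ibic < fit1.ibic

    def test_parameter_recovery_rank_correlations(self, cohort40):
        subs, choices = cohort40
        fit = dc.em_fit(choices, "hyper2", seed=5)
        from scipy.stats import spearmanr
        true = {
            0: [np.log(s.itc_params["k"]) for s in subs],
            1: [np.log(s.itc_params["S"]) for s in subs],
            2: [np.log(s.itc_params["beta"]) for s in subs]}
        for i in range(3):
            assert spearmanr(true[i], fit.maps[:, i]).statistic >= 0.6

    def test_requires_two_subjects(self, battery):
        with pytest.raises(ValueError):
            dc.em_fit([battery.assign(choice=1)], "hyper1")


class TestAUC:
    def test_always_later_gives_full_area(self, battery):
        assert dc.discounting_auc(battery.assign(choice=1)) == pytest.approx(1.0)

    def test_always_sooner_is_floor(self, battery):
        auc = dc.discounting_auc(battery.assign(choice=0))
        assert auc <= 0.01

    def test_steeper_discounting_lowers_auc(self, battery):
        auc = []
        for k in (0.005, 0.05, 0.5):
            c = simulate_itc_choices({"k": k, "S": 1.0, "beta": 10.0},
                                     battery, seed=4)
            auc.append(dc.discounting_auc(c))
        assert auc[0] > auc[1] > auc[2]

    def test_auc_anticorrelates_with_log_kS(self, cohort40):
        subs, choices = cohort40
        from scipy.stats import spearmanr
        aucs = [dc.discounting_auc(c) for c in choices]
        log_kS = [s.log_kS for s in subs]
        assert spearmanr(aucs, log_kS).statistic < -0.7


class TestLoso:
    def test_median_split_assigns_ties_low(self):
        labels = dc.median_split_labels(np.array([1.0, 2.0, 2.0, 3.0, 4.0]))
        np.testing.assert_array_equal(labels, [0, 0, 0, 1, 1])

    def test_irls_matches_sklearn(self):
        sklearn = pytest.importorskip("sklearn.linear_model")
        rng = np.random.default_rng(0)
        X = rng.normal(size=(60, 2))
        y = (X[:, 0] + 0.5 * rng.normal(size=60) > 0).astype(float)
        ridge = 1e-3
        Xd = np.column_stack([np.ones(60), X])
        w = dc._batched_irls(Xd, y[None, :], ridge=ridge)[0]
        clf = sklearn.LogisticRegression(C=1.0 / ridge, solver="lbfgs",
                                         max_iter=2000, tol=1e-10)
        clf.fit(X, y)
        # sklearn does not penalise the intercept; slopes should agree closely
        np.testing.assert_allclose(w[1:], clf.coef_[0], rtol=0.02, atol=0.02)

    def test_detects_planted_association(self):
        subs = sample_cohort(40, CohortConfig(coupling=-0.8), seed=2)
        lam = np.array([s.fbt_params["hi_share"]["lambda"] for s in subs])
        log_kS = np.array([s.log_kS for s in subs])
        res = dc.loso_classify(lam, log_kS, n_permutations=600, seed=7)
        assert res.p_value < 0.05
        assert res.median_ce < np.log(2)

    def test_null_is_not_extreme(self):
        subs = sample_cohort(40, CohortConfig(coupling=0.0), seed=103)
        lam = np.array([s.fbt_params["hi_share"]["lambda"] for s in subs])
        log_kS = np.array([s.log_kS for s in subs])
        res = dc.loso_classify(lam, log_kS, n_permutations=400, seed=7)
        assert res.p_value > 0.05

    def test_requires_ten_subjects(self):
        with pytest.raises(ValueError):
            dc.loso_classify(np.arange(5), np.arange(5.0), 10, 0)

    def test_compare_feature_sets_prefers_informative(self):
        subs = sample_cohort(40, CohortConfig(coupling=-0.8), seed=2)
        lam = np.array([s.fbt_params["hi_share"]["lambda"] for s in subs])
        tau = np.array([s.fbt_params["hi_share"]["tau"] for s in subs])
        log_kS = np.array([s.log_kS for s in subs])
        diff, p = dc.compare_feature_sets(lam, tau, log_kS,
                                          n_permutations=300, seed=5)
        assert diff < 0        # lambda yields lower (better) cross-entropy
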