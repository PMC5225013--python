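"""Assessment metrics, curation, decomposition, and domain scanning."""

import numpy as np
import pytest

import gpkin.expressions as ex
from gpkin.analysis import (CurationRules, aicc, curate, decompose,
                            domain_scan, r_squared, select_best)
from gpkin.exceptions import NoModelError, UndefinedRSquaredError
from gpkin.reference_models import BEST_MODEL, PRUNED_MODEL


class TestRSquared:
    def test_perfect_prediction_is_one(self, rng):
        y = rng.normal(0, 1, 20)
        assert r_squared(y, y) == 1.0

    def test_mean_predictor_is_zero(self, rng):
        y = rng.normal(5, 2, 20)
        assert r_squared(y, np.full(20, y.mean())) == pytest.approx(0.0,
                                                                    abs=1e-12)

    def test_can_be_negative(self):
        y = np.array([1.0, 2.0, 3.0])
        assert r_squared(y, np.array([10.0, 10.0, 10.0])) < 0

    def test_scale_invariance(self, rng):
        y = rng.normal(0, 1, 30)
        yhat = y + rng.normal(0, 0.3, 30)
        a = r_squared(y, yhat)
        b = r_squared(1000 * y, 1000 * yhat)
        assert a == pytest.approx(b, rel=1e-12)

    def test_constant_observations_undefined(self):
        with pytest.raises(UndefinedRSquaredError):
            r_squared([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


class TestAicc:
    def test_hand_computed_value(self):
        # N=10, SSE=1, k=2: 10*ln(0.1) + 4 + 12/7
        y = np.zeros(10)
        yhat = np.full(10, np.sqrt(0.1))
        expected = 10 * np.log(0.1) + 4 + 2 * 2 * 3 / (10 - 2 - 1)
        assert aicc(y, yhat, 2) == pytest.approx(expected, rel=1e-12)

    def test_parameter_penalty_is_monotone(self, rng):
        y = rng.normal(0, 1, 15)
        yhat = y + 0.1
        assert aicc(y, yhat, 3) > aicc(y, yhat, 2) > aicc(y, yhat, 1)

    def test_same_k_ranking_agrees_with_r2(self, rng):
        # within a cohort of equal parameter count, higher R^2 <=> lower AICc
        y = rng.normal(10, 3, 20)
        good = y + rng.normal(0, 0.5, 20)
        bad = y + rng.normal(0, 2.0, 20)
        assert r_squared(y, good) > r_squared(y, bad)
        assert aicc(y, good, 2) < aicc(y, bad, 2)

    def test_insufficient_dof_rejected(self):
        with pytest.raises(ValueError):
            aicc(np.zeros(4), np.ones(4), 3)


class TestCurate:
    RULES = CurationRules(n_random_probes=500)

    def test_low_r2_removed(self):
        cands = [(ex.parse("C0*t"), None, 0.79),
                 (ex.parse("C0*t"), None, 0.81)]
        survivors, verdicts = curate(cands, self.RULES)
        assert len(survivors) == 1
        assert verdicts[0].first_violation == "min_r2"
        assert verdicts[1].passed

    def test_singular_model_removed(self):
        cands = [(ex.parse("ln(t)*C0"), None, 0.95)]
        _, verdicts = curate(cands, self.RULES)
        assert verdicts[0].first_violation == "singularity"

    def test_negative_uptake_removed(self):
        cands = [(ex.parse("0.0 - C0*t"), None, 0.9)]
        _, verdicts = curate(cands, self.RULES)
        assert verdicts[0].first_violation == "nonnegativity"

    def test_pruned_reference_model_survives(self):
        cands = [(PRUNED_MODEL.tree,
                  PRUNED_MODEL.beta_mse, PRUNED_MODEL.stats["r2_train"])]
        survivors, verdicts = curate(cands, self.RULES)
        assert verdicts[0].passed
        assert len(survivors) == 1

    def test_order_independence(self):
        cands = [(ex.parse("C0*t"), None, 0.85),
                 (ex.parse("ln(t)*C0"), None, 0.9),
                 (ex.parse("C0+t"), None, 0.5),
                 (PRUNED_MODEL.tree, PRUNED_MODEL.beta_mse, 0.854)]
        surv_fwd, _ = curate(cands, self.RULES)
        surv_rev, _ = curate(cands[::-1], self.RULES)
        key = lambda c: ex.serialize(c[0])
        assert sorted(map(key, surv_fwd)) == sorted(map(key, surv_rev))


class TestSelectBest:
    def test_single_candidate(self):
        assert select_best(["m"], ges=[1.0]) == 0

    def test_min_ge_ordering(self):
        assert select_best(["a", "b"], ges=[1.0, 2.0]) == 0
        assert select_best(["a", "b"], ges=[3.0, 2.0]) == 1

    def test_synthetic_cohort_argmin(self, rng):
        ges = rng.uniform(0, 10, 25)
        assert select_best(list(range(25)), ges=ges) == int(np.argmin(ges))

    def test_ties_break_on_r2_then_size(self):
        idx = select_best(["a", "b", "c"], ges=[1.0, 1.0, 1.0],
                          r2s=[0.8, 0.9, 0.9], n_params=[4, 5, 3])
        assert idx == 2  # best r2 tie -> fewer parameters

    def test_training_r2_criterion(self):
        idx = select_best(["a", "b"], ges=[1.0, 9.0], r2s=[0.7, 0.95],
                          criterion="max_r2_train")
        assert idx == 1

    def test_empty_set_raises(self):
        with pytest.raises(NoModelError):
            select_best([])


class TestDecompose:
    def test_linear_only_model_is_single_component(self):
        tree = ex.parse("3.0*C0")
        rep = decompose(tree, None, "t", 3.0)
        assert len(rep.components) == 1
        assert rep.components[0].label == "linear"
        assert rep.shares(5.0)["linear"] == 1.0

    def test_concentration_components_of_best_model(self):
        rep = decompose(BEST_MODEL.tree, BEST_MODEL.beta_mse, "t", 3.0)
        labels = {c.label for c in rep.components}
        assert labels == {"linear", "quadratic", "sinusoidal"}

    def test_time_components_of_best_model(self):
        rep = decompose(BEST_MODEL.tree, BEST_MODEL.beta_mse, "C0", 20.0)
        labels = {c.label for c in rep.components}
        # constant + linear drift + quadratic-exponential transient
        assert "linear" in labels
        assert "exponential" in labels

    def test_components_sum_to_model_at_random_points(self, rng):
        rep = decompose(BEST_MODEL.tree, BEST_MODEL.beta_mse, "t", 3.0)
        for c0 in rng.uniform(0.1, 25.0, 25):
            total = rep.total(float(c0))
            direct = BEST_MODEL.uptake_exact(float(c0), 3.0)
            assert total == pytest.approx(direct, rel=1e-9)

    def test_pruned_model_has_no_sinusoidal_component(self):
        rep = decompose(PRUNED_MODEL.tree, PRUNED_MODEL.beta_mse, "t", 3.0)
        assert "sinusoidal" not in {c.label for c in rep.components}


class TestDomainScan:
    def test_monotone_model_peaks_at_right_endpoint(self):
        scan = domain_scan(lambda c0, t: 2.0 * np.asarray(c0) * t,
                           (0.0, 100.0), 3.0)
        assert scan.argmax_c0 == pytest.approx(100.0, abs=1e-6)
        assert scan.zero_crossing_c0 is None

    def test_parabolic_rate_maximum_and_zero(self):
        # uptake = c0 * (60 - c0) * t: rate max at 30, zero at 60
        scan = domain_scan(
            lambda c0, t: np.asarray(c0) * (60.0 - np.asarray(c0)) * t,
            (0.0, 100.0), 3.0)
        assert scan.argmax_c0 == pytest.approx(30.0, abs=1e-4)
        assert scan.max_rate == pytest.approx(30 * 30 / 1000.0, rel=1e-6)
        assert scan.zero_crossing_c0 == pytest.approx(60.0, abs=1e-6)

    def test_grid_convergence(self):
        coarse = domain_scan(PRUNED_MODEL.uptake, (0.0, 100.0), 3.0,
                             n_grid=501)
        fine = domain_scan(PRUNED_MODEL.uptake, (0.0, 100.0), 3.0,
                           n_grid=4001)
        assert abs(coarse.argmax_c0 - fine.argmax_c0) < 0.5
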