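"""Diagnostic statistics: oracles, closed forms and cross-checks."""

import itertools
import subprocess

import numpy as np
import pytest
from scipy import stats

from cytorigin.bagio import CATEGORIES, ClinicalCovariates
from cytorigin.errors import DataError, ParameterError
from cytorigin.evaluation import (PredictionSet, accuracy_bounds, binomial_ci,
                                  cancer_probability, delong_ci, diagnostic_score_mean,
                                  diagnostic_scores, evaluate_predictions,
                                  fleiss_kappa, landis_koch_label, micro_ovr_auroc,
                                  permutation_test, perturb_importance, topn_accuracy)


def random_prediction_set(rng, n):
    probs = rng.dirichlet(np.ones(5), size=n)
    labels = [CATEGORIES[i] for i in rng.integers(0, 5, n)]
    return PredictionSet(probs, labels)


class TestCancerProbability:
    def test_complement_of_benign(self):
        p = np.array([0.1, 0.2, 0.3, 0.1, 0.3])
        assert cancer_probability(p) == pytest.approx(0.7)
        assert cancer_probability(np.array([0, 0, 0, 0, 1.0])) == 0.0

    def test_invalid_vector_rejected(self):
        with pytest.raises(ParameterError):
            cancer_probability(np.array([0.5, 0.5, 0.5, 0.0, 0.0]))


class TestTopN:
    def test_three_case_enumeration(self):
        # true category ranked 1st, 2nd and 4th respectively
        probs = np.array([[0.5, 0.2, 0.1, 0.1, 0.1],
                          [0.3, 0.4, 0.1, 0.1, 0.1],
                          [0.3, 0.3, 0.2, 0.15, 0.05]])
        labels = ["digestive", "digestive", "blood_lymphatic"]
        ps = PredictionSet(probs, labels)
        assert topn_accuracy(ps, 1) == pytest.approx(1 / 3)
        assert topn_accuracy(ps, 2) == pytest.approx(2 / 3)
        assert topn_accuracy(ps, 3) == pytest.approx(2 / 3)

    def test_perfect_predictions(self):
        probs = np.eye(5)
        ps = PredictionSet(probs, list(CATEGORIES))
        for n in (1, 2, 3):
            assert topn_accuracy(ps, n) == 1.0

    def test_full_category_count_always_one(self, rng):
        ps = random_prediction_set(rng, 30)
        assert topn_accuracy(ps, 5) == 1.0

    def test_monotone_in_n(self, rng):
        for seed in range(20):
            ps = random_prediction_set(np.random.default_rng(seed), 25)
            accs = [topn_accuracy(ps, n) for n in (1, 2, 3)]
            assert accs[0] <= accs[1] <= accs[2]

    def test_invalid_n(self, rng):
        ps = random_prediction_set(rng, 5)
        with pytest.raises(ParameterError):
            topn_accuracy(ps, 0)
        with pytest.raises(ParameterError):
            topn_accuracy(ps, 6)


def brute_force_micro_auroc(ps):
    truth = ps.label_indices()
    onehot = np.zeros_like(ps.probs, dtype=bool)
    onehot[np.arange(ps.n), truth] = True
    y = onehot.ravel(order="F")
    s = ps.probs.ravel(order="F")
    pos, neg = s[y], s[~y]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


class TestAUROC:
    def test_matches_pair_counting_oracle_exactly(self):
        """Exhaustive positive-negative pair counting on 50 seeded sets."""
        for seed in range(50):
            rng = np.random.default_rng(seed)
            ps = random_prediction_set(rng, int(rng.integers(4, 21)))
            if len(set(ps.labels)) < 2:
                continue
            assert micro_ovr_auroc(ps, with_ci=False)["auroc"] == pytest.approx(
                brute_force_micro_auroc(ps), abs=1e-12)

    def test_perfect_and_constant_scores(self):
        probs = np.eye(5)[[0, 1, 2, 3, 4]] * 0.96 + 0.008
        ps = PredictionSet(probs, list(CATEGORIES))
        assert micro_ovr_auroc(ps, with_ci=False)["auroc"] == 1.0
        flat = PredictionSet(np.full((6, 5), 0.2),
                             [CATEGORIES[i % 2] for i in range(6)])
        assert micro_ovr_auroc(flat, with_ci=False)["auroc"] == 0.5

    def test_single_class_degenerate(self):
        ps = PredictionSet(np.full((4, 5), 0.2), ["benign"] * 4)
        with pytest.raises(DataError):
            micro_ovr_auroc(ps)

    def test_delong_ci_matches_r_proc(self):
        """DeLong CI cross-checked against the R pROC implementation."""
        rng = np.random.default_rng(7)
        y = rng.integers(0, 2, 40)
        y[:3] = 1
        y[3:6] = 0
        scores = rng.normal(size=40) + y
        lo, hi = delong_ci(y, scores)
        rcode = f"""
suppressMessages(library(pROC))
y <- c({','.join(map(str, y))})
s <- c({','.join(map(str, scores))})
ci <- ci.auc(roc(y, s, quiet=TRUE), method="delong")
cat(ci[1], ci[3])
"""
        out = subprocess.run(["Rscript", "-e", rcode], capture_output=True, text=True)
        r_lo, r_hi = map(float, out.stdout.split())
        assert lo == pytest.approx(r_lo, abs=1e-6)
        assert hi == pytest.approx(r_hi, abs=1e-6)


class TestBinomialCI:
    def test_boundaries(self):
        assert binomial_ci(10, 10)[1] == 1.0
        assert binomial_ci(0, 10)[0] == 0.0

    def test_beta_quantile_oracle(self):
        lo, hi = binomial_ci(5, 10, 0.95)
        assert lo == pytest.approx(stats.beta.ppf(0.025, 5, 6), abs=1e-12)
        assert hi == pytest.approx(stats.beta.ppf(0.975, 6, 5), abs=1e-12)

    def test_contains_point_estimate(self):
        for k, n in [(1, 7), (3, 9), (8, 11)]:
            lo, hi = binomial_ci(k, n)
            assert lo <= k / n <= hi

    def test_invalid_counts(self):
        with pytest.raises(ParameterError):
            binomial_ci(11, 10)


class TestDiagnosticScore:
    def test_scoring_rules(self):
        etas = diagnostic_scores(
            ["benign", "digestive", "respiratory", "digestive"],
            ["digestive", "digestive", "digestive", "digestive"])
        assert list(etas) == [0, 2, 1, 2]
        assert diagnostic_score_mean(etas)["mean"] == pytest.approx(1.25)

    def test_all_correct_is_two(self):
        etas = diagnostic_scores(list(CATEGORIES), list(CATEGORIES))
        assert diagnostic_score_mean(etas)["mean"] == 2.0

    def test_benign_malignant_confusion_is_zero(self):
        assert diagnostic_scores(["respiratory"], ["benign"])[0] == 0
        assert diagnostic_scores(["benign"], ["respiratory"])[0] == 0

    def test_wrong_origin_right_malignancy_is_one(self):
        preds = ["digestive", "respiratory", "female_reproductive"]
        truth = ["respiratory", "female_reproductive", "digestive"]
        assert diagnostic_score_mean(diagnostic_scores(preds, truth))["mean"] == 1.0


class TestFleissKappa:
    def test_complete_agreement(self):
        M = np.array([[4, 0, 0], [0, 4, 0], [4, 0, 0], [0, 0, 4]])
        assert fleiss_kappa(M).kappa == pytest.approx(1.0)

    def test_hand_computed_toy(self):
        # 4 cases x 3 raters over 2 categories
        M = np.array([[3, 0], [2, 1], [1, 2], [0, 3]])
        n, r = 4, 3
        p_i = ((M**2).sum(axis=1) - r) / (r * (r - 1))
        p_o = p_i.mean()
        p_j = M.sum(axis=0) / (n * r)
        p_e = (p_j**2).sum()
        expected = (p_o - p_e) / (1 - p_e)
        assert fleiss_kappa(M).kappa == pytest.approx(expected, abs=1e-12)

    def test_landis_koch_bins(self):
        assert landis_koch_label(0.365) == "fair"
        assert landis_koch_label(-0.1) == "poor"
        assert landis_koch_label(0.1) == "slight"
        assert landis_koch_label(0.5) == "moderate"
        assert landis_koch_label(0.7) == "substantial"
        assert landis_koch_label(0.95) == "almost perfect"

    def test_random_ratings_near_zero(self):
        rng = np.random.default_rng(3)
        M = np.zeros((2000, 4), dtype=int)
        for i in range(2000):
            for _ in range(5):
                M[i, rng.integers(4)] += 1
        res = fleiss_kappa(M)
        assert abs(res.kappa) < 0.05

    def test_unequal_rater_counts_rejected(self):
        with pytest.raises(DataError):
            fleiss_kappa(np.array([[2, 1], [1, 1]]))


class TestAccuracyBounds:
    def test_closed_form(self):
        assert accuracy_bounds(0.8, 80, 20) == pytest.approx((0.64, 0.84))

    def test_no_uncertain_cases_collapse(self):
        lo, hi = accuracy_bounds(0.77, 123, 0)
        assert lo == hi == pytest.approx(0.77)

    def test_bracketing_property(self, rng):
        for _ in range(20):
            acc = rng.uniform()
            nk, nu = int(rng.integers(1, 100)), int(rng.integers(0, 100))
            lo, hi = accuracy_bounds(acc, nk, nu)
            assert lo <= acc + 1e-12 and acc <= hi + 1e-12
            assert (lo == hi) == (nu == 0)

    def test_invalid_counts(self):
        with pytest.raises(ParameterError):
            accuracy_bounds(0.5, 0, 10)


class TestStratifiedEval:
    def test_single_stratum_equals_unstratified(self, rng):
        ps = random_prediction_set(rng, 24)
        ps.strata["site"] = np.array(["hydrothorax"] * 24)
        from cytorigin.evaluation import stratified_eval

        strat = stratified_eval(ps, "site")["hydrothorax"]
        full = evaluate_predictions(ps)
        assert strat.auroc == pytest.approx(full.auroc)
        assert strat.topn == full.topn

    def test_per_stratum_delegation_and_counts(self, rng):
        from cytorigin.evaluation import stratified_eval

        ps = random_prediction_set(rng, 30)
        tags = np.array(["hydrothorax"] * 15 + ["ascites"] * 15)
        ps.strata["site"] = tags
        reports = stratified_eval(ps, "site")
        assert sum(r.n for r in reports.values()) == 30
        half = ps.subset(tags == "ascites")
        assert reports["ascites"].auroc == pytest.approx(
            micro_ovr_auroc(half)["auroc"])

    def test_unknown_stratifier(self, rng):
        from cytorigin.evaluation import stratified_eval

        with pytest.raises(ParameterError):
            stratified_eval(random_prediction_set(rng, 8), "hospital")


class TestPermutationTest:
    def test_identical_sets_give_one(self):
        x = np.arange(10.0)
        assert permutation_test(x, x, reps=500, seed=0) == 1.0

    def test_reproducible(self, rng):
        a, b = rng.normal(size=12), rng.normal(size=12)
        p1 = permutation_test(a, b, reps=1000, seed=5)
        p2 = permutation_test(a, b, reps=1000, seed=5)
        assert p1 == p2

    def test_matches_exhaustive_sign_flip_enumeration(self, rng):
        """10 paired cases with all-positive differences: exact two-sided
        p = 2/2^10; the Monte-Carlo estimate must agree within sampling error."""
        diff = rng.uniform(0.5, 1.5, size=10)
        a = np.zeros(10)
        b = -diff
        obs = abs(diff.mean())
        exact = sum(1 for signs in itertools.product([-1, 1], repeat=10)
                    if abs(np.mean(signs * diff)) >= obs - 1e-12) / 2**10
        assert exact == pytest.approx(2 / 1024)
        reps = 4000
        p = permutation_test(a, b, reps=reps, seed=1)
        se = np.sqrt(exact * (1 - exact) / reps)
        assert abs(p - exact) < 4 * se + 2 / reps

    def test_minimum_reps_enforced(self):
        with pytest.raises(ParameterError):
            permutation_test(np.ones(4), np.zeros(4), reps=50)


class TestPerturbImportance:
    @staticmethod
    def _cases(rng, n, label_from_site=False):
        cases = []
        for _ in range(n):
            cov = ClinicalCovariates(int(rng.integers(18, 91)),
                                     "male" if rng.random() < 0.5 else "female",
                                     "ascites" if rng.random() < 0.5 else "hydrothorax")
            y = (0 if cov.site == "ascites" else 2) if label_from_site \
                else int(rng.integers(5))
            cases.append((None, cov, y))
        return cases

    def test_covariate_blind_model_has_near_zero_deltas(self, rng):
        from cytorigin.mil_models import ProbabilityVector

        def blind_predict(bag, cov):
            p = np.full(5, 0.1)
            p[0] = 0.6
            return ProbabilityVector(p)

        rep = perturb_importance(blind_predict, self._cases(rng, 500), seed=0)
        assert abs(rep.delta_age) < 0.02
        assert abs(rep.delta_sex) < 0.02
        assert abs(rep.delta_site) < 0.02

    def test_site_oracle_model_recovers_site_dominance(self, rng):
        from cytorigin.mil_models import ProbabilityVector

        def site_predict(bag, cov):
            p = np.full(5, 0.05)
            p[0 if cov.site == "ascites" else 2] = 0.8
            return ProbabilityVector(p / p.sum())

        cases = self._cases(rng, 400, label_from_site=True)
        rep = perturb_importance(site_predict, cases, seed=0)
        assert rep.delta_site > rep.delta_sex
        assert rep.delta_site > rep.delta_age
        assert rep.delta_site > 0.5

    def test_image_only_model_not_applicable(self):
        with pytest.raises(ParameterError):
            perturb_importance(lambda b, c: None, [], uses_clinical=False)
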