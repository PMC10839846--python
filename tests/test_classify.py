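import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from tmfc.classify import (
    compare_auc_models,
    rank_auc,
    roc_auc_bootstrap,
    run_classification_suite,
    stepwise_logistic,
    youden_cutpoint,
)


def brute_force_auc(scores, labels):
    """Pairwise Mann–Whitney count: P(score_pos > score_neg) + 0.5 P(tie)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def textbook_kruskal(*groups):
    """H statistic with tie correction, straight from the rank formula."""
    pooled = np.concatenate(groups)
    ranks = sps.rankdata(pooled)
    n = len(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1 - ((counts**3 - counts).sum()) / (n**3 - n)
    return h / tie


class TestStepwiseLogistic:
    def test_aic_equals_hand_computed_bernoulli_likelihood(self):
        x = pd.DataFrame({"x": [-2.0, -1.0, -0.5, 0.5, 1.0, 2.0]})
        y = np.array([0, 0, 1, 0, 1, 1])
        spec = stepwise_logistic(x, y, direction="forward")
        res = spec.model
        probs = np.asarray(res.fittedvalues)
        ll = np.sum(y * np.log(probs) + (1 - y) * np.log(1 - probs))
        k = len(res.params)
        assert spec.aic == pytest.approx(2 * k - 2 * ll, abs=1e-8)

    def test_informative_feature_selected_among_noise(self):
        hits = 0
        runs = 20
        for seed in range(runs):
            rng = np.random.default_rng(seed)
            n = 150
            X = pd.DataFrame(rng.standard_normal((n, 10)),
                             columns=[f"x{j}" for j in range(10)])
            logits = 2.0 * X["x0"]
            y = (rng.random(n) < 1 / (1 + np.exp(-logits))).astype(int)
            spec = stepwise_logistic(X, y)
            hits += "x0" in spec.selected
        assert hits >= int(0.9 * runs)

    def test_null_features_rarely_selected(self):
        sizes = []
        for seed in range(15):
            rng = np.random.default_rng(100 + seed)
            X = pd.DataFrame(rng.standard_normal((80, 8)),
                             columns=[f"x{j}" for j in range(8)])
            y = rng.integers(0, 2, 80)
            sizes.append(len(stepwise_logistic(X, y).selected))
        # AIC admits ~15.7% of pure-noise variables per candidate
        assert np.mean(sizes) < 8 * 0.35
        assert min(sizes) == 0

    def test_aic_trace_is_strictly_decreasing(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.standard_normal((100, 5)),
                         columns=list("abcde"))
        y = (X["a"].to_numpy() + 0.5 * rng.standard_normal(100) > 0).astype(int)
        trace = stepwise_logistic(X, y).aic_trace
        assert all(b < a for a, b in zip(trace, trace[1:]))

    def test_perfect_separation_warns_but_returns(self):
        X = pd.DataFrame({"x": [-3.0, -2.0, -1.0, 1.0, 2.0, 3.0]})
        y = np.array([0, 0, 0, 1, 1, 1])
        with pytest.warns(RuntimeWarning, match="separation"):
            spec = stepwise_logistic(X, y)
        assert np.isfinite(spec.aic)


class TestRankAuc:
    def test_perfect_separation_gives_one(self):
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        labels = np.array([0, 0, 1, 1])
        assert rank_auc(scores, labels) == 1.0
        cut, sens, spec = youden_cutpoint(scores, labels)
        assert sens == 1.0 and spec == 1.0

    def test_fully_tied_scores_give_half(self):
        assert rank_auc(np.ones(10), np.array([0, 1] * 5)) == 0.5

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_pairwise_count(self, seed):
        rng = np.random.default_rng(seed)
        scores = np.round(rng.random(30), 1)  # force ties
        labels = rng.integers(0, 2, 30)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        assert rank_auc(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels), abs=1e-12
        )


class TestBootstrap:
    def test_replicate_count_and_determinism(self):
        rng = np.random.default_rng(0)
        scores = rng.random(40)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        r1 = roc_auc_bootstrap(scores, labels, n_boot=100, seed=7)
        r2 = roc_auc_bootstrap(scores, labels, n_boot=100, seed=7)
        assert len(r1.replicates) == 100
        np.testing.assert_array_equal(r1.replicates, r2.replicates)
        assert r1.n_redrawn == 0

    def test_confusion_matrix_totals(self):
        rng = np.random.default_rng(1)
        labels = np.array([0] * 25 + [1] * 15)
        scores = rng.random(40) + labels * 0.5
        res = roc_auc_bootstrap(scores, labels, n_boot=50, seed=0)
        assert res.confusion["tp"] + res.confusion["fn"] == 15
        assert res.confusion["tn"] + res.confusion["fp"] == 25

    def test_percentile_interval_covers_known_auc(self):
        # normal shift model with analytically known AUC = Phi(delta/sqrt(2))
        delta = 1.2
        true_auc = sps.norm.cdf(delta / np.sqrt(2))
        rng = np.random.default_rng(2)
        covered = 0
        runs = 60
        for seed in range(runs):
            neg = rng.standard_normal(60)
            pos = rng.standard_normal(60) + delta
            scores = np.concatenate([neg, pos])
            labels = np.array([0] * 60 + [1] * 60)
            res = roc_auc_bootstrap(scores, labels, n_boot=300, seed=seed)
            lo, hi = np.percentile(res.replicates, [2.5, 97.5])
            covered += lo <= true_auc <= hi
        assert covered / runs > 0.85


class TestCompareAucModels:
    def test_identical_sets_give_null_result(self):
        reps = np.random.default_rng(0).random(100)
        h, p = compare_auc_models(reps, reps.copy(), reps.copy())
        assert h == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_disjoint_ranges_are_significant(self):
        a = np.linspace(0.5, 0.6, 200)
        b = np.linspace(0.8, 0.9, 200)
        _, p = compare_auc_models(a, b)
        assert p < 1e-10

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_textbook_h(self, seed):
        rng = np.random.default_rng(seed)
        groups = [np.round(rng.random(20), 2) for _ in range(3)]
        h, _ = compare_auc_models(*groups)
        assert h == pytest.approx(textbook_kruskal(*groups), abs=1e-10)


def _classification_cohort(rng, effect=1.0, n=40):
    rows = []
    for g, size in (("CN_Abneg", n), ("AD_Abpos", n // 2)):
        for _ in range(size):
            shift = effect if g == "AD_Abpos" else 0.0
            rows.append({
                "group": g,
                "age": rng.normal(75 + 4 * (shift > 0), 7),
                "sex": rng.integers(0, 2),
                "apoe4": int(rng.random() < (0.55 if shift else 0.23)),
                "flexibility_VIS": rng.normal(0.3 - 0.1 * shift, 0.08),
                "integration_VIS": rng.normal(0.2 + 0.1 * shift, 0.08),
            })
    return pd.DataFrame(rows)


class TestSuite:
    FEATURES = ["flexibility_VIS", "integration_VIS"]

    def test_informative_features_beat_risk_factors(self):
        wins = 0
        runs = 10
        for seed in range(runs):
            cohort = _classification_cohort(np.random.default_rng(seed))
            suite = run_classification_suite(cohort, self.FEATURES,
                                             n_boot=50, seed=seed)
            comp = suite["AD_Abpos_vs_CN_Abneg"]
            wins += comp["F+R"]["auc"].auc >= comp["R"]["auc"].auc
        assert wins >= int(0.9 * runs)

    def test_shuffled_labels_give_chance_auc(self):
        rng = np.random.default_rng(42)
        cohort = _classification_cohort(rng, effect=0.0)
        suite = run_classification_suite(cohort, self.FEATURES, n_boot=50, seed=0)
        for m in ("F", "R", "F+R"):
            auc = suite["AD_Abpos_vs_CN_Abneg"][m]["auc"].auc
            assert 0.4 <= auc <= 0.75  # in-sample optimism keeps this loose

    def test_deterministic_given_seed(self):
        cohort = _classification_cohort(np.random.default_rng(3))
        s1 = run_classification_suite(cohort, self.FEATURES, n_boot=30, seed=11)
        s2 = run_classification_suite(cohort, self.FEATURES, n_boot=30, seed=11)
        a1 = s1["AD_Abpos_vs_CN_Abneg"]["F+R"]["auc"]
        a2 = s2["AD_Abpos_vs_CN_Abneg"]["F+R"]["auc"]
        np.testing.assert_array_equal(a1.replicates, a2.replicates)

    def test_cross_validated_auc_is_not_more_optimistic(self):
        cohort = _classification_cohort(np.random.default_rng(6), effect=0.6)
        in_sample = run_classification_suite(cohort, self.FEATURES,
                                             n_boot=10, seed=0)
        out_of_fold = run_classification_suite(cohort, self.FEATURES,
                                               n_boot=10, seed=0,
                                               cross_validate=True)
        comp = "AD_Abpos_vs_CN_Abneg"
        assert (out_of_fold[comp]["F"]["auc"].auc
                <= in_sample[comp]["F"]["auc"].auc + 0.05)
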