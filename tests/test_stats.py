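"""Statistical battery: chi-square, t tests, logistic regression, ROC."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lungntcp.errors import (
    DegenerateDataError,
    InsufficientDataError,
    RankError,
)
from lungntcp.stats import (
    ContingencyTable2x2,
    chi_square_2x2,
    confusion_at_cutoff,
    logistic_fit,
    roc_curve,
    stratified_incidence,
    two_sample_t,
    two_sample_t_from_samples,
)

CHEMO_TABLE = ContingencyTable2x2(2, 64, 8, 35)


class TestChiSquare:
    def test_yates_corrected_matches_closed_form(self):
        stat, p = chi_square_2x2(CHEMO_TABLE)
        assert stat == pytest.approx(5.825, abs=5e-4)
        assert p < 0.05

    def test_uncorrected_pearson(self):
        stat, _ = chi_square_2x2(CHEMO_TABLE, continuity_correction=False)
        assert stat == pytest.approx(7.579, abs=5e-4)

    def test_no_association(self):
        stat, p = chi_square_2x2(ContingencyTable2x2(10, 10, 10, 10))
        assert stat == 0.0 and p == 1.0

    def test_zero_marginal_rejected(self):
        with pytest.raises(DegenerateDataError):
            chi_square_2x2(ContingencyTable2x2(0, 0, 5, 5))

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.tuples(*[st.integers(1, 60)] * 4))
    def test_correction_never_increases_statistic(self, cells):
        table = ContingencyTable2x2(*cells)
        corrected, _ = chi_square_2x2(table, True)
        plain, _ = chi_square_2x2(table, False)
        assert corrected <= plain + 1e-12


class TestTTest:
    def test_identical_groups(self):
        res = two_sample_t(5.0, 1.0, 20, 5.0, 1.0, 20)
        assert res.statistic == 0.0 and res.p_value == pytest.approx(1.0)

    def test_dosimetric_summary_example(self):
        # group summaries rounded to table precision give t ~ -4.58
        res = two_sample_t(25.9, 2.5, 99, 29.6, 1.6, 10)
        assert res.statistic == pytest.approx(-4.575, abs=5e-3)
        assert res.p_value < 0.001

    def test_pooled_equals_welch_balanced_equal_variance(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            m1, m2 = rng.normal(size=2)
            sd, n = float(rng.uniform(0.5, 3)), int(rng.integers(5, 40))
            a = two_sample_t(m1, sd, n, m2, sd, n, "pooled")
            b = two_sample_t(m1, sd, n, m2, sd, n, "welch")
            assert a.statistic == pytest.approx(b.statistic, abs=1e-12)
            assert a.df == pytest.approx(b.df, abs=1e-9)

    def test_summary_equals_samples(self):
        rng = np.random.default_rng(1)
        x1, x2 = rng.normal(0, 1, 30), rng.normal(0.5, 1.2, 25)
        res = two_sample_t_from_samples(x1, x2)
        direct = two_sample_t(
            x1.mean(), x1.std(ddof=1), 30, x2.mean(), x2.std(ddof=1), 25
        )
        assert res.statistic == pytest.approx(direct.statistic, rel=1e-12)

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            two_sample_t(1.0, 1.0, 1, 2.0, 1.0, 10)


class TestLogistic:
    def test_intercept_only_closed_form(self):
        y = np.array([1.0] * 10 + [0.0] * 99)
        res = logistic_fit(np.zeros((109, 0)), y)
        assert res.coef[0] == pytest.approx(np.log(10 / 99), abs=1e-6)

    def test_two_by_two_slope_is_log_odds_ratio(self):
        x = np.array([0.0] * 66 + [1.0] * 43).reshape(-1, 1)
        y = np.array([1.0] * 2 + [0.0] * 64 + [1.0] * 8 + [0.0] * 35)
        res = logistic_fit(x, y, names=["chemo_gt6"])
        assert res.coef[1] == pytest.approx(np.log((8 * 64) / (2 * 35)), abs=1e-6)
        assert res.odds_ratios[1] == pytest.approx(512 / 70, rel=1e-5)

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(2)
        X = rng.normal(size=(200, 3))
        y = (rng.random(200) < 1 / (1 + np.exp(-(0.5 + X @ [1.0, -0.7, 0.2])))).astype(float)
        res = logistic_fit(X, y)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        np.testing.assert_allclose(res.coef, ref.params, atol=1e-6)
        np.testing.assert_allclose(res.se, ref.bse, atol=1e-5)

    def test_null_covariate_ci_covers_one_at_nominal_rate(self):
        # a 95% Wald CI should cover OR = 1 in the vast majority of null fits
        rng = np.random.default_rng(3)
        covered = 0
        for _ in range(20):
            x = rng.normal(size=(300, 1))
            y = (rng.random(300) < 0.3).astype(float)  # independent of x
            res = logistic_fit(x, y)
            covered += res.ci_low[1] < 1.0 < res.ci_high[1]
        assert covered >= 16

    def test_separation_flagged(self):
        x = np.linspace(-2, 2, 40).reshape(-1, 1)
        y = (x.ravel() > 0).astype(float)
        res = logistic_fit(x, y)
        assert res.separation

    def test_singular_design_rejected(self):
        x = np.ones((50, 2))  # duplicates the intercept twice over
        y = np.array([0.0, 1.0] * 25)
        with pytest.raises(RankError):
            logistic_fit(x, y)


def _auc_pair_counting(scores, labels):
    """Brute-force Mann-Whitney AUC: ties count one half."""
    scores = np.asarray(scores, dtype=float)
    pos = scores[np.asarray(labels) == 1]
    neg = scores[np.asarray(labels) == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRoc:
    def test_perfect_separation(self):
        roc = roc_curve([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert roc.auc == 1.0
        assert roc.youden_j == pytest.approx(1.0)
        assert 0.2 < roc.best_cutoff < 0.8

    def test_half_auc_from_pair_counting(self):
        # 2 of 4 positive-negative pairs correctly ordered
        roc = roc_curve([0.9, 0.35, 0.4, 0.8], [1, 1, 0, 0])
        assert roc.auc == pytest.approx(0.5)

    def test_label_inversion_symmetry(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=60)
        labels = (rng.random(60) < 0.4).astype(int)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        a = roc_curve(scores, labels).auc
        b = roc_curve(scores, 1 - labels).auc
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateDataError):
            roc_curve([0.1, 0.2], [1, 1])

    def test_matches_sklearn_auc(self):
        sk = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(5)
        scores = np.round(rng.normal(size=150), 1)  # force ties
        labels = (rng.random(150) < 0.35).astype(int)
        roc = roc_curve(scores, labels)
        assert roc.auc == pytest.approx(sk.roc_auc_score(labels, scores), abs=1e-12)

    @settings(deadline=None, max_examples=150, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_trapezoid_equals_pair_counting_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 40))
        scores = np.round(rng.normal(size=n), 1)
        labels = (rng.random(n) < 0.5).astype(int)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        roc = roc_curve(scores, labels)
        assert roc.auc == pytest.approx(_auc_pair_counting(scores, labels), abs=1e-12)

    def test_best_cutoff_attains_max_youden(self):
        rng = np.random.default_rng(6)
        scores = rng.normal(size=80)
        labels = (scores + rng.normal(0, 1.2, 80) > 0).astype(int)
        roc = roc_curve(scores, labels)
        j = roc.sensitivities + roc.specificities - 1.0
        assert roc.youden_j == pytest.approx(j.max(), abs=1e-12)
        cm = confusion_at_cutoff(scores, labels, roc.best_cutoff)
        assert cm.sensitivity + cm.specificity - 1 == pytest.approx(roc.youden_j)


class TestConfusion:
    def test_printed_classifier_counts(self):
        scores = np.array([0.15] * 9 + [0.05] + [0.12] * 30 + [0.04] * 69)
        labels = np.array([1] * 10 + [0] * 99)
        cm = confusion_at_cutoff(scores, labels, 0.0962)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (9, 30, 1, 69)
        # agreement to one unit in the third decimal (9/39 is truncated to
        # 0.230 in the reference tabulation)
        assert cm.sensitivity == pytest.approx(0.900, abs=1e-3)
        assert cm.specificity == pytest.approx(0.697, abs=1e-3)
        assert cm.accuracy == pytest.approx(0.716, abs=1e-3)
        assert cm.ppv == pytest.approx(0.230, abs=1e-3)
        assert cm.npv == pytest.approx(0.986, abs=1e-3)

    def test_extreme_cutoffs(self):
        scores = np.array([0.2, 0.4, 0.6, 0.8])
        labels = np.array([0, 1, 0, 1])
        lo = confusion_at_cutoff(scores, labels, 0.0)
        assert lo.sensitivity == 1.0 and lo.specificity == 0.0
        hi = confusion_at_cutoff(scores, labels, 1.0)
        assert hi.sensitivity == 0.0 and hi.specificity == 1.0

    def test_undefined_ratio_absent_not_zero(self):
        cm = confusion_at_cutoff(
            np.array([0.9, 0.8]), np.array([1, 0]), 0.0
        )  # nothing predicted negative
        assert cm.npv is None

    def test_accuracy_decomposition(self):
        rng = np.random.default_rng(7)
        scores = rng.random(200)
        labels = (rng.random(200) < 0.3).astype(int)
        cm = confusion_at_cutoff(scores, labels, 0.5)
        prev = labels.mean()
        assert cm.accuracy == pytest.approx(
            cm.sensitivity * prev + cm.specificity * (1 - prev), abs=1e-12
        )


class TestStratifiedIncidence:
    def test_printed_rates(self):
        scores = np.array([0.15] * 9 + [0.05] + [0.12] * 30 + [0.04] * 69)
        labels = np.array([1] * 10 + [0] * 99)
        si = stratified_incidence(scores, labels, 0.0962)
        assert si.rate_below == pytest.approx(1 / 70)
        assert si.rate_above == pytest.approx(9 / 39)
        assert round(100 * si.rate_below, 2) == 1.43
        assert round(100 * si.rate_above, 2) == 23.08
        assert si.p_value < 0.05

    def test_all_events_above(self):
        scores = np.array([1.0, 1.0, 0.1, 0.1])
        labels = np.array([1, 1, 0, 0])
        si = stratified_incidence(scores, labels, 0.5)
        assert si.rate_below == 0.0 and si.rate_above == 1.0

    def test_agrees_with_confusion_accounting(self):
        rng = np.random.default_rng(8)
        scores = rng.random(150)
        labels = (rng.random(150) < 0.25).astype(int)
        cut = 0.6
        si = stratified_incidence(scores, labels, cut)
        cm = confusion_at_cutoff(scores, labels, cut)
        assert si.events_above == cm.tp and si.n_above == cm.tp + cm.fp
        assert si.events_below == cm.fn and si.n_below == cm.fn + cm.tn

    def test_empty_stratum_rejected(self):
        with pytest.raises(DegenerateDataError):
            stratified_incidence(np.array([1.0, 2.0]), np.array([0, 1]), 5.0)
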