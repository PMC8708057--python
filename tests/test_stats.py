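"""Agreement, regression thresholds, rank tests, normality, median CIs and
response classification."""

from datetime import date, timedelta

import numpy as np
import pytest

from edemaquant import (
    Visit,
    classify_response,
    generate_cohort,
    icc_agreement,
    kruskal_conover,
    ks_normality,
    linreg_threshold,
    median_ci,
)


def icc21_oracle(x, y):
    """Textbook two-way ANOVA ICC(2,1): absolute agreement, single measure."""
    data = np.column_stack([x, y])
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sse = ((data - grand) ** 2).sum() - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestICC:
    def test_perfect_agreement(self):
        x = np.arange(20, dtype=float)
        res = icc_agreement(x, x)
        assert res.icc == pytest.approx(1.0, abs=1e-9)
        assert res.n_pairs == 20

    def test_matches_formula_oracle(self):
        rng = np.random.default_rng(11)
        x = rng.normal(2.0, 1.0, size=60)
        y = x + rng.normal(0, 0.3, size=60)
        res = icc_agreement(x, y)
        assert res.icc == pytest.approx(icc21_oracle(x, y), abs=1e-6)
        assert res.ci_low <= res.icc <= res.ci_high

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=500)
        y = rng.normal(size=500)
        assert abs(icc_agreement(x, y).icc) <= 0.1

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=40)
        y = x + rng.normal(0, 0.5, size=40)
        a = icc_agreement(x, y).icc
        b = icc_agreement(3.0 * x + 7.0, 3.0 * y + 7.0).icc
        assert a == pytest.approx(b, abs=1e-9)

    def test_errors(self):
        with pytest.raises(ValueError):
            icc_agreement([1.0, 2.0], [1.0, 2.0])  # too short
        with pytest.raises(ValueError):
            icc_agreement([1.0] * 5, [1.0] * 5)  # zero variance


class TestLinregThreshold:
    def test_exact_line(self):
        ev = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = linreg_threshold(2.0 * ev + 5.0, ev)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(5.0)
        assert res.r == pytest.approx(1.0)

    def test_flat_feature_degenerate(self):
        ev = np.array([1.0, 2.0, 3.0, 4.0])
        res = linreg_threshold(np.full(4, 386.06), ev)
        assert res.degenerate
        assert res.intercept == pytest.approx(386.06)
        assert res.r == 0.0 and res.p_value == 1.0

    def test_zero_ev_rows_excluded(self):
        ev = np.array([0.0, 0.0, 1.0, 2.0, 3.0])
        feat = np.array([999.0, 999.0, 7.0, 9.0, 11.0])
        res = linreg_threshold(feat, ev)
        assert res.n == 3
        assert res.intercept == pytest.approx(5.0)

    def test_errors(self):
        with pytest.raises(ValueError):
            linreg_threshold([1.0, 2.0], [1.0, 2.0])  # < 3 pairs
        with pytest.raises(ValueError):
            linreg_threshold([1.0, 2.0, 3.0], [2.0, 2.0, 2.0])  # no EV spread

    def test_intercept_recovery_on_synthetic_cohorts(self):
        """The fitted zero-EV intercept is unbiased for the generating
        intercept and its 95% CI covers it at roughly the nominal rate."""
        hits = 0
        intercepts = []
        n_rep = 100
        for s in range(n_rep):
            df = generate_cohort(seed=s)
            res = linreg_threshold(df["cft_um"], df["ev_mm3"])
            intercepts.append(res.intercept)
            lo, hi = res.intercept_ci
            hits += lo <= 386.06 <= hi
        assert np.mean(intercepts) == pytest.approx(386.06, abs=10.0)
        assert 0.88 <= hits / n_rep <= 1.0


class TestKruskalConover:
    def test_identical_groups_h_zero(self):
        g = {k: list(range(1, 11)) for k in "abc"}
        res = kruskal_conover(g)
        assert res.h_statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0)

    def test_constant_data_h_zero(self):
        res = kruskal_conover({"a": [5.0] * 4, "b": [5.0] * 4})
        assert res.h_statistic == 0.0 and res.p_value == 1.0

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(1)
        groups = {f"g{i}": rng.normal(0, 1, 30) for i in range(3)}
        groups["shifted"] = rng.normal(2.0, 1, 30)
        res = kruskal_conover(groups)
        assert res.p_value < 0.001
        pair = res.pairwise_p.loc["shifted", "g0"]
        assert pair < 0.01
        assert res.pairwise_p.loc["g0", "g1"] > 0.05

    def test_power_against_2sd_shift(self):
        rng = np.random.default_rng(9)
        rejections = 0
        n_rep = 100
        for _ in range(n_rep):
            groups = {
                "a": rng.normal(0, 1, 30),
                "b": rng.normal(0, 1, 30),
                "c": rng.normal(2.0, 1, 30),
            }
            rejections += kruskal_conover(groups).p_value < 0.05
        assert rejections / n_rep > 0.8

    def test_h_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        groups = {k: rng.uniform(0.1, 5, 20) for k in "abcd"}
        h1 = kruskal_conover(groups).h_statistic
        h2 = kruskal_conover({k: np.log(v) for k, v in groups.items()}).h_statistic
        assert h1 == pytest.approx(h2, rel=1e-12)

    def test_pairwise_matrix_shape(self):
        rng = np.random.default_rng(0)
        groups = {k: rng.normal(size=10) for k in "abc"}
        res = kruskal_conover(groups)
        m = res.pairwise_p
        assert list(m.index) == list("abc")
        assert np.allclose(m.values, m.values.T)
        assert np.all(np.diag(m.values) == 1.0)

    def test_errors(self):
        with pytest.raises(ValueError):
            kruskal_conover({"a": [1.0, 2.0]})
        with pytest.raises(ValueError):
            kruskal_conover({"a": [1.0, 2.0], "b": [1.0]})


class TestKSNormality:
    def test_exponential_rejected(self):
        rng = np.random.default_rng(8)
        x = rng.exponential(size=200)
        _, p = ks_normality(x, seed=0)
        assert p < 0.01

    def test_normal_sample_not_rejected(self):
        rng = np.random.default_rng(8)
        x = rng.normal(10, 2, size=200)
        _, p = ks_normality(x, seed=0)
        assert p > 0.05

    def test_null_p_values_roughly_uniform(self):
        """Under the null the Monte-Carlo p-value should be ~Uniform(0,1)."""
        from scipy.stats import kstest

        rng = np.random.default_rng(123)
        ps = []
        for s in range(100):
            x = rng.normal(size=50)
            ps.append(ks_normality(x, n_sim=500, seed=1000 + s)[1])
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_errors(self):
        with pytest.raises(ValueError):
            ks_normality([1.0, 2.0, 3.0])  # too few
        with pytest.raises(ValueError):
            ks_normality([2.0] * 10)  # zero SD


class TestMedianCI:
    def test_median_of_1_to_9(self):
        med, (lo, hi) = median_ci(np.arange(1.0, 10.0))
        assert med == 5.0
        assert lo <= med <= hi

    def test_ci_contains_median_symmetric_sample(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=41)
        med, (lo, hi) = median_ci(x)
        assert lo <= med <= hi

    def test_close_to_bootstrap_oracle(self):
        rng = np.random.default_rng(17)
        x = np.sort(rng.gamma(2.0, 1.0, size=50))
        med, (lo, hi) = median_ci(x)
        boot = np.median(
            rng.choice(x, size=(10000, x.size), replace=True), axis=1
        )
        blo, bhi = np.quantile(boot, [0.025, 0.975])
        # order-statistic CI endpoints within one order statistic of bootstrap
        def rank_dist(v, w):
            return abs(np.searchsorted(x, v) - np.searchsorted(x, w))

        assert rank_dist(lo, blo) <= 2
        assert rank_dist(hi, bhi) <= 2

    def test_too_small_errors(self):
        with pytest.raises(ValueError):
            median_ci([1.0, 2.0, 3.0, 4.0, 5.0])


def _series(cfts, injections, start=date(2021, 1, 1), step=30):
    return [
        Visit(when=start + timedelta(days=step * i), cft_um=c, injection=inj)
        for i, (c, inj) in enumerate(zip(cfts, injections))
    ]


class TestClassifyResponse:
    def test_no_injection_is_treatment_naive(self):
        visits = _series([420, 415, 418], [False, False, False])
        assert classify_response(visits) == "treatment-naive"

    def test_drop_after_first_injection_is_responder(self):
        visits = _series([500, 380], [True, False])
        assert classify_response(visits) == "responder"

    def test_drop_after_second_injection_is_responder(self):
        visits = _series([500, 470, 460, 340], [True, False, True, False])
        assert classify_response(visits) == "responder"

    def test_small_drop_is_not_response(self):
        visits = _series([500, 420, 460, 420, 430], [True, False, True, True, False])
        assert classify_response(visits) == "non-responder"

    def test_rebound_after_injection_free_period_is_recurrent(self):
        visits = [
            Visit(date(2021, 1, 1), 500, injection=True),
            Visit(date(2021, 2, 1), 410, injection=False),  # -90: no response
            Visit(date(2021, 4, 15), 530, injection=False),  # +120 after 104 free days
        ]
        assert classify_response(visits) == "recurrent"

    def test_rebound_too_soon_is_not_recurrent(self):
        visits = [
            Visit(date(2021, 1, 1), 500, injection=True),
            Visit(date(2021, 1, 20), 420, injection=False),
            Visit(date(2021, 2, 10), 540, injection=False),  # only 40 free days
        ]
        assert classify_response(visits) == "non-responder"

    def test_responder_takes_precedence_over_recurrence(self):
        visits = [
            Visit(date(2021, 1, 1), 600, injection=True),
            Visit(date(2021, 2, 1), 450, injection=False),  # responder by rule 2
            Visit(date(2021, 6, 1), 580, injection=False),
        ]
        assert classify_response(visits) == "responder"

    def test_errors(self):
        with pytest.raises(ValueError):
            classify_response([])
        bad = [
            Visit(date(2021, 2, 1), 500, injection=True),
            Visit(date(2021, 1, 1), 400, injection=False),
        ]
        with pytest.raises(ValueError):
            classify_response(bad)
        with pytest.raises(ValueError):
            classify_response(_series([500, float("nan")], [True, False]))
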