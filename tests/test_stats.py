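"""Closed-form oracles for the inferential procedures."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from strugglescope import stats as S
from strugglescope.errors import DegenerateInputError, DomainError


def oracle_pearson(x, y):
    """Textbook Pearson r, t-based p, and OLS slope with 95% CI."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = x.size
    xm, ym = x - x.mean(), y - y.mean()
    r = (xm * ym).sum() / math.sqrt((xm**2).sum() * (ym**2).sum())
    t = r * math.sqrt((n - 2) / (1 - r**2))
    p = 2 * sps.t.sf(abs(t), n - 2)
    slope = (xm * ym).sum() / (xm**2).sum()
    intercept = y.mean() - slope * x.mean()
    resid = y - (slope * x + intercept)
    se = math.sqrt((resid**2).sum() / (n - 2) / (xm**2).sum())
    tc = sps.t.ppf(0.975, n - 2)
    return r, p, slope, (slope - tc * se, slope + tc * se)


def oracle_welch(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    return t, df, 2 * sps.t.sf(abs(t), df)


def oracle_paired(x, y):
    d = np.asarray(x, float) - np.asarray(y, float)
    t = d.mean() / (d.std(ddof=1) / math.sqrt(d.size))
    return t, 2 * sps.t.sf(abs(t), d.size - 1)


def oracle_binomial_two_sided(k, n):
    """Minimum-likelihood two-sided exact binomial p at p0 = 0.5."""
    probs = np.array([math.comb(n, i) * 0.5**n for i in range(n + 1)])
    return probs[probs <= probs[k] * (1 + 1e-12)].sum()


def oracle_bky(p, q):
    """Step-by-step two-stage step-up, following the published definition."""
    p = np.asarray(p, float)
    m = p.size
    q1 = q / (1 + q)

    def bh(p, level):
        order = np.argsort(p)
        ps = p[order]
        crit = level * np.arange(1, m + 1) / m
        below = np.flatnonzero(ps <= crit)
        k = below[-1] + 1 if below.size else 0
        rej = np.zeros(m, bool)
        rej[order[:k]] = True
        return rej

    r1 = bh(p, q1).sum()
    if r1 == 0:
        return np.zeros(m, bool)
    if r1 == m:
        return np.ones(m, bool)
    return bh(p, q1 * m / (m - r1))


class TestCorrelateAucDuration:
    def test_perfect_linearity(self):
        d = np.array([1.0, 2.0, 3.0, 4.0])
        res = S.correlate_auc_duration(d, 2 * d)
        assert res.r == pytest.approx(1.0)
        assert res.slope == pytest.approx(2.0)

    def test_five_point_fixture_matches_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.1, 3.9, 6.2, 7.8, 9.9])
        res = S.correlate_auc_duration(x, y)
        r, p, slope, ci = oracle_pearson(x, y)
        assert res.r == pytest.approx(r, abs=1e-9)
        assert res.p == pytest.approx(p, abs=1e-9)
        assert res.slope == pytest.approx(slope, abs=1e-9)
        assert res.slope_ci == pytest.approx(ci, abs=1e-9)

    def test_randomized_fixtures_match_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = rng.integers(3, 21)
            x = rng.normal(size=n)
            y = 0.5 * x + rng.normal(size=n)
            if x.std() == 0 or y.std() == 0:
                continue
            res = S.correlate_auc_duration(x, y)
            r, p, slope, ci = oracle_pearson(x, y)
            assert res.r == pytest.approx(r, abs=1e-9)
            assert res.p == pytest.approx(p, abs=1e-9)
            assert res.slope_ci == pytest.approx(ci, abs=1e-9)

    def test_zero_variance_raises(self):
        with pytest.raises(DegenerateInputError):
            S.correlate_auc_duration(np.ones(5), np.arange(5.0))


class TestWelchT:
    def test_identical_groups(self):
        res = S.welch_t(np.array([1.0, 2, 3]), np.array([1.0, 2, 3]))
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_fixture_matches_formula(self):
        a, b = np.array([1.0, 2, 3]), np.array([2.0, 3, 4, 5])
        res = S.welch_t(a, b)
        t, df, p = oracle_welch(a, b)
        assert res.statistic == pytest.approx(t, abs=1e-9)
        assert res.df == pytest.approx(df, abs=1e-9)
        assert res.p == pytest.approx(p, abs=1e-9)

    def test_randomized_fixtures_match_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            a = rng.normal(0, 1, rng.integers(2, 20))
            b = rng.normal(0.5, 2, rng.integers(2, 20))
            res = S.welch_t(a, b)
            t, df, p = oracle_welch(a, b)
            assert res.statistic == pytest.approx(t, abs=1e-9)
            assert res.df == pytest.approx(df, abs=1e-9)
            assert res.p == pytest.approx(p, abs=1e-9)

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=8), rng.normal(1, 1, 9)
        r1, r2 = S.welch_t(a, b), S.welch_t(-3 * a, -3 * b)
        assert abs(r2.statistic) == pytest.approx(abs(r1.statistic))
        assert r2.p == pytest.approx(r1.p)


class TestPairedT:
    def test_zero_differences_degenerate(self):
        x = np.array([1.0, 2, 3])
        with pytest.raises(DegenerateInputError):
            S.paired_t(x, x)

    def test_differences_fixture(self):
        y = np.array([0.0, 0.0, 0.0])
        x = np.array([1.0, 2.0, 3.0])
        res = S.paired_t(x, y)
        t, p = oracle_paired(x, y)
        assert res.statistic == pytest.approx(t, abs=1e-9)  # 2/(1/sqrt 3)
        assert res.statistic == pytest.approx(2 * math.sqrt(3), abs=1e-9)
        assert res.p == pytest.approx(p, abs=1e-9)

    def test_sign_flip_antisymmetry(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=10), rng.normal(size=10)
        r1, r2 = S.paired_t(x, y), S.paired_t(y, x)
        assert r2.statistic == pytest.approx(-r1.statistic)
        assert r2.p == pytest.approx(r1.p)

    def test_randomized_fixtures_match_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            n = rng.integers(2, 20)
            x, y = rng.normal(size=n), rng.normal(size=n)
            t, p = oracle_paired(x, y)
            res = S.paired_t(x, y)
            assert res.statistic == pytest.approx(t, abs=1e-9)
            assert res.p == pytest.approx(p, abs=1e-9)


class TestPositiveAucProportion:
    @pytest.mark.parametrize(
        "pos, neg, expected_p",
        [(5, 5, 1.0), (0, 1, 1.0)],
    )
    def test_symmetric_cases(self, pos, neg, expected_p):
        aucs = np.array([1.0] * pos + [-1.0] * neg)
        assert S.positive_auc_proportion(aucs)["p"] == pytest.approx(expected_p)

    def test_nine_of_ten_matches_enumeration(self):
        aucs = np.array([1.0] * 9 + [-1.0])
        res = S.positive_auc_proportion(aucs)
        assert res["p"] == pytest.approx(oracle_binomial_two_sided(9, 10), abs=1e-12)

    def test_randomized_counts_match_enumeration(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            n = int(rng.integers(1, 40))
            k = int(rng.integers(0, n + 1))
            aucs = np.array([1.0] * k + [-1.0] * (n - k))
            res = S.positive_auc_proportion(aucs)
            assert res["p"] == pytest.approx(
                oracle_binomial_two_sided(k, n), abs=1e-9
            )


class TestBkyTwoStageFdr:
    def test_all_ones_no_rejections(self):
        assert not S.bky_two_stage_fdr(np.ones(10), q=0.05)["reject"].any()

    def test_all_zeros_all_rejected(self):
        assert S.bky_two_stage_fdr(np.zeros(10), q=0.05)["reject"].all()

    def test_fixture_matches_stepwise_oracle(self):
        p = np.array([0.001, 0.008, 0.04, 0.2, 0.9])
        got = S.bky_two_stage_fdr(p, q=0.05)["reject"]
        np.testing.assert_array_equal(got, oracle_bky(p, 0.05))

    def test_randomized_fixtures_match_oracle_and_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(6)
        for _ in range(100):
            m = int(rng.integers(1, 40))
            p = rng.random(m) ** rng.uniform(0.3, 3.0)
            got = S.bky_two_stage_fdr(p, q=0.05)["reject"]
            np.testing.assert_array_equal(got, oracle_bky(p, 0.05))
            sm = multipletests(p, alpha=0.05, method="fdr_tsbky")[0]
            np.testing.assert_array_equal(got, sm)

    def test_superset_of_bh_at_stage_one_level(self):
        """Stage 2 reruns BH at a level >= q/(1+q), so the two-stage
        rejections contain the BH rejections at the stage-1 level."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            p = rng.random(int(rng.integers(1, 40)))
            q = 0.05
            two = S.bky_two_stage_fdr(p, q=q)["reject"]
            bh = S._bh_stepup(p, q / (1 + q))
            assert (bh & ~two).sum() == 0

    def test_out_of_range_p_raises(self):
        with pytest.raises(DomainError):
            S.bky_two_stage_fdr(np.array([0.5, 1.2]))

    def test_null_fdr_control(self):
        """Global-null false-rejection proportion stays within q + 2 MC se."""
        rng = np.random.default_rng(8)
        reps, m, q = 2000, 50, 0.05
        false = sum(
            S.bky_two_stage_fdr(rng.random(m), q=q)["reject"].any()
            for _ in range(reps)
        )
        rate = false / reps
        assert rate <= q + 2 * math.sqrt(q * (1 - q) / reps)


class TestNormalizeFrequencyByDay:
    def test_percent_of_day1(self):
        import pandas as pd

        df = pd.DataFrame(
            {
                "subject": ["a", "a", "b", "b"],
                "day": [1, 3, 1, 3],
                "frequency_hz": [0.1, 0.05, 0.2, 0.3],
            }
        )
        out = S.normalize_frequency_by_day(df)
        assert out.loc[(out.subject == "a") & (out.day == 1), "percent_of_day1"].iloc[0] == 100.0
        assert out.loc[(out.subject == "a") & (out.day == 3), "percent_of_day1"].iloc[0] == pytest.approx(50.0)
        assert out.loc[(out.subject == "b") & (out.day == 3), "percent_of_day1"].iloc[0] == pytest.approx(150.0)

    def test_zero_day1_subject_excluded(self):
        import pandas as pd

        df = pd.DataFrame(
            {
                "subject": ["a", "a", "b", "b"],
                "day": [1, 2, 1, 2],
                "frequency_hz": [0.0, 0.1, 0.1, 0.1],
            }
        )
        out = S.normalize_frequency_by_day(df)
        assert set(out["subject"]) == {"b"}
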