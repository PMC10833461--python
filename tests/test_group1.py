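"""Group-1 diagnostics: ASMD formulas, Hotelling T², Little's MCAR test.

The Little oracle is an independent brute-force EM written here from the
textbook recipe, plus the closed-form ML solution for the bivariate
monotone pattern; neither shares code with the package implementation.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pocdiag import (
    CohortTable,
    asmd,
    build_comparison_matrix,
    hotelling,
    little_mcar,
)
from pocdiag.group1 import _asmd_binary, _asmd_continuous, _em_mvn


def _two_group_cohort(x1, x0, extra=None):
    """Cohort whose POC is missing exactly for the x1 rows."""
    x1, x0 = np.asarray(x1, float), np.asarray(x0, float)
    poc = np.concatenate([np.full(len(x1), np.nan), np.zeros(len(x0))])
    cov = np.concatenate([x1, x0])
    data = {"cov": cov, "poc": poc}
    if extra is not None:
        data.update(extra)
    return CohortTable.from_dataframe(pd.DataFrame(data))


class TestComparisonMatrix:
    def test_encoding_arithmetic(self):
        rng = np.random.default_rng(0)
        n = 40
        df = pd.DataFrame(
            {
                "exposure": rng.integers(0, 2, n),
                "cont": rng.normal(size=n),
                "cat3": rng.choice(list("abc"), n),
                "poc": np.where(rng.random(n) < 0.3, np.nan, rng.normal(size=n)),
                "other": np.where(rng.random(n) < 0.3, np.nan, rng.normal(size=n)),
            }
        )
        t = CohortTable.from_dataframe(df, exposure="exposure")
        X, labels = build_comparison_matrix(t, "poc")
        # exposure + 1 continuous + 3 one-hot levels + 1 other-POC indicator
        assert X.shape[1] == 1 + 1 + 3 + 1
        assert "other_missing" in X.columns
        assert "other" not in X.columns  # values of other POCs never enter
        assert set(labels) == {0, 1}

    def test_no_other_pocs_no_indicators(self):
        df = pd.DataFrame(
            {"cont": np.arange(10.0), "poc": [np.nan, 1, 2, 3, 4, 5, 6, 7, np.nan, 9]}
        )
        t = CohortTable.from_dataframe(df)
        X, _ = build_comparison_matrix(t, "poc")
        assert not any(c.endswith("_missing") for c in X.columns)

    def test_zero_variance_dropped_with_warning(self):
        df = pd.DataFrame(
            {
                "flat": np.ones(10),
                "cont": np.arange(10.0),
                "poc": [np.nan, 1, 2, 3, 4, 5, 6, 7, np.nan, 9],
            }
        )
        t = CohortTable.from_dataframe(df)
        with pytest.warns(UserWarning, match="zero-variance"):
            X, _ = build_comparison_matrix(t, "poc")
        assert "flat" not in X.columns


class TestAsmd:
    def test_identical_strata_zero(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        t = _two_group_cohort(x, x)
        res = asmd(t, "poc")
        assert res.aggregate == pytest.approx(0.0)

    def test_hand_formula_unit_difference(self):
        # means 1 vs 0, both variances 1 -> ASMD = 1
        rng = np.random.default_rng(1)
        z = rng.normal(size=2000)
        z = (z - z.mean()) / z.std(ddof=1)
        t = _two_group_cohort(z + 1.0, z)
        res = asmd(t, "poc")
        assert res.per_covariate["cov"] == pytest.approx(1.0, abs=1e-12)

    def test_binary_formula(self):
        assert _asmd_binary(0.5, 0.5) == 0.0
        expected = abs(0.6 - 0.4) / np.sqrt((0.6 * 0.4 + 0.4 * 0.6) / 2)
        assert _asmd_binary(0.6, 0.4) == pytest.approx(expected)

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        x1, x0 = rng.normal(2, 1, 100), rng.normal(0, 1, 120)
        base = _asmd_continuous(x1, x0)
        scaled = _asmd_continuous(5.0 * x1 - 3.0, 5.0 * x0 - 3.0)
        assert scaled == pytest.approx(base, rel=1e-12)

    def test_small_stratum_flagged(self):
        t = _two_group_cohort([1.0], [0.0, 1.0, 2.0])
        res = asmd(t, "poc")
        assert "cov" in res.flagged
        assert np.isnan(res.per_covariate["cov"])

    def test_aggregate_ordering(self, default_cohort):
        for poc in default_cohort.poc_cols:
            res = asmd(default_cohort, poc)
            assert res.asmd_min <= res.aggregate <= res.asmd_max
            assert (res.per_covariate.dropna() >= 0).all()

    def test_mean_aggregate_flag(self, default_cohort):
        med = asmd(default_cohort, "ecog")
        mean = asmd(default_cohort, "ecog", aggregate="mean")
        assert med.aggregate == pytest.approx(med.per_covariate.dropna().median())
        assert mean.aggregate == pytest.approx(mean.per_covariate.dropna().mean())


class TestHotelling:
    def test_identical_strata_zero_statistic(self):
        x = np.arange(20.0)
        t = _two_group_cohort(x, x)
        res = hotelling(t, "poc")
        assert res.t2 == pytest.approx(0.0, abs=1e-20)
        assert res.p_value == pytest.approx(1.0)

    def test_univariate_reduction_to_t_squared(self):
        """With one comparison column, T² equals the squared pooled-variance
        two-sample t statistic."""
        rng = np.random.default_rng(3)
        x1, x0 = rng.normal(0.5, 1, 60), rng.normal(0, 1, 80)
        t = _two_group_cohort(x1, x0)
        res = hotelling(t, "poc")
        tt = stats.ttest_ind(x1, x0, equal_var=True)
        assert res.t2 == pytest.approx(tt.statistic**2, rel=1e-10)
        assert res.p_value == pytest.approx(tt.pvalue, rel=1e-10)

    def test_invariance_under_linear_maps(self):
        """T² is unchanged by any nonsingular linear transformation of the
        covariate matrix."""
        rng = np.random.default_rng(4)
        n = 120
        X = rng.normal(size=(n, 3))
        miss = rng.random(n) < 0.4
        poc = np.where(miss, np.nan, 0.0)

        def t2_of(mat):
            df = pd.DataFrame(mat, columns=["a", "b", "c"])
            df["poc"] = poc
            return hotelling(CohortTable.from_dataframe(df), "poc").t2

        base = t2_of(X)
        for _ in range(3):
            A = rng.normal(size=(3, 3)) + 3 * np.eye(3)
            assert t2_of(X @ A) == pytest.approx(base, rel=1e-8)

    def test_singular_covariance_rejected(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=30)
        df = pd.DataFrame(
            {"a": a, "b": 2 * a, "poc": np.where(rng.random(30) < 0.4, np.nan, 0.0)}
        )
        t = CohortTable.from_dataframe(df)
        with pytest.raises(np.linalg.LinAlgError, match="singular"):
            hotelling(t, "poc")


# --------------------------------------------------------------------- #
# independent Little oracles
# --------------------------------------------------------------------- #
def _brute_force_em(Y, n_iter=3000):
    """Textbook EM for MVN with missing data, written independently:
    row-by-row conditional expectations, no pattern grouping."""
    Y = np.asarray(Y, float)
    n, p = Y.shape
    mu = np.nanmean(Y, axis=0)
    S = np.diag(np.nanvar(Y, axis=0))
    for _ in range(n_iter):
        Ey = np.zeros((n, p))
        Eyy = np.zeros((p, p))
        for i in range(n):
            o = np.flatnonzero(~np.isnan(Y[i]))
            m = np.flatnonzero(np.isnan(Y[i]))
            yi = np.zeros(p)
            yi[o] = Y[i, o]
            if m.size:
                Soo_inv = np.linalg.inv(S[np.ix_(o, o)])
                yi[m] = mu[m] + S[np.ix_(m, o)] @ Soo_inv @ (Y[i, o] - mu[o])
                C = S[np.ix_(m, m)] - S[np.ix_(m, o)] @ Soo_inv @ S[np.ix_(o, m)]
            Ey[i] = yi
            Eyy += np.outer(yi, yi)
            if m.size:
                Eyy[np.ix_(m, m)] += C
        mu = Ey.mean(axis=0)
        S = Eyy / n - np.outer(mu, mu)
    return mu, S


def _little_d2(Y, mu, S):
    keys = {}
    for i, row in enumerate(np.isnan(Y)):
        keys.setdefault(tuple(row), []).append(i)
    d2, df = 0.0, 0
    p = Y.shape[1]
    for key, rows in keys.items():
        o = np.flatnonzero(~np.asarray(key))
        if o.size == 0:
            continue
        ybar = Y[np.ix_(rows, o)].mean(axis=0)
        diff = ybar - mu[o]
        d2 += len(rows) * diff @ np.linalg.inv(S[np.ix_(o, o)]) @ diff
        df += o.size
    return d2, df - p


@pytest.fixture()
def bivariate_monotone():
    rng = np.random.default_rng(7)
    n = 80
    y1 = rng.normal(0, 1, n)
    y2 = 0.6 * y1 + rng.normal(0, 0.8, n)
    y2[50:] = np.nan  # second variable missing for the tail block
    return np.column_stack([y1, y2])


class TestLittle:
    def test_complete_data_inapplicable(self):
        df = pd.DataFrame(
            {"a": [1.0, 2.0, 3.0, np.nan], "b": [1.0, 2.0, 3.0, 4.0]}
        )
        # single missingness pattern over the selected variable set
        t = CohortTable.from_dataframe(df.dropna().reset_index(drop=True), pocs=[])
        with pytest.raises(ValueError, match="at least one POC"):
            little_mcar(t)

    def test_single_pattern_flagged(self):
        # every row missing the same variable -> one pattern, df = 0
        df = pd.DataFrame({"a": [np.nan] * 6, "b": np.arange(6.0)})
        t = CohortTable.from_dataframe(df)
        res = little_mcar(t)
        assert not res.applicable

    def test_matches_brute_force_em(self, bivariate_monotone):
        """d² from the packaged EM equals the independent brute-force EM
        to 1e-8 on a 2-variable, 2-pattern dataset."""
        Y = bivariate_monotone
        mu_b, S_b = _brute_force_em(Y)
        d2_b, df_b = _little_d2(Y, mu_b, S_b)

        df = pd.DataFrame(Y, columns=["y1", "y2"])
        t = CohortTable.from_dataframe(df)
        res = little_mcar(t, tol=1e-13, ridge=0.0)
        assert res.df == df_b
        assert res.statistic == pytest.approx(d2_b, abs=1e-8)

    def test_matches_closed_form_mle(self, bivariate_monotone):
        """For the bivariate monotone pattern the ML estimates have a
        closed form (complete-case regression + full-margin moments)."""
        Y = bivariate_monotone
        comp = ~np.isnan(Y[:, 1])
        y1c, y2c = Y[comp, 0], Y[comp, 1]
        b = np.cov(y1c, y2c, ddof=0)[0, 1] / np.var(y1c)
        a = y2c.mean() - b * y1c.mean()
        mu1 = Y[:, 0].mean()
        s11 = np.var(Y[:, 0])  # ML, /n
        mu2 = a + b * mu1
        resid = y2c - (a + b * y1c)
        s22 = np.var(resid) + b**2 * s11
        s12 = b * s11
        mu = np.array([mu1, mu2])
        S = np.array([[s11, s12], [s12, s22]])
        d2_cf, df_cf = _little_d2(Y, mu, S)

        t = CohortTable.from_dataframe(pd.DataFrame(Y, columns=["y1", "y2"]))
        res = little_mcar(t, tol=1e-13, ridge=0.0)
        assert res.statistic == pytest.approx(d2_cf, abs=1e-6)
        assert res.df == df_cf

    def test_nonnegative_and_df_bookkeeping(self, default_cohort):
        from pocdiag import pattern_matrix

        res = little_mcar(default_cohort)
        assert res.statistic >= 0
        pm = pattern_matrix(default_cohort)
        assert res.n_patterns == len(pm.patterns)

    def test_mar_cohort_rejected(self, default_cohort):
        # the default cohort contains a strongly MAR POC
        assert little_mcar(default_cohort).p_value < 0.001
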