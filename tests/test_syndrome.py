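import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from syndromekit import syndrome
from syndromekit.syndrome import PopulationCovariance


def _traits(pops, values):
    rows = []
    k = 0
    for pop, vals in zip(pops, values):
        for v in vals:
            rows.append((f"i{k}", pop, *v))
            k += 1
    return pd.DataFrame(
        rows,
        columns=["individual_id", "population_id", "body_mass",
                 "metabolic_rate", "excretion_rate", "boldness"],
    )


class TestTransform:
    def test_log_and_sqrt_values(self):
        t = _traits(["A"], [[(1.0, 1.0, 1.0, 900.0)]])
        out = syndrome.transform_traits(t)
        assert out.loc[0, "body_mass"] == 0.0
        assert out.loc[0, "boldness"] == 30.0

    def test_nonpositive_log_trait_excluded(self):
        t = _traits(["A"], [[(0.0, 1.0, 1.0, 4.0)]])
        out = syndrome.transform_traits(t)
        assert np.isnan(out.loc[0, "body_mass"])
        assert out.loc[0, "boldness"] == 2.0

    def test_missing_propagates(self):
        t = _traits(["A"], [[(2.0, np.nan, 1.0, 4.0)]])
        out = syndrome.transform_traits(t)
        assert np.isnan(out.loc[0, "metabolic_rate"])


class TestAnova:
    def test_two_group_hand_oracle(self):
        # groups {1,2,3} and {4,5,6}: MSB = 13.5, MSW = 1 -> F = 13.5
        t = _traits(
            ["A", "B"],
            [[(v, 1, 1, 1) for v in (1, 2, 3)],
             [(v, 1, 1, 1) for v in (4, 5, 6)]],
        )
        r = syndrome.anova_by_population(t, "body_mass")
        assert r.F == pytest.approx(13.5, abs=1e-10)
        assert (r.df_between, r.df_within) == (1, 4)
        # two-group ANOVA F equals the squared pooled t statistic
        tstat, _ = stats.ttest_ind([1, 2, 3], [4, 5, 6])
        assert r.F == pytest.approx(tstat**2, abs=1e-10)

    def test_identical_group_means_give_zero_f(self):
        t = _traits(
            ["A", "B"],
            [[(v, 1, 1, 1) for v in (1, 2, 3)],
             [(v, 1, 1, 1) for v in (1, 2, 3)]],
        )
        assert syndrome.anova_by_population(t, "body_mass").F == pytest.approx(0.0)


class TestStandardize:
    def test_population_slices_have_zero_mean_unit_variance(self):
        rng = np.random.default_rng(0)
        t = _traits(
            ["A", "B"],
            [
                [tuple(rng.uniform(1, 10, 4)) for _ in range(20)],
                [tuple(rng.uniform(1, 10, 4)) for _ in range(20)],
            ],
        )
        out = syndrome.standardize_within(t)
        for _, sub in out.groupby("population_id"):
            for trait in ("body_mass", "boldness"):
                assert sub[trait].mean() == pytest.approx(0.0, abs=1e-12)
                assert sub[trait].var(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_zero_variance_errors(self):
        t = _traits(["A"], [[(2.0, 1, 1, 1)] * 5])
        with pytest.raises(ValueError, match="zero variance"):
            syndrome.standardize_within(t)

    def test_missing_stays_missing(self):
        rng = np.random.default_rng(1)
        vals = [tuple(rng.uniform(1, 10, 4)) for _ in range(10)]
        t = _traits(["A"], [vals])
        t.loc[0, "boldness"] = np.nan
        out = syndrome.standardize_within(t)
        assert np.isnan(out.loc[0, "boldness"])


class TestPopulationCov:
    def _std(self, rng, n=30, r=0.8):
        cov = np.array([[1, r], [r, 1]])
        X = rng.multivariate_normal([0, 0], cov, size=n)
        t = _traits(["A"], [[(*row, 1.0, 1.0) for row in X]])
        t["excretion_rate"] = rng.normal(size=n)
        t["boldness"] = rng.normal(size=n)
        return syndrome.standardize_within(t)

    def test_correlation_recovered_with_significance(self):
        rng = np.random.default_rng(3)
        std = self._std(rng, n=200, r=0.8)
        covs = syndrome.population_cov_matrices(std)
        c = covs["A"]
        # hand covariance oracle on the standardized columns
        x = std["body_mass"].to_numpy()
        y = std["metabolic_rate"].to_numpy()
        r_hand = float(np.mean((x - x.mean()) * (y - y.mean()))) / (
            x.std() * y.std()
        )
        assert c.S[0, 1] == pytest.approx(r_hand, abs=1e-10)
        assert c.p[0, 1] < 0.001
        assert np.allclose(np.diag(c.S), 1.0)

    def test_null_correlations_mostly_nonsignificant(self):
        rng = np.random.default_rng(12)
        hits = total = 0
        for _ in range(30):
            X = rng.standard_normal((60, 4))
            t = _traits(["A"], [[tuple(row) for row in X]])
            std = syndrome.standardize_within(t)
            c = syndrome.population_cov_matrices(std)["A"]
            iu = np.triu_indices(4, 1)
            assert np.all(np.abs(c.S[iu]) < 0.6)
            hits += int((c.p[iu] < 0.05).sum())
            total += len(iu[0])
        assert hits / total < 0.12

    def test_too_few_complete_cases_errors(self):
        t = _traits(["A"], [[(1.0, 2.0, 3.0, 4.0), (2.0, 1.0, 4.0, 3.0),
                             (3.0, 4.0, 1.0, 2.0)]])
        with pytest.raises(ValueError, match="complete cases"):
            syndrome.population_cov_matrices(
                syndrome.standardize_within(t)
            )


def _make_covs(mats, n=100):
    return {
        f"p{i}": PopulationCovariance(
            f"p{i}", np.asarray(S, float), n,
            np.zeros_like(mats[0]), np.zeros_like(mats[0])
        )
        for i, S in enumerate(mats)
    }


class TestHomogeneityFit:
    def test_identical_matrices_perfect_fit(self):
        S = np.array([[1, 0.3], [0.3, 1.0]])
        fit = syndrome.homogeneity_fit(_make_covs([S] * 4))
        assert fit.chi2 < 1e-6
        assert fit.rmsea == 0.0
        assert fit.cfi == 1.0
        assert fit.srmr < 1e-8
        assert not fit.heterogeneous

    def test_chi2_matches_direct_ml_discrepancy(self):
        # two groups with correlations +0.9 / -0.9: hand-evaluate the ML
        # discrepancy against the pooled matrix
        S1 = np.array([[1, 0.9], [0.9, 1]])
        S2 = np.array([[1, -0.9], [-0.9, 1]])
        covs = _make_covs([S1, S2], n=100)
        fit = syndrome.homogeneity_fit(covs)
        pooled = (S1 + S2) / 2
        direct = 0.0
        for S in (S1, S2):
            direct += 100 * (
                math.log(np.linalg.det(pooled)) - math.log(np.linalg.det(S))
                + np.trace(S @ np.linalg.inv(pooled)) - 2
            )
        assert fit.chi2 == pytest.approx(direct, abs=1e-8)
        assert fit.heterogeneous

    def test_invariant_to_population_order(self):
        rng = np.random.default_rng(5)
        mats = []
        for _ in range(4):
            A = rng.standard_normal((2, 4))
            S = A @ A.T / 4 + np.eye(2)
            mats.append(S)
        covs = _make_covs(mats)
        rev = dict(reversed(list(covs.items())))
        assert syndrome.homogeneity_fit(covs).chi2 == pytest.approx(
            syndrome.homogeneity_fit(rev).chi2, abs=1e-9
        )

    def test_verdict_thresholds(self):
        S = np.eye(2)
        fit = syndrome.homogeneity_fit(_make_covs([S] * 3))
        # defaults follow the conventional cutoffs
        import inspect

        sig = inspect.signature(syndrome.homogeneity_fit)
        assert sig.parameters["rmsea_threshold"].default == 0.06
        assert sig.parameters["srmr_threshold"].default == 0.09
        assert sig.parameters["cfi_threshold"].default == 0.96

    def test_false_positive_rate_under_common_matrix_large_n(self):
        # sampling noise alone should rarely trigger the verdict once the
        # per-population matrices are well estimated
        rng = np.random.default_rng(21)
        R = np.array(
            [[1, 0.4, 0.3, 0.1],
             [0.4, 1, 0.25, 0.15],
             [0.3, 0.25, 1, 0.05],
             [0.1, 0.15, 0.05, 1]]
        )
        fires = 0
        reps = 40
        n = 300
        for _ in range(reps):
            covs = {}
            for gidx in range(13):
                X = rng.multivariate_normal(np.zeros(4), R, size=n)
                X = (X - X.mean(0)) / X.std(0, ddof=1)
                S = X.T @ X / n
                d = np.sqrt(np.diag(S))
                covs[f"p{gidx:02d}"] = PopulationCovariance(
                    f"p{gidx:02d}", S / np.outer(d, d), n,
                    np.zeros((4, 4)), np.zeros((4, 4))
                )
            fires += syndrome.homogeneity_fit(covs).heterogeneous
        assert fires / reps <= 0.10
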