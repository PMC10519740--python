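import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ace_subtypes import (ACEHeterogeneityModel, ACEPathParams,
                          GroupedPairData, PairGroup, aic,
                          implied_moments, lrt, lrt_pvalue, neg2ll,
                          simulate_grouped, standardized_components)
from tests.conftest import REFERENCE_GROUP_SIZES

paths = st.floats(-1.5, 1.5, allow_nan=False)
corrs = st.floats(-1.0, 1.0, allow_nan=False)


def _random_grouped_data(rng, n_pairs=20, n_singles=4):
    """Small dataset with every group populated, values kept for oracles."""
    zyg, l1, l2, y1, y2 = [], [], [], [], []
    labels = ["short", "normal_long"]
    for i in range(n_pairs):
        zyg.append("MZ" if i % 2 else "DZ")
        l1.append(labels[rng.integers(2)])
        l2.append(labels[rng.integers(2)])
        y1.append(rng.standard_normal())
        y2.append(rng.standard_normal())
    for i in range(n_singles):
        zyg.append("MZ")
        l1.append(labels[i % 2])
        l2.append(None)
        y1.append(rng.standard_normal())
        y2.append(np.nan)
    return GroupedPairData.from_arrays(zyg, l1, l2, y1, y2, keep_values=True)


def _oracle_neg2ll(params, data, kind):
    """Direct bivariate Gaussian density sum (independent code path)."""
    total = 0.0
    for grp, vals in data.pair_values.items():
        mu, sigma = implied_moments(params, grp, kind)
        for row in vals:
            total += -2.0 * stats.multivariate_normal.logpdf(row, mu, sigma)
    return total


class TestImpliedMoments:
    def test_mz_concordant_short_path_arithmetic(self):
        p = ACEPathParams(a_s=0.6, c_s=0.0, e_s=0.8, a_n=0.5, c_n=0.5, e_n=0.7)
        mu, sigma = implied_moments(p, PairGroup.MZ_CONC_SHORT)
        assert sigma[0, 0] == pytest.approx(1.0)
        assert sigma[0, 1] == pytest.approx(0.36)

    def test_dz_concordant_short_halves_genetic_covariance(self):
        p = ACEPathParams(a_s=0.6, c_s=0.0, e_s=0.8, a_n=0.5, c_n=0.5, e_n=0.7)
        _, sigma = implied_moments(p, PairGroup.DZ_CONC_SHORT)
        assert sigma[0, 1] == pytest.approx(0.18)

    def test_qualitative_decoupling_zeroes_discordant_covariance(self):
        p = ACEPathParams(a_s=0.6, c_s=0.0, e_s=0.8, a_n=0.6, c_n=0.0,
                          e_n=0.8, rA_mz=0.0)
        _, sigma = implied_moments(p, PairGroup.MZ_DISCORDANT, "full")
        assert sigma[0, 1] == pytest.approx(0.0)

    def test_quantitative_kind_ignores_qualitative_correlations(self):
        p = ACEPathParams(a_s=0.6, c_s=0.0, e_s=0.8, a_n=0.6, c_n=0.0,
                          e_n=0.8, rA_mz=0.0)
        _, sigma = implied_moments(p, PairGroup.MZ_DISCORDANT, "quantitative")
        assert sigma[0, 1] == pytest.approx(0.36)

    def test_discordant_means_follow_twin_order(self):
        p = ACEPathParams(0.5, 0.4, 0.7, 0.3, 0.2, 0.9, mu_s=1.0, mu_n=-1.0)
        mu, _ = implied_moments(p, PairGroup.DZ_DISCORDANT)
        np.testing.assert_allclose(mu, [1.0, -1.0])

    @given(a_s=paths, c_s=paths, a_n=paths, c_n=paths,
           rA=corrs, rC=corrs)
    @settings(max_examples=200, deadline=None)
    def test_cauchy_schwarz_for_all_parameters(self, a_s, c_s, a_n, c_n,
                                               rA, rC):
        p = ACEPathParams(a_s=a_s, c_s=c_s, e_s=0.5, a_n=a_n, c_n=c_n,
                          e_n=0.5, rA_mz=rA, rA_dz=rA, rC=rC)
        for grp in PairGroup:
            _, s = implied_moments(p, grp, "full")
            assert abs(s[0, 1]) <= np.sqrt(s[0, 0] * s[1, 1]) + 1e-12
            assert np.linalg.eigvalsh(s)[0] >= -1e-12


class TestNeg2LL:
    def test_standard_normal_pair_density(self):
        data = GroupedPairData.from_arrays(
            ["MZ"], ["short"], ["short"], [0.0], [0.0])
        p = ACEPathParams(a_s=0.0, c_s=0.0, e_s=1.0, a_n=0.0, c_n=0.0, e_n=1.0)
        # implied covariance is the identity; -2 log density at the origin
        assert neg2ll(p, data) == pytest.approx(2.0 * np.log(2 * np.pi),
                                                abs=1e-10)

    def test_matches_direct_density_oracle(self, rng):
        data = _random_grouped_data(rng, n_pairs=20, n_singles=0)
        p = ACEPathParams(a_s=0.5, c_s=0.4, e_s=0.8, a_n=0.6, c_n=0.2,
                          e_n=0.7, mu_s=0.2, mu_n=-0.1, rA_mz=0.7,
                          rA_dz=0.6, rC=0.9)
        for kind in ("full", "quantitative"):
            assert neg2ll(p, data, kind) == pytest.approx(
                _oracle_neg2ll(p, data, kind), abs=1e-8)

    def test_singleton_contributes_univariate_marginal(self):
        p = ACEPathParams(a_s=0.6, c_s=0.0, e_s=0.8, a_n=0.5, c_n=0.3,
                          e_n=0.7, mu_s=0.1)
        data = GroupedPairData.from_arrays(
            ["MZ"], ["short"], [None], [0.4], [np.nan])
        expected = -2.0 * stats.norm.logpdf(0.4, loc=0.1, scale=1.0)
        assert neg2ll(p, data) == pytest.approx(expected, abs=1e-10)

    def test_all_missing_pair_changes_nothing(self):
        p = ACEPathParams(0.5, 0.4, 0.8, 0.6, 0.2, 0.7)
        base = GroupedPairData.from_arrays(
            ["MZ", "DZ"], ["short", "short"], ["short", "normal_long"],
            [0.3, -0.2], [0.1, 0.5])
        extra = GroupedPairData.from_arrays(
            ["MZ", "DZ", "DZ"], ["short", "short", "short"],
            ["short", "normal_long", "short"],
            [0.3, -0.2, np.nan], [0.1, 0.5, np.nan])
        assert neg2ll(p, base) == pytest.approx(neg2ll(p, extra), abs=1e-12)
        assert extra.n_excluded_pairs == 1

    def test_non_positive_definite_rejected(self):
        p = ACEPathParams(a_s=0.0, c_s=0.0, e_s=0.0, a_n=0.0, c_n=0.0, e_n=1.0)
        data = GroupedPairData.from_arrays(
            ["MZ"], ["short"], ["short"], [0.0], [0.0])
        assert neg2ll(p, data) == np.inf


class TestStandardizedComponents:
    def test_equal_paths_give_thirds(self):
        p = ACEPathParams(0.5, 0.5, 0.5, 0.5, 0.5, 0.5)
        np.testing.assert_allclose(standardized_components(p, "short"),
                                   [1 / 3] * 3)

    def test_zero_path_gives_zero_share(self):
        p = ACEPathParams(0.6, 0.0, 0.8, 0.6, 0.0, 0.8)
        assert standardized_components(p, "short")[1] == 0.0

    @given(a=paths, c=paths)
    @settings(max_examples=100, deadline=None)
    def test_components_sum_to_one(self, a, c):
        p = ACEPathParams(a, c, 0.7, a, c, 0.7)
        assert sum(standardized_components(p, "short")) == pytest.approx(1.0)


class TestFitIndices:
    @pytest.mark.parametrize("m2ll,k,expected", [
        (24068.75, 11, 24090.75),
        (24071.33, 8, 24087.33),
        (0.0, 0, 0.0),
    ])
    def test_aic_identity(self, m2ll, k, expected):
        assert aic(m2ll, k) == pytest.approx(expected)

    def test_lrt_pvalues(self):
        assert lrt_pvalue(2.57, 3) == pytest.approx(0.46, abs=0.005)
        assert lrt_pvalue(835.11, 4) < 0.001
        assert lrt_pvalue(0.0, 1) == 1.0


@pytest.fixture(scope="module")
def fitted():
    params = ACEPathParams(
        a_s=np.sqrt(0.30), c_s=np.sqrt(0.20), e_s=np.sqrt(0.50),
        a_n=np.sqrt(0.30), c_n=np.sqrt(0.20), e_n=np.sqrt(0.50),
        mu_s=0.2, mu_n=0.0)
    cohort = simulate_grouped(REFERENCE_GROUP_SIZES, params, seed=99)
    model = ACEHeterogeneityModel.from_cohort(cohort, kind="quantitative")
    return model, model.fit(seed=1)


class TestFit:
    def test_nesting_monotonicity(self, fitted):
        model, quant = fitted
        full = ACEHeterogeneityModel(model.data, kind="full").fit(seed=1)
        homog = ACEHeterogeneityModel(model.data, kind="homogeneity"
                                      ).fit(seed=1)
        assert full.minus2ll <= quant.minus2ll + 1e-6
        assert quant.minus2ll <= homog.minus2ll + 1e-6
        ae = ACEHeterogeneityModel(model.data, kind="quantitative",
                                   components="AE").fit(seed=1)
        e = ACEHeterogeneityModel(model.data, kind="quantitative",
                                  components="E").fit(seed=1)
        assert quant.minus2ll <= ae.minus2ll + 1e-6
        assert ae.minus2ll <= e.minus2ll + 1e-6

    def test_df_plus_nfree_constant(self, fitted):
        model, quant = fitted
        homog = ACEHeterogeneityModel(model.data, kind="homogeneity"
                                      ).fit(seed=1)
        assert quant.df + quant.n_free == homog.df + homog.n_free

    def test_permutation_invariance(self):
        params = ACEPathParams(0.5, 0.4, 0.8, 0.5, 0.4, 0.8)
        cohort = simulate_grouped({"MZ_CS": 60, "MZ_CN": 80, "MZ_D": 40,
                                   "DZ_CS": 60, "DZ_CN": 80, "DZ_D": 40},
                                  params, seed=3)
        shuffled = cohort.sample(frac=1.0, random_state=0).reset_index(
            drop=True)
        f1 = ACEHeterogeneityModel.from_cohort(cohort).fit(seed=2)
        f2 = ACEHeterogeneityModel.from_cohort(shuffled).fit(seed=2)
        assert f1.minus2ll == pytest.approx(f2.minus2ll, abs=1e-8)

    def test_profile_ci_contains_estimate_and_clamps(self, fitted):
        _, quant = fitted
        a_hat = quant.standardized("short")[0]
        lo, hi = quant.standardized_ci("A", "short")
        assert lo <= a_hat <= hi
        assert 0.0 <= lo and hi <= 1.0

    def test_dropped_component_ci_degenerates(self, fitted):
        model, _ = fitted
        ae = ACEHeterogeneityModel(model.data, kind="quantitative",
                                   components="AE").fit(seed=1)
        assert ae.standardized_ci("C", "short") == (0.0, 0.0)

    def test_lrt_rejects_reversed_nesting(self, fitted):
        model, quant = fitted
        full = ACEHeterogeneityModel(model.data, kind="full").fit(seed=1)
        with pytest.raises(ValueError):
            lrt(full, quant)

    def test_summary_prints_components(self, fitted):
        _, quant = fitted
        text = quant.summary(ci=False)
        assert "-2LL" in text and "short sleep" in text
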