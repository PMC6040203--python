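"""LP-corrected marginal/posterior machinery, shrinkage estimators,
Robbins' formula, macro summaries and study clustering."""

import numpy as np
import pytest
from scipy import integrate

from dsbayes import (
    ConjugateFamily,
    DSPrior,
    elastic_bayes,
    group_studies,
    macro_summary,
    marginal_fG,
    marginal_lp,
    micro_table,
    posterior_lp,
    posterior_mean_lp,
    robbins,
    stein_peb,
)
from dsbayes.datasets import INSURANCE_FREQ
from dsbayes.inference import posterior_summary
from dsbayes.lp_basis import leg


BETA = ConjugateFamily("binomial", 2.30, 14.08)


def brute_force_marginal(y, exposure, prior, nodes=3000):
    """Oracle: direct quadrature of int f(y|theta) pi(theta) dtheta on the
    rank scale, independent of the posterior-moment machinery."""
    x, w = np.polynomial.legendre.leggauss(nodes)
    u = 0.5 * (x + 1)
    theta = prior.family.ppf(u)
    lik = prior.family.likelihood(y, theta, exposure)
    d = prior.u_function(u)
    return float(np.sum(0.5 * w * lik * d))


class TestMarginalLP:
    def test_reduces_to_conjugate_marginal(self):
        prior = DSPrior(BETA)
        for y in range(5):
            assert marginal_lp(y, 9, prior) == pytest.approx(marginal_fG(y, 9, BETA))

    def test_sums_to_one(self, rat_printed_prior):
        total = sum(marginal_lp(y, 9, rat_printed_prior) for y in range(10))
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_matches_brute_force_integral(self, rng):
        """20 random (y, coefficient) pairs against the defining integral."""
        for _ in range(20):
            coef = rng.uniform(-0.25, 0.25, size=rng.integers(1, 5))
            prior = DSPrior(BETA, coef)
            y = int(rng.integers(0, 13))
            assert marginal_lp(y, 12, prior) == pytest.approx(
                brute_force_marginal(y, 12, prior), abs=1e-6
            )


class TestPosteriorLP:
    def test_reduces_to_conjugate_posterior(self):
        prior = DSPrior(BETA)
        from dsbayes import posterior_G

        theta = np.linspace(0.05, 0.6, 9)
        np.testing.assert_allclose(
            posterior_lp(theta, 4, 14, prior),
            posterior_G(4, 14, BETA).pdf(theta),
        )

    def test_navy_posterior_integrates_to_one(self, navy_fit):
        val, _ = integrate.quad(
            lambda t: posterior_lp(t, 0, 5, navy_fit.prior), 0, 1, limit=200
        )
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_large_n_limit_agrees_with_conjugate(self, rat_printed_prior):
        """With overwhelming data the correction washes out of the posterior."""
        n = 10_000
        y = 1500
        lp_mean = elastic_bayes(y, n, rat_printed_prior)
        conj_mean = stein_peb(y, n, rat_printed_prior.family)
        assert lp_mean == pytest.approx(conj_mean, abs=2e-4)
        assert lp_mean == pytest.approx(y / n, abs=2e-3)


class TestPosteriorMeanLP:
    def test_constant_h_normalizes_to_one(self, rat_printed_prior, navy_fit):
        for prior, y, ex in [(rat_printed_prior, 4, 14), (navy_fit.prior, 0, 5)]:
            assert posterior_mean_lp(lambda t: 1.0, y, ex, prior) == pytest.approx(1.0)

    def test_no_correction_gives_conjugate_mean(self):
        prior = DSPrior(BETA)
        assert posterior_mean_lp(None, 4, 14, prior) == pytest.approx(
            (2.30 + 4) / (2.30 + 14.08 + 14)
        )

    def test_elastic_bayes_equals_integrated_posterior(self, navy_fit):
        """Two independent routes to the same posterior mean."""
        val, _ = integrate.quad(
            lambda t: t * posterior_lp(t, 1, 5, navy_fit.prior), 0, 1, limit=200
        )
        assert elastic_bayes(1, 5, navy_fit.prior) == pytest.approx(val, abs=1e-6)


class TestSteinPEB:
    def test_large_n_converges_to_sample_proportion(self):
        assert stein_peb(9000, 10_000, BETA) == pytest.approx(0.9, abs=1e-2)

    def test_rat_tumor_shrinkage_arithmetic(self):
        fam = ConjugateFamily("binomial", 2.30, 14.08)
        assert stein_peb(4, 14, fam) == pytest.approx((4 + 2.30) / (14 + 16.38), abs=1e-4)

    def test_insurance_zero_claims(self, insurance_family):
        assert stein_peb(0, None, insurance_family) == pytest.approx(0.164, abs=0.005)

    def test_poisson_closed_form(self):
        fam = ConjugateFamily("poisson", 0.7, 0.31)
        assert stein_peb(3, None, fam) == pytest.approx((3 + 0.7) / (1 / 0.31 + 1))

    def test_normal_shrinkage_weights(self):
        fam = ConjugateFamily("normal", 2.0, 1.0)
        lam = 4.0 / (4.0 + 1.0)  # s = 2
        assert stein_peb(6.0, 2.0, fam) == pytest.approx(lam * 2.0 + (1 - lam) * 6.0)


class TestElasticBayes:
    def test_zero_correction_reduces_to_stein(self):
        prior = DSPrior(ConjugateFamily("poisson", 0.7, 0.31))
        for y in range(5):
            assert elastic_bayes(y, None, prior) == pytest.approx(
                stein_peb(y, None, prior.family)
            )

    def test_published_insurance_prior_low_counts(self):
        """The published second-order insurance correction reproduces the
        reported low-count Bayes estimates."""
        prior = DSPrior(ConjugateFamily("poisson", 0.70, 0.31), [0.0, -0.26])
        assert elastic_bayes(0, None, prior) == pytest.approx(0.156, abs=0.005)
        assert elastic_bayes(1, None, prior) == pytest.approx(0.322, abs=0.005)
        assert elastic_bayes(2, None, prior) == pytest.approx(0.517, abs=0.01)

    def test_selective_shrinkage_toward_nearest_mode(self, rat_printed_prior):
        """A low-rate study shrinks below its PEB estimate (toward the 0.034
        mode), a mid-rate study shrinks toward 0.156 instead of the mean."""
        peb_low = stein_peb(0, 20, rat_printed_prior.family)
        ds_low = elastic_bayes(0, 20, rat_printed_prior)
        assert ds_low < peb_low
        peb_mid = stein_peb(3, 20, rat_printed_prior.family)
        ds_mid = elastic_bayes(3, 20, rat_printed_prior)
        assert abs(ds_mid - 0.156) < abs(peb_mid - 0.156)


class TestRobbins:
    def test_insurance_row_exact(self):
        expected = [1317 / 7840, 2 * 239 / 1317, 3 * 42 / 239, 4 * 14 / 42,
                    5 * 4 / 14, 6 * 4 / 4, 7 * 1 / 4]
        for y, e in enumerate(expected):
            assert robbins(y, INSURANCE_FREQ) == pytest.approx(e)
        assert robbins(7, INSURANCE_FREQ) is None  # table edge

    def test_zero_numerator_and_empty_cell(self):
        freq = [5, 0, 3, 0]
        assert robbins(0, freq) == 0.0
        assert robbins(1, freq) is None  # N_y = 0
        assert robbins(5, freq) is None  # outside table

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            robbins(0, [3, -1])

    def test_matches_true_posterior_mean_under_known_prior(self, rng):
        """Poisson-gamma identity: (y+1) f(y+1)/f(y) with exact marginal
        frequencies equals the conjugate posterior mean."""
        fam = ConjugateFamily("poisson", 2.0, 0.5)
        probs = [marginal_fG(y, None, fam) for y in range(50)]
        for y in range(5):
            exact = (y + 1) * probs[y + 1] / probs[y]
            assert exact == pytest.approx(stein_peb(y, None, fam), abs=1e-10)


class TestMacroSummary:
    def test_m0_prior_mean_and_pooled_average(self, rat_data):
        prior = DSPrior(BETA)
        s = macro_summary(rat_data, prior, B=0)
        assert s.prior_mean == pytest.approx(2.30 / 16.38, abs=1e-6)
        assert s.pooled_naive == pytest.approx(
            np.sum(rat_data.y) / np.sum(rat_data.exposure)
        )

    def test_rat_grand_mean_near_014(self, rat_data, rat_family):
        s = macro_summary(rat_data, DSPrior(rat_family), B=0)
        assert s.prior_mean == pytest.approx(0.14, abs=0.01)

    def test_bootstrap_ses_are_finite_and_positive(self, rat_data,
                                                   rat_printed_prior):
        s = macro_summary(rat_data, rat_printed_prior, B=20, seed=1)
        assert len(s.modes) == 2
        assert len(s.mode_se) == 2
        assert all(se > 0 for se in s.mode_se)
        assert all(n > 0 for n in s.n_matched)

    def test_seeded_bootstrap_is_reproducible(self, navy_data, navy_fit):
        a = macro_summary(navy_data, navy_fit.prior, B=5, seed=4)
        b = macro_summary(navy_data, navy_fit.prior, B=5, seed=4)
        assert a.mode_se == b.mode_se


class TestMicroAndGrouping:
    def test_micro_table_columns_and_m0_identity(self, rat_data):
        prior = DSPrior(BETA)
        table = micro_table(rat_data, prior)
        assert len(table) == rat_data.k
        np.testing.assert_allclose(table["ds_mean"], table["peb_mean"], atol=1e-9)
        assert ((table["ds_mode"] >= 0) & (table["ds_mode"] <= 1)).all()

    def test_new_study_mle(self, rat_printed_prior):
        s = posterior_summary(70, 4, 14, rat_printed_prior)
        assert s.mle == pytest.approx(4 / 14)
        assert 0 < s.ds_mode < 1 and 0 < s.ds_median < 1

    def test_rat_two_group_partition_matches_published_split(
            self, rat_data, rat_printed_prior):
        """K-means on posterior modes reproduces the published 22/48 split:
        every zero- or one-event study except (1, 10) lands in the low
        group."""
        table = micro_table(rat_data, rat_printed_prior)
        labels = group_studies(table, 2, seed=1)
        low = {(int(y), int(n))
               for y, n, l in zip(rat_data.y, rat_data.exposure, labels) if l == 0}
        assert sum(labels == 0) == 22
        assert (1, 10) not in low
        assert all(y <= 1 for y, _ in low)

    def test_well_separated_synthetic_clusters_recovered(self, rng):
        vals = np.concatenate([rng.normal(0.1, 0.005, 15),
                               rng.normal(0.6, 0.005, 10)])
        import pandas as pd

        labels = group_studies(pd.DataFrame({"ds_mode": vals}), 2, seed=1)
        assert list(labels) == [0] * 15 + [1] * 10

    def test_identical_modes_single_cluster(self):
        import pandas as pd

        labels = group_studies(pd.DataFrame({"ds_mode": np.full(6, 0.3)}), 2, seed=1)
        assert set(labels) == {0}

    def test_more_groups_than_studies_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError):
            group_studies(pd.DataFrame({"ds_mode": [0.1, 0.2]}), 3)
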