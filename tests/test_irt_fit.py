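"""Whole-sampler behaviour: determinism, recovery, identification, exports."""

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

import depindex as d
from depindex import irt
from depindex.containers import ItemResponseMatrix
from depindex.preprocess import complete_cases


def one_province_cohort(n=400, seed=2, j=9):
    labels = [f"i{x}" for x in range(j)]
    rng = np.random.default_rng(seed)
    beta = rng.lognormal(0, 0.3, size=(j, 1))
    alpha = rng.normal(0, 0.8, size=(j, 1))
    cfg = d.CohortConfig(
        province_labels=["X"],
        province_sizes=[n],
        item_labels=labels,
        true_alpha=alpha,
        true_beta=beta,
        missing_rates=np.zeros((j, 1)),
        outcome_intercept=0.0,
        outcome_slope=0.0,
        seed=seed,
    )
    X, truth = d.simulate_items(cfg)
    return X, truth


class TestFitContracts:
    def test_same_seed_identical_draws(self):
        X, _ = one_province_cohort(n=80, j=3)
        mcmc = irt.McmcConfig(iterations=60, burn_in=30, chains=2, seed=5)
        d1, _ = irt.fit(X, irt.IrtModelSpec("pooled"), mcmc)
        d2, _ = irt.fit(X, irt.IrtModelSpec("pooled"), mcmc)
        np.testing.assert_array_equal(d1.alpha, d2.alpha)
        np.testing.assert_array_equal(d1.theta, d2.theta)

    def test_zero_variance_item_is_fatal_and_named(self):
        idx = pd.RangeIndex(10, name="id")
        resp = pd.DataFrame(
            {"flat": np.ones(10), "ok": [0, 1] * 5}, index=idx, dtype=float
        )
        X = ItemResponseMatrix(resp, pd.Series(["A"] * 10, index=idx))
        with pytest.raises(ValueError, match="flat"):
            irt.fit(X, irt.IrtModelSpec("pooled"), irt.McmcConfig(iterations=10, burn_in=5))

    def test_incomplete_cases_rejected(self):
        idx = pd.RangeIndex(4, name="id")
        resp = pd.DataFrame({"a": [0, 1, np.nan, 1], "b": [1, 0, 1, 0]}, index=idx)
        X = ItemResponseMatrix(resp, pd.Series(["A"] * 4, index=idx))
        with pytest.raises(ValueError, match="complete"):
            irt.fit(X, irt.IrtModelSpec("pooled"), irt.McmcConfig(iterations=10, burn_in=5))


@pytest.fixture(scope="module")
def fitted():
    X, truth = one_province_cohort(n=400, seed=2)
    mcmc = irt.McmcConfig(iterations=1200, burn_in=600, chains=2, seed=3)
    draws, diag = irt.fit(X, irt.IrtModelSpec("pooled"), mcmc)
    return X, truth, draws, diag


class TestPooledRecovery:
    def test_item_parameters_recovered_within_three_posterior_sds(self, fitted):
        _, truth, draws, _ = fitted
        ok = 0
        for j in range(9):
            za = abs(draws.alpha[:, j, 0].mean() - truth.alpha_true[j, 0])
            za /= draws.alpha[:, j, 0].std()
            zb = abs(draws.beta[:, j, 0].mean() - truth.beta_true[j, 0])
            zb /= draws.beta[:, j, 0].std()
            ok += (za < 3) and (zb < 3)
        assert ok >= 8

    def test_theta_aggregate_shrinkage(self, fitted):
        _, _, draws, _ = fitted
        person_means = draws.theta.mean(axis=0)
        assert abs(person_means.mean()) < 0.1
        assert draws.theta.std() <= 1.1

    def test_index_orientation_extreme_rows(self, fitted):
        X, _, draws, _ = fitted
        rows = X.responses.sum(axis=1).to_numpy()
        person_means = draws.theta.mean(axis=0)
        if (rows == 9).any() and (rows == 0).any():
            assert person_means[rows == 9].min() > person_means[rows == 0].max()
        # monotone on average regardless
        assert np.corrcoef(rows, person_means)[0, 1] > 0.9

    def test_all_beta_draws_positive(self, fitted):
        _, _, draws, _ = fitted
        assert (draws.beta > 0).all()


class TestHierarchicalEquivalenceSingleGroup:
    def test_k1_hierarchical_indistinguishable_from_pooled(self):
        """With one province the two code paths target near-identical posteriors."""
        X, _ = one_province_cohort(n=300, seed=4, j=5)
        mcmc = irt.McmcConfig(iterations=1500, burn_in=750, chains=2, seed=6)
        dp, _ = irt.fit(X, irt.IrtModelSpec("pooled"), mcmc)
        mcmc2 = irt.McmcConfig(iterations=1500, burn_in=750, chains=2, seed=60)
        dh, _ = irt.fit(X, irt.IrtModelSpec("hierarchical"), mcmc2)
        assert dh.alpha.shape[2] == 1
        pvals = [
            stats.ks_2samp(dp.alpha[::10, j, 0], dh.alpha[::10, j, 0]).pvalue
            for j in range(5)
        ]
        assert min(pvals) > 0.01


class TestPosteriorFunctionals:
    def test_pointwise_loglik_constants(self, pooled_fit_small):
        Xcc, draws, _ = pooled_fit_small
        d0 = irt.PosteriorDraws(
            alpha=np.zeros((2, len(Xcc.items), 1)),
            beta=np.full((2, len(Xcc.items), 1), 1e-300),
            theta=np.zeros((2, Xcc.n)),
            chain_id=np.zeros(2, int),
            spec=draws.spec,
            item_labels=draws.item_labels,
            province_labels=["pooled"],
            province_idx=np.zeros(Xcc.n, int),
            ids=draws.ids,
        )
        ll = irt.pointwise_loglik(d0, Xcc)
        np.testing.assert_allclose(ll, np.log(0.5), atol=1e-12)

    def test_pointwise_loglik_saturation_no_underflow(self, pooled_fit_small):
        Xcc, draws, _ = pooled_fit_small
        big = irt.PosteriorDraws(
            alpha=np.full((2, len(Xcc.items), 1), 10.0),
            beta=np.full((2, len(Xcc.items), 1), 1e-300),
            theta=np.zeros((2, Xcc.n)),
            chain_id=np.zeros(2, int),
            spec=draws.spec,
            item_labels=draws.item_labels,
            province_labels=["pooled"],
            province_idx=np.zeros(Xcc.n, int),
            ids=draws.ids,
        )
        ll = irt.pointwise_loglik(big, Xcc)
        assert np.isfinite(ll).all()
        ones = Xcc.responses.to_numpy().ravel() == 1
        assert ll[0][ones].max() < 0 and ll[0][ones].min() > -1e-6

    def test_pointwise_loglik_matches_direct_reevaluation(self, pooled_fit_small):
        Xcc, draws, _ = pooled_fit_small
        ll = irt.pointwise_loglik(draws, Xcc)
        s = 3
        Xv = Xcc.responses.to_numpy()
        direct = np.empty(Xv.size)
        for i in range(Xv.shape[0]):
            for j in range(Xv.shape[1]):
                eta = draws.alpha[s, j, 0] + draws.beta[s, j, 0] * draws.theta[s, i]
                p = special.ndtr(eta)
                direct[i * Xv.shape[1] + j] = np.log(p if Xv[i, j] == 1 else 1 - p)
        np.testing.assert_allclose(ll[s], direct, atol=1e-10)

    def test_posterior_index_constant_draws(self, pooled_fit_small):
        Xcc, draws, _ = pooled_fit_small
        const = irt.PosteriorDraws(
            alpha=draws.alpha[:2],
            beta=draws.beta[:2],
            theta=np.full((2, Xcc.n), 1.3),
            chain_id=np.zeros(2, int),
            spec=draws.spec,
            item_labels=draws.item_labels,
            province_labels=draws.province_labels,
            province_idx=draws.province_idx,
            ids=draws.ids,
            person_province=draws.person_province,
        )
        summary = irt.posterior_index(const)
        assert (summary["theta_mean"] == 1.3).all()
        assert (summary["q50"] == 1.3).all()
        assert (summary["theta_sd"] == 0.0).all()

    def test_posterior_index_against_sorting_oracle(self, pooled_fit_small):
        _, draws, _ = pooled_fit_small
        summary = irt.posterior_index(draws)
        i = 5
        srt = np.sort(draws.theta[:, i])
        lo = np.percentile(srt, 2.5)
        assert summary["q2.5"].iloc[i] == pytest.approx(lo, abs=1e-10)
        assert summary["theta_mean"].iloc[i] == pytest.approx(srt.mean(), abs=1e-12)

    def test_standard_normal_draw_quantiles(self):
        rng = np.random.default_rng(0)
        dnorm = irt.PosteriorDraws(
            alpha=np.zeros((20000, 1, 1)),
            beta=np.ones((20000, 1, 1)),
            theta=rng.standard_normal((20000, 3)),
            chain_id=np.zeros(20000, int),
            spec=irt.IrtModelSpec("pooled"),
            item_labels=["i"],
            province_labels=["pooled"],
            province_idx=np.zeros(3, int),
            ids=pd.RangeIndex(3),
        )
        summary = irt.posterior_index(dnorm)
        np.testing.assert_allclose(summary["q2.5"], -1.96, atol=0.08)
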