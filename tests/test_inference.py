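"""Bayesian estimation: determinism, structural constraints, priors,
classification plumbing, and small-scale recovery."""

import numpy as np
import pytest

import mmirtree as mt
from mmirtree.sampler import McmcSettings, PriorSpec, run_mcmc


@pytest.fixture(scope="module")
def small_mixture():
    return mt.make_fixture("mixture_small", seed=5)


@pytest.fixture(scope="module")
def small_mm_fit(small_mixture):
    return mt.MMIRTree(small_mixture.ratings).fit(
        n_chains=2, n_iterations=250, n_burnin=100, seed=4)


class TestSettingsValidation:
    def test_burnin_bound(self):
        with pytest.raises(ValueError):
            McmcSettings(n_iterations=100, n_burnin=100)

    def test_prior_validation(self):
        with pytest.raises(ValueError):
            PriorSpec(loading_var=-1)
        with pytest.raises(ValueError):
            PriorSpec(omega_bounds=(2, 1))

    def test_unknown_kind(self, small_mixture):
        with pytest.raises(ValueError, match="unknown model kind"):
            run_mcmc(small_mixture.ratings.responses, kind="nope")

    def test_single_class_kind_guard(self, small_mixture):
        with pytest.raises(ValueError):
            mt.IRTree(small_mixture.ratings, kind="mm")


class TestDeterminism:
    def test_same_seed_identical_draws(self, small_mixture):
        settings = McmcSettings(n_chains=1, n_iterations=120, n_burnin=40, seed=9)
        a = run_mcmc(small_mixture.ratings.responses, "mm", settings=settings)
        b = run_mcmc(small_mixture.ratings.responses, "mm", settings=settings)
        np.testing.assert_array_equal(a[0]["beta"], b[0]["beta"])
        np.testing.assert_array_equal(a[0]["z"], b[0]["z"])
        np.testing.assert_array_equal(a[0]["deviance"], b[0]["deviance"])

    def test_different_seeds_differ(self, small_mixture):
        a = run_mcmc(small_mixture.ratings.responses, "mm",
                     settings=McmcSettings(n_chains=1, n_iterations=120,
                                           n_burnin=40, seed=9))
        b = run_mcmc(small_mixture.ratings.responses, "mm",
                     settings=McmcSettings(n_chains=1, n_iterations=120,
                                           n_burnin=40, seed=10))
        assert not np.array_equal(a[0]["deviance"], b[0]["deviance"])


class TestStructuralIdentification:
    def test_masked_loadings_zero_in_every_draw(self, small_mm_fit):
        chains = small_mm_fit.chains
        for ch in chains:
            assert (ch["alpha_ers"][:, :, 1] == 0).all()  # MRS_ONLY
            assert (ch["alpha_ers"][:, :, 3] == 0).all()  # ZERO_RS
            assert (ch["alpha_mrs"][:, :, 0] == 0).all()  # ERS_ONLY
            assert (ch["alpha_mrs"][:, :, 3] == 0).all()

    def test_free_loadings_positive(self, small_mm_fit):
        for ch in small_mm_fit.chains:
            assert (ch["alpha_theta"] > 0).all()
            assert (ch["alpha_ers"][:, :, [0, 2]] > 0).all()
            assert (ch["omega"] > 0).all() and (ch["omega"] < 2).all()

    def test_pz_rows_sum_to_one(self, small_mm_fit):
        Pz = small_mm_fit.class_probabilities
        np.testing.assert_allclose(Pz.sum(axis=1), 1.0, atol=1e-9)
        # modal assignment consistent with Pz
        np.testing.assert_array_equal(
            small_mm_fit.modal_classes, np.argmax(Pz, axis=1) + 1)

    def test_single_class_fit_has_no_pz(self, small_mixture):
        res = mt.IRTree(small_mixture.ratings, kind="0rs").fit(
            n_chains=1, n_iterations=80, n_burnin=30, seed=2)
        with pytest.raises(ValueError, match="single-class"):
            res.class_probabilities


class TestPriorPredictive:
    def test_pi_reproduces_dirichlet_moments_without_data(self):
        """With zero items the posterior of pi is its Dirichlet(1,1,1,1)
        prior: mean 1/4, sd sqrt(3/80)."""
        Y = np.empty((200, 0), dtype=np.int64)
        chains = run_mcmc(Y, "mm", settings=McmcSettings(
            n_chains=2, n_iterations=1600, n_burnin=100, seed=3))
        pi = np.concatenate([ch["pi"] for ch in chains])
        assert np.abs(pi.mean(axis=0) - 0.25).max() < 0.03
        sd_target = np.sqrt(3.0 / 80.0)  # approx 0.194
        assert np.abs(pi.std(axis=0) - sd_target).max() < 0.04


class TestRecoverySmall:
    def test_zero_rs_parameter_recovery(self):
        """0RS tree refit to 0RS data recovers loadings and traits."""
        ds = mt.generate_condition(mt.get_condition(
            "0rs_only", n_persons=300, n_items=10, n_replications=1,
            master_seed=21))[0]
        res = mt.IRTree(ds.ratings, kind="0rs").fit(
            n_chains=2, n_iterations=500, n_burnin=200, seed=6)
        bias, rmse = mt.bias_rmse(res.alpha_theta, ds.items.alpha_theta)
        assert rmse <= 0.25
        assert np.corrcoef(res.theta, ds.persons.theta)[0, 1] > 0.85
        b_bias, b_rmse = mt.bias_rmse(res.beta[:, :, 3], ds.items.beta[:, :, 3])
        assert b_rmse <= 0.3

    def test_mm_on_non_mixture_concentrates(self):
        """The hierarchical Dirichlet prior keeps non-existent classes
        essentially empty when the population is a single class."""
        ds = mt.generate_condition(mt.get_condition(
            "0rs_only", n_persons=450, n_items=20, n_replications=1,
            master_seed=22))[0]
        res = mt.MMIRTree(ds.ratings).fit(
            n_chains=2, n_iterations=700, n_burnin=300, seed=8)
        assert res.pi[3] > 0.8
        assert (res.modal_classes == 4).mean() > 0.9


class TestInitialisationInvariance:
    def test_heuristic_and_random_init_agree(self):
        """Both initialisations reach the same stationary distribution
        (posterior mean deviance and alpha_theta agree loosely)."""
        ds = mt.generate_condition(mt.get_condition(
            "equal", n_persons=200, n_items=8, n_replications=1,
            master_seed=23))[0]
        fits = {}
        for init in ("heuristic", "random"):
            fits[init] = mt.MMIRTree(ds.ratings).fit(
                n_chains=1, n_iterations=700, n_burnin=300, seed=12, init=init)
        d_a = fits["heuristic"].deviance_draws.mean()
        d_b = fits["random"].deviance_draws.mean()
        assert abs(d_a - d_b) / abs(d_a) < 0.02
        np.testing.assert_allclose(
            fits["heuristic"].alpha_theta, fits["random"].alpha_theta,
            atol=0.3)


class TestResultsSurface:
    def test_summary_mentions_key_quantities(self, small_mm_fit):
        text = small_mm_fit.summary()
        assert "DIC" in text and "omega" in text
        assert "class proportions" in text

    def test_params_series_complete(self, small_mm_fit):
        params = small_mm_fit.params
        assert "omega" in params.index
        assert any(ix.startswith("alpha_theta") for ix in params.index)
        assert any(ix.startswith("pi") for ix in params.index)

    def test_rhat_table_nonempty(self, small_mm_fit):
        rh = small_mm_fit.rhat
        assert len(rh) > 50
        assert (rh > 0.8).all()

    def test_dic_consistency(self, small_mm_fit):
        d = small_mm_fit.dic_result
        assert d.dic == d.dbar + d.pv
        assert d.pv >= 0

    def test_constant_column_warns(self):
        Y = np.full((30, 3), 3)
        Y[:, 1] = np.random.default_rng(0).integers(1, 6, 30)
        Y[:, 2] = np.random.default_rng(1).integers(1, 6, 30)
        with pytest.warns(UserWarning, match="constant"):
            run_mcmc(Y, "0rs", settings=McmcSettings(
                n_chains=1, n_iterations=30, n_burnin=10, seed=1))


class TestPosteriorClassProbabilityCounting:
    def test_degenerate(self):
        z = np.full((50, 3), 3)
        Pz = mt.posterior_class_probabilities(z)
        np.testing.assert_array_equal(Pz, np.tile([0, 0, 1, 0], (3, 1)))

    def test_counting(self):
        z = np.concatenate([np.full((600, 1), 1), np.full((400, 1), 3)])
        Pz = mt.posterior_class_probabilities(z)
        np.testing.assert_allclose(Pz[0], [0.6, 0, 0.4, 0])
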