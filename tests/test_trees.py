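"""Core tree mathematics: decomposition, node/category probabilities,
mixture likelihood."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mmirtree as mt
from mmirtree.trees import MISSING, InvalidResponseError


def _items_for(alpha_theta, omega, aers13, amrs23, beta):
    """Build ItemParameters from free values (scalars broadcast, J=1)."""
    J = len(np.atleast_1d(alpha_theta))
    aers = np.zeros((J, 4))
    amrs = np.zeros((J, 4))
    aers[:, [0, 2]] = np.reshape(aers13, (J, 2))
    amrs[:, [1, 2]] = np.reshape(amrs23, (J, 2))
    return mt.ItemParameters(np.atleast_1d(alpha_theta), omega, aers, amrs, beta)


class TestDecomposition:
    # full Table-1 style coding: response -> (disagreement, neutrality, extremity)
    CODING = {
        1: (1, MISSING, 1),
        2: (1, MISSING, 0),
        3: (0, 1, MISSING),
        4: (0, 0, 0),
        5: (0, 0, 1),
    }

    @pytest.mark.parametrize("resp,expected", sorted(CODING.items()))
    def test_coding(self, resp, expected):
        rm = mt.RatingMatrix([[resp]])
        table = mt.decompose_responses(rm)
        assert tuple(table.values[0, 0]) == expected

    def test_missingness_is_function_of_response(self, rng):
        Y = rng.integers(1, 6, size=(40, 7))
        table = mt.decompose_responses(mt.RatingMatrix(Y))
        miss = table.values == MISSING
        # node 1 missing iff response < 3; node 2 missing iff response == 3
        assert (miss[:, :, 0] == False).all()  # noqa: E712
        assert (miss[:, :, 1] == (Y <= 2)).all()
        assert (miss[:, :, 2] == (Y == 3)).all()

    @given(st.integers(1, 5))
    def test_roundtrip_single(self, resp):
        rm = mt.RatingMatrix([[resp]])
        assert mt.recompose_responses(mt.decompose_responses(rm)).responses[0, 0] == resp

    def test_roundtrip_matrix(self, rng):
        Y = rng.integers(1, 6, size=(25, 9))
        rm = mt.RatingMatrix(Y)
        back = mt.recompose_responses(mt.decompose_responses(rm))
        np.testing.assert_array_equal(back.responses, Y)

    @pytest.mark.parametrize("bad", [0, 6, -1])
    def test_out_of_range_named(self, bad):
        with pytest.raises(InvalidResponseError, match="person index 1"):
            mt.RatingMatrix([[3, 3], [3, bad]])

    def test_inconsistent_pattern_rejected(self):
        # y0 = 1 (disagreement) with an observed neutrality node
        table = mt.PseudoItemTable(np.array([[[1, 1, 0]]], dtype=np.int8))
        with pytest.raises(InvalidResponseError, match="inconsistent"):
            mt.recompose_responses(table)

    def test_wide_export_shape(self, rng):
        Y = rng.integers(1, 6, size=(5, 4))
        wide = mt.decompose_responses(mt.RatingMatrix(Y)).to_wide_dataframe()
        assert wide.shape == (5, 12)
        assert wide.isna().to_numpy().sum() == ((Y <= 2).sum() + (Y == 3).sum())


class TestNodeProbabilities:
    def test_all_zero_is_half(self):
        items = _items_for([1.0], 0.5, [1, 1], [0.6, 0.6], np.zeros((1, 3, 4)))
        pers = mt.PersonParameters([0.0], [0.0], [0.0])
        nodes = mt.node_probabilities(pers, items, 3)
        for v in nodes.values():
            assert v[0, 0] == pytest.approx(0.5)

    def test_derived_two_rs_example(self):
        # theta=1, a_theta=1, omega=0.5, eta_ers=1, a_ers=1, eta_mrs=0, beta=0:
        # logistic at -1, -1, +0.5, +1.5
        items = _items_for([1.0], 0.5, [1.0, 1.0], [0.6, 0.6], np.zeros((1, 3, 4)))
        pers = mt.PersonParameters([1.0], [1.0], [0.0])
        nodes = mt.node_probabilities(pers, items, 3)
        assert nodes["p0"][0, 0] == pytest.approx(0.2689, abs=5e-5)
        assert nodes["p1"][0, 0] == pytest.approx(0.2689, abs=5e-5)
        assert nodes["p2_disagree"][0, 0] == pytest.approx(0.6225, abs=5e-5)
        assert nodes["p2_agree"][0, 0] == pytest.approx(0.8176, abs=5e-5)

    def test_zero_rs_masks_rs_traits(self, random_items, rng):
        """ZERO_RS output never depends on the RS trait values."""
        theta = rng.standard_normal(5)
        a = mt.PersonParameters(theta, rng.standard_normal(5), rng.standard_normal(5))
        b = mt.PersonParameters(theta, np.zeros(5), np.zeros(5))
        pa = mt.category_probabilities(a, random_items, 4)
        pb = mt.category_probabilities(b, random_items, 4)
        np.testing.assert_array_equal(pa, pb)

    def test_class_index_out_of_range(self, random_items, random_persons):
        with pytest.raises(IndexError):
            mt.node_probabilities(random_persons, random_items, 5)

    def test_nonfinite_person_raises(self, random_items):
        pers = mt.PersonParameters([0.0], [0.0], [0.0])
        pers.theta = np.array([np.nan])
        with pytest.raises(FloatingPointError):
            mt.node_probabilities(pers, random_items, 1)

    def test_probit_option(self, random_items, random_persons):
        p = mt.category_probabilities(random_persons, random_items, 3, link="probit")
        assert np.allclose(p.sum(axis=-1), 1.0, atol=1e-12)


class TestCategoryProbabilities:
    def test_all_zero_closed_form(self):
        items = _items_for([1.0], 0.5, [1, 1], [0.6, 0.6], np.zeros((1, 3, 4)))
        pers = mt.PersonParameters([0.0], [0.0], [0.0])
        probs = mt.category_probabilities(pers, items, 3)[0, 0]
        np.testing.assert_allclose(probs, [0.25, 0.25, 0.25, 0.125, 0.125],
                                   atol=1e-12)

    def test_derived_example(self):
        items = _items_for([1.0], 0.5, [1.0, 1.0], [0.6, 0.6], np.zeros((1, 3, 4)))
        pers = mt.PersonParameters([1.0], [1.0], [0.0])
        probs = mt.category_probabilities(pers, items, 3)[0, 0]
        np.testing.assert_allclose(
            probs, [0.1674, 0.1015, 0.1966, 0.0975, 0.4370], atol=1e-4)
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_theta_limit(self):
        items = _items_for([1.0], 0.5, [1, 1], [0.6, 0.6], np.zeros((1, 3, 4)))
        pers = mt.PersonParameters([50.0], [0.0], [0.0])
        probs = mt.category_probabilities(pers, items, 4)[0, 0]
        assert probs[4] > 0.999

    def test_normalization_many_draws(self, rng):
        """Category probabilities sum to 1 for >=1000 random draws per class."""
        n = 1000
        for class_index in (1, 2, 3, 4):
            J = 1
            aers = np.zeros((n, J, 4))
            amrs = np.zeros((n, J, 4))
            # draw item parameters per pseudo-person to cover the space
            items = _items_for(
                rng.uniform(0.1, 3.0, size=1), rng.uniform(0.05, 2.0),
                rng.uniform(0, 2, 2), rng.uniform(0, 2, 2),
                rng.uniform(-4, 4, size=(1, 3, 4)))
            pers = mt.PersonParameters(
                rng.standard_normal(n) * 2, rng.standard_normal(n) * 2,
                rng.standard_normal(n) * 2)
            probs = mt.category_probabilities(pers, items, class_index)
            np.testing.assert_allclose(probs.sum(axis=-1), 1.0, atol=1e-12)
            assert (probs > 0).all()

    def test_masking_equivalence(self, rng):
        """ERS_ONLY == TWO_RS with a_mrs=0 etc., bit-level."""
        J = 4
        aers_vals = rng.uniform(0.75, 1.25, J)
        amrs_vals = rng.uniform(0.5, 0.75, J)
        beta = rng.uniform(-2, 2, size=(J, 3, 4))
        # force class-c beta equal to TWO_RS beta so only loadings differ
        for c in range(4):
            beta[:, :, c] = beta[:, :, 2]
        pers = mt.PersonParameters(
            rng.standard_normal(8), rng.standard_normal(8), rng.standard_normal(8))

        def make(aers13, amrs23):
            aers = np.zeros((J, 4))
            amrs = np.zeros((J, 4))
            aers[:, [0, 2]] = np.column_stack(aers13)
            amrs[:, [1, 2]] = np.column_stack(amrs23)
            return mt.ItemParameters(np.full(J, 1.2), 0.5, aers, amrs, beta)

        full = make((aers_vals, aers_vals), (amrs_vals, amrs_vals))
        ref_ers = mt.category_probabilities(pers, full, 1)
        ref_mrs = mt.category_probabilities(pers, full, 2)
        ref_zero = mt.category_probabilities(pers, full, 4)
        zero_mrs = make((aers_vals, aers_vals), (amrs_vals, np.zeros(J)))
        np.testing.assert_array_equal(
            mt.category_probabilities(pers, zero_mrs, 3), ref_ers)
        zero_ers = make((aers_vals, np.zeros(J)), (amrs_vals, amrs_vals))
        np.testing.assert_array_equal(
            mt.category_probabilities(pers, zero_ers, 3), ref_mrs)
        zero_both = make((aers_vals, np.zeros(J)), (amrs_vals, np.zeros(J)))
        np.testing.assert_array_equal(
            mt.category_probabilities(pers, zero_both, 3), ref_zero)

    @pytest.mark.parametrize("class_index", [1, 2, 3, 4])
    def test_monotonicity_in_theta(self, random_items, class_index):
        thetas = np.linspace(-3, 3, 21)
        pers = mt.PersonParameters(thetas, np.zeros(21), np.zeros(21))
        probs = mt.category_probabilities(pers, random_items, class_index)
        p5 = probs[:, :, 4]
        p1 = probs[:, :, 0]
        assert (np.diff(p5, axis=0) > 0).all()
        assert (np.diff(p1, axis=0) < 0).all()

    @pytest.mark.parametrize("class_index", [2, 3])
    def test_monotonicity_in_mrs(self, random_items, class_index):
        etas = np.linspace(-3, 3, 21)
        pers = mt.PersonParameters(np.zeros(21), np.zeros(21), etas)
        p3 = mt.category_probabilities(pers, random_items, class_index)[:, :, 2]
        assert (np.diff(p3, axis=0) > 0).all()

    @pytest.mark.parametrize("class_index", [1, 3])
    def test_monotonicity_in_ers(self, random_items, class_index):
        etas = np.linspace(-3, 3, 21)
        pers = mt.PersonParameters(np.zeros(21), etas, np.zeros(21))
        probs = mt.category_probabilities(pers, random_items, class_index)
        extreme = probs[:, :, 0] + probs[:, :, 4]
        assert (np.diff(extreme, axis=0) > 0).all()


class TestMixture:
    def test_indicator_selection(self, random_items, random_persons):
        n = random_persons.n_persons
        for c in (1, 2, 3, 4):
            mix = mt.mixture_category_probabilities(
                random_persons, random_items, np.full(n, c))
            direct = mt.category_probabilities(random_persons, random_items, c)
            np.testing.assert_array_equal(mix, direct)

    def test_class_specific_beta_used(self, rng):
        """With beta differing between classes, class 1 members use class-1
        beta only."""
        J = 3
        aers = np.zeros((J, 4))
        aers[:, [0, 2]] = 1.0
        amrs = np.zeros((J, 4))
        amrs[:, [1, 2]] = 0.6
        beta = rng.uniform(-2, 2, size=(J, 3, 4))
        items = mt.ItemParameters(np.ones(J), 0.5, aers, amrs, beta)
        pers = mt.PersonParameters([0.3], [0.1], [-0.2])
        mix = mt.mixture_category_probabilities(pers, items, [1])
        # direct evaluation of the ERS-only component
        direct = mt.category_probabilities(pers, items, 1)
        np.testing.assert_array_equal(mix, direct)
        # and it differs from what class-2 beta would give
        other = mt.category_probabilities(pers, items, 2)
        assert not np.allclose(mix, other)

    def test_z_out_of_range(self, random_items, random_persons):
        with pytest.raises(IndexError):
            mt.mixture_category_probabilities(
                random_persons, random_items,
                np.full(random_persons.n_persons, 5))


class TestLogLikelihood:
    def test_single_cell_closed_form(self):
        items = _items_for([1.0], 0.5, [1, 1], [0.6, 0.6], np.zeros((1, 3, 4)))
        pers = mt.PersonParameters([0.0], [0.0], [0.0])
        rm = mt.RatingMatrix([[3]])
        ll = mt.log_likelihood(rm, pers, items, np.array([3]))
        assert ll == pytest.approx(np.log(0.25), abs=1e-12)

    def test_mean_loglik_bounded(self, random_items, random_persons, rng):
        n = random_persons.n_persons
        z = rng.integers(1, 5, size=n)
        Y = rng.integers(1, 6, size=(n, random_items.n_items))
        rm = mt.RatingMatrix(Y)
        ll = mt.log_likelihood(rm, random_persons, random_items, z)
        per_obs = np.exp(ll / Y.size)
        assert 0 < per_obs < 1

    def test_brute_force_oracle(self, rng):
        """Mixture log-likelihood equals independent per-category evaluation
        on small instances (P=3, J=2)."""
        J = 2
        aers = np.zeros((J, 4))
        aers[:, [0, 2]] = rng.uniform(0.75, 1.25, (J, 2))
        amrs = np.zeros((J, 4))
        amrs[:, [1, 2]] = rng.uniform(0.5, 0.75, (J, 2))
        items = mt.ItemParameters(
            rng.uniform(0.75, 1.75, J), 0.5, aers, amrs,
            rng.uniform(-2, 2, (J, 3, 4)))
        pers = mt.PersonParameters(
            rng.standard_normal(3), rng.standard_normal(3), rng.standard_normal(3))
        z = np.array([1, 3, 4])
        Y = rng.integers(1, 6, size=(3, J))
        ll = mt.log_likelihood(mt.RatingMatrix(Y), pers, items, z)

        # oracle: evaluate each cell's category probability independently
        # through the node-probability formulas
        from scipy.special import expit

        total = 0.0
        for p in range(3):
            c = z[p] - 1
            for j in range(J):
                th, ers, mrs = pers.theta[p], pers.eta_ers[p], pers.eta_mrs[p]
                at, ae, am = (items.alpha_theta[j], items.alpha_ers[j, c],
                              items.alpha_mrs[j, c])
                b0, b1, b2 = items.beta[j, :, c]
                p0 = expit(-at * th - am * mrs - b0)
                p1 = expit(-at * th + am * mrs - b1)
                p2d = expit(-0.5 * at * th + ae * ers - b2)
                p2a = expit(0.5 * at * th + ae * ers - b2)
                cat = [p0 * p2d, p0 * (1 - p2d), (1 - p0) * p1,
                       (1 - p0) * (1 - p1) * (1 - p2a),
                       (1 - p0) * (1 - p1) * p2a]
                total += np.log(cat[Y[p, j] - 1])
        assert ll == pytest.approx(total, abs=1e-10)

    def test_pathwise_factorization(self, rng):
        """Log-likelihood equals the sum of Bernoulli log-likelihoods over
        the observed pseudo-items of the decomposed data."""
        J = 4
        aers = np.zeros((J, 4))
        aers[:, [0, 2]] = 1.0
        amrs = np.zeros((J, 4))
        amrs[:, [1, 2]] = 0.6
        items = mt.ItemParameters(np.ones(J), 0.5, aers, amrs,
                                  rng.uniform(-1, 1, (J, 3, 4)))
        pers = mt.PersonParameters(
            rng.standard_normal(6), rng.standard_normal(6), rng.standard_normal(6))
        z = rng.integers(1, 5, size=6)
        Y = rng.integers(1, 6, size=(6, J))
        rm = mt.RatingMatrix(Y)
        ll = mt.log_likelihood(rm, pers, items, z)

        table = mt.decompose_responses(rm).values
        total = 0.0
        for p in range(6):
            nodes = mt.node_probabilities(
                mt.PersonParameters(pers.theta[[p]], pers.eta_ers[[p]],
                                    pers.eta_mrs[[p]]),
                items, int(z[p]))
            for j in range(J):
                y0, y1, y2 = table[p, j]
                probs = {
                    0: nodes["p0"][0, j],
                    1: nodes["p1"][0, j],
                    2: (nodes["p2_disagree"] if y0 == 1 else
                        nodes["p2_agree"])[0, j],
                }
                for k, y in enumerate((y0, y1, y2)):
                    if y == MISSING:
                        continue
                    pk = probs[k]
                    total += np.log(pk if y == 1 else 1 - pk)
        assert ll == pytest.approx(total, rel=1e-10)


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 2 ** 31 - 1))
def test_probability_normalization_property(seed):
    """Category probabilities are a simplex for arbitrary valid parameters."""
    r = np.random.default_rng(seed)
    J = 2
    aers = np.zeros((J, 4))
    aers[:, [0, 2]] = r.uniform(0, 3, (J, 2))
    amrs = np.zeros((J, 4))
    amrs[:, [1, 2]] = r.uniform(0, 3, (J, 2))
    items = mt.ItemParameters(r.uniform(0.05, 3, J), r.uniform(0.05, 2),
                              aers, amrs, r.uniform(-4, 4, (J, 3, 4)))
    pers = mt.PersonParameters(r.standard_normal(3) * 2,
                               r.standard_normal(3) * 2,
                               r.standard_normal(3) * 2)
    for c in (1, 2, 3, 4):
        probs = mt.category_probabilities(pers, items, c)
        np.testing.assert_allclose(probs.sum(axis=-1), 1.0, atol=1e-12)
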