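import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from actihmm import (
    GaussianHMM,
    SimulationSpec,
    StateProbabilities,
    fit_homogeneous,
    information_criteria,
    load_fit,
    local_decode,
    log_likelihood,
    pseudo_residuals,
    simulate,
    smooth,
)
from oracles import enum_loglik, enum_posterior, random_instance


class TestLogLikelihood:
    def test_single_state_standard_normal_at_zero(self):
        m1 = GaussianHMM.from_params([1.0], [0.0], [1.0], [[1.0]])
        assert m1.score(np.array([0.0])) == pytest.approx(-0.5 * np.log(2 * np.pi))

    def test_matches_path_enumeration_on_toy_chain(self, toy2):
        model, y = toy2
        expected = enum_loglik(
            model.startprob_, model.transmat_, model.means_, model.sds_, y
        )
        assert model.score(y) == pytest.approx(expected, abs=1e-12)

    def test_all_missing_series_has_zero_loglik(self, toy2):
        model, _ = toy2
        assert model.score(np.array([np.nan] * 3)) == 0.0

    def test_empty_series_rejected(self, toy2):
        model, _ = toy2
        with pytest.raises(ValueError):
            model.score(np.array([]))

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_forward_equals_enumeration_with_missing(self, seed):
        """Scaled forward recursion == exhaustive path sum (random chains,
        T <= 8, m <= 3, with missing epochs)."""
        rng = np.random.default_rng(seed)
        delta, A, means, sds, y = random_instance(rng)
        model = GaussianHMM.from_params(delta, means, sds, A)
        assert model.score(y) == pytest.approx(
            enum_loglik(delta, A, means, sds, y), abs=1e-10
        )

    def test_marking_missing_equals_analytic_marginalisation(self, toy2):
        """Masking an epoch must equal summing the full likelihood over
        that epoch's observation (identity emission matrix)."""
        model, y = toy2
        y_missing = y.copy()
        y_missing[1] = np.nan
        expected = enum_loglik(
            model.startprob_, model.transmat_, model.means_, model.sds_, y_missing
        )
        assert model.score(y_missing) == pytest.approx(expected, abs=1e-12)


class TestSmoothing:
    def test_single_state_probabilities_are_one(self):
        m1 = GaussianHMM.from_params([1.0], [0.0], [1.0], [[1.0]])
        probs = m1.predict_proba(np.array([0.5, 1.5]))
        np.testing.assert_allclose(probs.probs, 1.0)

    def test_matches_enumeration_posterior(self, toy2):
        model, y = toy2
        post = enum_posterior(
            model.startprob_, model.transmat_, model.means_, model.sds_, y
        )
        np.testing.assert_allclose(model.predict_proba(y).probs, post, atol=1e-12)

    def test_missing_epoch_inherits_neighbouring_state(self):
        model = GaussianHMM.from_params(
            [0.5, 0.5], [0.0, 5.0], [1.0, 1.0], [[0.95, 0.05], [0.05, 0.95]]
        )
        y = np.array([0.0, np.nan, 0.1])
        probs = model.predict_proba(y).probs
        post = enum_posterior(
            model.startprob_, model.transmat_, model.means_, model.sds_, y
        )
        np.testing.assert_allclose(probs, post, atol=1e-12)
        assert probs[1, 0] > 0.9

    def test_rows_sum_to_one(self, homog3_fit):
        fit, res = homog3_fit
        probs = fit.predict_proba(res.series)
        np.testing.assert_allclose(probs.probs.sum(axis=1), 1.0, atol=1e-8)


class TestLocalDecode:
    def test_argmax_and_tiebreak(self):
        probs = StateProbabilities(np.array([[0.7, 0.2, 0.1], [0.5, 0.5, 0.0]]))
        np.testing.assert_array_equal(local_decode(probs), [0, 0])

    def test_well_separated_states_recovered(self):
        truth = GaussianHMM.from_params(
            [0.5, 0.5], [0.0, 8.0], [1.0, 1.0], [[0.95, 0.05], [0.05, 0.95]]
        )
        res = simulate(SimulationSpec(model=truth, n_days=10, seed=4,
                                      missing_blocks_per_day=0))
        decoded = truth.predict(res.series)
        assert (decoded == res.states).mean() > 0.99


class TestFit:
    def test_single_state_reduces_to_gaussian_mle(self):
        rng = np.random.default_rng(2)
        y = rng.normal(3.0, 1.5, size=400)
        fit = fit_homogeneous(y, m=1, n_starts=1)
        assert fit.means_[0] == pytest.approx(y.mean(), abs=1e-9)
        assert fit.sds_[0] == pytest.approx(y.std(), abs=1e-9)  # divide-by-T MLE
        closed_form = stats.norm(y.mean(), y.std()).logpdf(y).sum()
        assert fit.loglik_ == pytest.approx(closed_form, abs=1e-6)

    def test_em_ascent_on_fixtures(self, homog3_fit):
        fit, _ = homog3_fit
        diffs = np.diff(fit.loglik_trace_)
        assert np.all(diffs >= -1e-7 * np.abs(fit.loglik_trace_[:-1]))

    def test_two_state_parameter_recovery(self, homog2_sim):
        truth, res = homog2_sim
        fit = GaussianHMM(n_states=2, n_starts=3, random_state=1).fit(res.series)
        np.testing.assert_allclose(fit.means_, truth.means_, atol=0.1)
        np.testing.assert_allclose(
            np.diag(fit.transmat_), np.diag(truth.transmat_), atol=0.02
        )

    def test_states_labelled_by_ascending_mean(self, homog3_fit):
        fit, _ = homog3_fit
        assert np.all(np.diff(fit.means_) >= 0)

    def test_relabelling_leaves_likelihood_invariant(self, toy2):
        model, y = toy2
        perm = [1, 0]
        permuted = GaussianHMM.from_params(
            model.startprob_[perm],
            model.means_[perm],
            model.sds_[perm],
            model.transmat_[np.ix_(perm, perm)],
        )
        assert permuted.score(y) == pytest.approx(model.score(y), abs=1e-12)

    def test_gradient_vanishes_at_convergence(self):
        rng = np.random.default_rng(8)
        truth = GaussianHMM.from_params(
            [0.5, 0.5], [0.0, 4.0], [1.0, 1.0], [[0.9, 0.1], [0.2, 0.8]]
        )
        res = simulate(SimulationSpec(model=truth, n_days=2, seed=5,
                                      missing_blocks_per_day=0))
        fit = GaussianHMM(n_states=2, n_starts=2, tol=1e-12, max_iter=2000).fit(res.series)

        # numerical gradient of the loglik w.r.t. means/sds/free transition
        def ll(mu, sd, a01, a10):
            mdl = GaussianHMM.from_params(
                fit.startprob_, mu, sd,
                [[1 - a01, a01], [a10, 1 - a10]],
            )
            return mdl.score(res.series)

        base = (fit.means_.copy(), fit.sds_.copy(),
                fit.transmat_[0, 1], fit.transmat_[1, 0])
        eps = 1e-6
        grads = []
        for i in range(2):
            for vec_idx, arr in [(0, base[0]), (1, base[1])]:
                up, dn = arr.copy(), arr.copy()
                up[i] += eps
                dn[i] -= eps
                args_up = [base[0], base[1], base[2], base[3]]
                args_dn = [base[0], base[1], base[2], base[3]]
                args_up[vec_idx] = up
                args_dn[vec_idx] = dn
                grads.append((ll(*args_up) - ll(*args_dn)) / (2 * eps))
        for k in (2, 3):
            args_up = list(base)
            args_dn = list(base)
            args_up[k] = base[k] + eps
            args_dn[k] = base[k] - eps
            grads.append((ll(*args_up) - ll(*args_dn)) / (2 * eps))
        assert np.max(np.abs(grads)) < 1e-3

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            fit_homogeneous(np.array([1.0, 2.0, 3.0]), m=2)

    def test_more_states_than_distinct_values_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            fit_homogeneous(np.array([1.0] * 50), m=2)


class TestInformationCriteria:
    def test_arithmetic(self):
        fit = GaussianHMM.from_params([1.0], [0.0], [1.0], [[1.0]])
        fit.loglik_ = -100.0
        fit.n_params_ = 10
        ic = information_criteria(fit, np.zeros(100))
        assert ic["aic"] == pytest.approx(220.0)
        assert ic["bic"] == pytest.approx(200 + 10 * np.log(100))

    def test_param_count_formula(self, homog3_fit):
        fit, _ = homog3_fit
        m = fit.n_states
        assert fit.n_params_ == (m - 1) + 2 * m + m * (m - 1)


class TestPseudoResiduals:
    def test_single_state_is_plain_zscore(self):
        m1 = GaussianHMM.from_params([1.0], [2.0], [0.5], [[1.0]])
        y = np.array([2.5, 1.0, 2.0])
        np.testing.assert_allclose(
            m1.pseudo_residuals(y), (y - 2.0) / 0.5, atol=1e-10
        )

    def test_standard_normal_under_true_model(self, homog2_sim):
        truth, res = homog2_sim
        z = truth.pseudo_residuals(res.series)
        d = stats.kstest(z, "norm")
        assert d.pvalue > 0.01

    def test_misspecified_model_inflates_variance(self):
        truth = GaussianHMM.from_params(
            [0.5, 0.5], [0.0, 6.0], [1.0, 1.0], [[0.95, 0.05], [0.05, 0.95]]
        )
        res = simulate(SimulationSpec(model=truth, n_days=5000 * 300 / 86400,
                                      seed=6, missing_blocks_per_day=0))
        # merge the two distant states into one
        merged = GaussianHMM.from_params([1.0], [3.0], [1.0], [[1.0]])
        z = merged.pseudo_residuals(res.series)
        assert z.var() > 1.2

    def test_missing_epochs_yield_no_residual(self, toy2):
        model, y = toy2
        y2 = y.copy()
        y2[1] = np.nan
        assert model.pseudo_residuals(y2).size == 2


class TestSerialization:
    def test_bit_exact_roundtrip(self, tmp_path, homog3_fit):
        fit, _ = homog3_fit
        p = tmp_path / "fit.json"
        fit.to_json(p)
        back = load_fit(p)
        np.testing.assert_array_equal(back.means_, fit.means_)
        np.testing.assert_array_equal(back.sds_, fit.sds_)
        np.testing.assert_array_equal(back.transmat_, fit.transmat_)
        np.testing.assert_array_equal(back.startprob_, fit.startprob_)
        assert back.loglik_ == fit.loglik_
        assert json.loads(back.to_json()) == json.loads(fit.to_json())


class TestAgainstHmmlearn:
    """Cross-check the likelihood against an independent HMM implementation."""

    def test_score_matches_hmmlearn(self, toy2):
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        model, y = toy2
        ref = hmmlearn.GaussianHMM(n_components=2, covariance_type="diag",
                                   init_params="")
        ref.startprob_ = model.startprob_
        ref.transmat_ = model.transmat_
        ref.means_ = model.means_[:, None]
        ref.covars_ = (model.sds_ ** 2)[:, None]
        assert model.score(y) == pytest.approx(ref.score(y[:, None]), abs=1e-8)

    def test_fit_agrees_with_hmmlearn_on_simulated_data(self, homog2_sim):
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        truth, res = homog2_sim
        y = res.series.values[~res.series.missing_mask]
        fit = GaussianHMM(n_states=2, n_starts=2, random_state=0).fit(y)
        ref = hmmlearn.GaussianHMM(n_components=2, covariance_type="diag",
                                   n_iter=500, tol=1e-6, random_state=0)
        ref.fit(y[:, None])
        order = np.argsort(ref.means_.ravel())
        np.testing.assert_allclose(fit.means_, ref.means_.ravel()[order], atol=0.05)
        np.testing.assert_allclose(
            np.diag(fit.transmat_), np.diag(ref.transmat_[np.ix_(order, order)]),
            atol=0.02,
        )


def test_wrapper_functions_mirror_estimator_surface(toy2):
    model, y = toy2
    assert log_likelihood(model, y) == model.score(y)
    np.testing.assert_array_equal(local_decode(smooth(model, y)), model.predict(y))
    np.testing.assert_array_equal(pseudo_residuals(model, y), model.pseudo_residuals(y))
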