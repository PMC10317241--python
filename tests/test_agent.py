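"""Inference core: context prediction, Gaussian evidence, Normal-Gamma updates."""

import math

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from scoin import (
    AgentConfig,
    Block,
    NormalGammaBelief,
    ScoinAgent,
    TaskConfig,
    cue_likelihood,
    learning_datum,
    observation_likelihood,
    posterior_context,
    predict_context,
    prediction_sd,
    select_action,
    simulate_run,
    transition_kernel,
    update_beliefs,
)
from scoin.core import DegeneratePosteriorError, ValidationError


class TestTransitionKernel:
    def test_diagonal_and_off_diagonal(self):
        k = transition_kernel(0.9, 3)
        assert np.allclose(np.diag(k), 0.9)
        assert np.allclose(k[~np.eye(3, dtype=bool)], 0.05)
        assert np.allclose(k.sum(axis=1), 1.0)

    def test_certain_self_transition_is_identity(self):
        assert np.array_equal(transition_kernel(1.0, 4), np.eye(4))

    def test_single_context_requires_certain_self_transition(self):
        with pytest.raises(ValidationError):
            transition_kernel(0.9, 1)


class TestCueLikelihood:
    def test_noiseless_cue_is_one_hot(self):
        assert np.array_equal(cue_likelihood(1, 0.0, 3), [0.0, 1.0, 0.0])

    def test_noisy_cue_splits_uncertainty_evenly(self):
        np.testing.assert_allclose(cue_likelihood(0, 0.33, 3), [0.67, 0.165, 0.165])

    def test_absent_cue_is_uninformative(self):
        assert np.array_equal(cue_likelihood(None, 0.33, 4), np.full(4, 0.25))

    def test_unknown_symbol_rejected(self):
        with pytest.raises(ValidationError):
            cue_likelihood(5, 0.0, 3)


class TestPredictContext:
    def test_transition_prior_from_certain_context(self):
        pred = predict_context([1.0, 0.0], transition_kernel(0.9, 2), np.array([0.5, 0.5]))
        np.testing.assert_allclose(pred, [0.9, 0.1])

    def test_one_hot_cue_dominates_any_prior(self):
        pred = predict_context([0.8, 0.2], transition_kernel(0.9, 2), cue_likelihood(1, 0.0, 2))
        np.testing.assert_allclose(pred, [0.0, 1.0])

    def test_cue_excluding_all_supported_contexts_raises(self):
        with pytest.raises(DegeneratePosteriorError):
            predict_context([1.0, 0.0], np.eye(2), np.array([0.0, 1.0]))


class TestPredictionSd:
    @pytest.mark.parametrize(
        "sx,sr,su,expected",
        [(0.0, 3.0, 1.0, math.sqrt(10)), (1.0, 2.5, 2.0, math.sqrt(11.25))],
    )
    def test_pythagorean_composition(self, sx, sr, su, expected):
        # a belief whose shrunk state-uncertainty (beta/alpha)/sqrt(nu) equals sx
        b = NormalGammaBelief(mu=0.0, nu=1.0, alpha=1.0, beta=max(sx, 1e-12))
        if sx == 0.0:
            b = NormalGammaBelief(mu=0.0, nu=1e30, alpha=1.0, beta=1e-12)
            assert prediction_sd(b, sr, su) == pytest.approx(expected, rel=1e-6)
        else:
            assert prediction_sd(b, sr, su) == pytest.approx(expected, rel=1e-12)

    def test_zero_ambient_noise_returns_state_uncertainty(self):
        b = NormalGammaBelief(mu=0.0, nu=4.0, alpha=2.0, beta=6.0)
        assert prediction_sd(b, 0.0, 0.0) == pytest.approx((6.0 / 2.0) / 2.0)

    def test_expected_sd_mode_skips_pseudocount_shrinkage(self):
        b = NormalGammaBelief(mu=0.0, nu=4.0, alpha=2.0, beta=6.0)
        assert prediction_sd(b, 0.0, 0.0, sigma_x_mode="expected-sd") == pytest.approx(3.0)


class TestObservationLikelihood:
    @pytest.fixture
    def cfg(self):
        return AgentConfig(
            p_self=0.9,
            sigma_r=2.5,
            sigma_u=0.0,
            hyperpriors=((20.0, 1e12, 1.0, 1e-6), (0.0, 1e12, 1.0, 1e-6)),
        )

    def test_density_matches_scipy_normal(self, cfg):
        beliefs = cfg.initial_beliefs()
        dens = observation_likelihood(0.0, 20.0, beliefs, cfg)
        # context 0 predicts error 20-20=0 with sd ~2.5: the Gaussian mode
        assert dens[0] == pytest.approx(scipy.stats.norm.pdf(0.0, 0.0, 2.5), rel=1e-6)
        assert dens[1] == pytest.approx(scipy.stats.norm.pdf(0.0, -20.0, 2.5), rel=1e-6)

    def test_symmetric_contexts_get_equal_densities(self):
        cfg = AgentConfig(
            p_self=0.9,
            sigma_r=1.0,
            sigma_u=0.0,
            hyperpriors=((4.0, 1e12, 1.0, 1e-6), (-4.0, 1e12, 1.0, 1e-6)),
        )
        dens = observation_likelihood(0.0, 0.0, cfg.initial_beliefs(), cfg)
        assert dens[0] == pytest.approx(dens[1], rel=1e-12)

    def test_non_finite_error_rejected(self, cfg):
        with pytest.raises(ValidationError):
            observation_likelihood(float("nan"), 0.0, cfg.initial_beliefs(), cfg)


class TestPosteriorContext:
    def test_equal_densities_leave_predictive_unchanged(self):
        pred = np.array([0.3, 0.7])
        np.testing.assert_allclose(posterior_context(pred, np.array([2.0, 2.0])), pred)

    def test_hand_normalization(self):
        np.testing.assert_allclose(
            posterior_context(np.array([0.5, 0.5]), np.array([0.3, 0.1])), [0.75, 0.25]
        )

    def test_zero_predictive_entry_is_absorbing(self):
        post = posterior_context(np.array([0.0, 1.0]), np.array([5.0, 1.0]))
        assert post[0] == 0.0 and post[1] == 1.0

    def test_log_space_survives_extreme_underflow(self):
        # direct densities would underflow to zero; log-space must not
        log_dens = np.array([-800.0, -805.0])
        post = posterior_context(np.array([0.5, 0.5]), log_dens, log=True)
        np.testing.assert_allclose(post.sum(), 1.0, atol=1e-12)
        assert post[0] > post[1]

    def test_fully_degenerate_falls_back_to_predictive(self, caplog):
        pred = np.array([0.4, 0.6])
        with caplog.at_level("WARNING", logger="scoin"):
            post = posterior_context(pred, np.array([-np.inf, -np.inf]), log=True)
        np.testing.assert_allclose(post, pred)
        assert any("degenerate" in r.message for r in caplog.records)

    @settings(deadline=None, derandomize=True)
    @given(
        raw_p=st.lists(st.floats(0.01, 1.0), min_size=2, max_size=5),
        raw_d=st.lists(st.floats(1e-6, 1e6), min_size=2, max_size=5),
    )
    def test_posterior_is_normalized_for_any_inputs(self, raw_p, raw_d):
        n = min(len(raw_p), len(raw_d))
        pred = np.array(raw_p[:n]) / np.sum(raw_p[:n])
        post = posterior_context(pred, np.array(raw_d[:n]))
        assert abs(post.sum() - 1.0) <= 1e-12 and (post >= 0).all()


class TestSelectAction:
    def test_delta_probability_selects_that_context_mean(self, rng):
        beliefs = [NormalGammaBelief(0.0, 1, 1, 1), NormalGammaBelief(20.0, 1, 1, 1)]
        u, _ = select_action(np.array([0.0, 1.0]), beliefs, 0.0, rng)
        assert u == 20.0

    def test_weighted_mean_of_context_means(self, rng):
        beliefs = [NormalGammaBelief(0.0, 1, 1, 1), NormalGammaBelief(20.0, 1, 1, 1)]
        u, u_exec = select_action(np.array([0.5, 0.5]), beliefs, 0.0, rng)
        assert u == 10.0 and u_exec == 10.0  # no motor noise -> executed exactly

    def test_motor_noise_perturbs_execution_only(self, rng):
        beliefs = [NormalGammaBelief(5.0, 1, 1, 1)]
        u, u_exec = select_action(np.array([1.0]), beliefs, 2.0, rng)
        assert u == 5.0 and u_exec != 5.0


class TestLearningDatum:
    @pytest.mark.parametrize("e,u,expected", [(0.0, 20.0, 20.0), (20.0, 0.0, 20.0), (0.0, 0.0, 0.0)])
    def test_reconstructs_state_observation(self, e, u, expected):
        assert learning_datum(e, u) == expected


class TestUpdateBeliefs:
    def test_zero_weight_context_is_bitwise_unchanged(self):
        b = NormalGammaBelief(mu=1.2345, nu=3.0, alpha=2.0, beta=5.0)
        out = update_beliefs([b, NormalGammaBelief(0, 1, 1, 1)], 2.0, np.array([0.0, 1.0]))
        assert out[0] is b

    def test_unit_weight_conjugate_update(self):
        (out,) = update_beliefs([NormalGammaBelief(0, 1, 1, 1)], 2.0, np.array([1.0]))
        assert (out.mu, out.nu, out.alpha, out.beta) == (1.0, 2.0, 1.5, 2.0)

    def test_fractional_weight_follows_all_four_update_lines(self):
        beliefs = [NormalGammaBelief(0, 1, 1, 1), NormalGammaBelief(0, 1, 1, 1)]
        out = update_beliefs(beliefs, 2.0, np.array([0.5, 0.5]))
        b = out[0]
        assert b.mu == pytest.approx(2 / 3)
        assert b.nu == pytest.approx(1.5)
        assert b.alpha == pytest.approx(1.25)
        assert b.beta == pytest.approx(1 + 2 / 3)

    def test_unnormalized_responsibilities_rejected(self):
        with pytest.raises(ValidationError):
            update_beliefs([NormalGammaBelief(0, 1, 1, 1)], 2.0, np.array([0.5]))

    def test_sequential_one_hot_updates_equal_batch_posterior(self, rng):
        """Running T one-hot updates must equal the closed-form batch
        Normal-Gamma posterior of the same T data points."""
        mu0, nu0, a0, b0 = 0.5, 2.0, 1.5, 3.0
        data = rng.normal(4.0, 2.0, size=100)
        beliefs = [NormalGammaBelief(mu0, nu0, a0, b0)]
        for s in data:
            beliefs = update_beliefs(beliefs, float(s), np.array([1.0]))
        n, xbar = data.size, data.mean()
        mu_n = (nu0 * mu0 + n * xbar) / (nu0 + n)
        beta_n = b0 + 0.5 * ((data - xbar) ** 2).sum() + nu0 * n * (xbar - mu0) ** 2 / (2 * (nu0 + n))
        b = beliefs[0]
        assert b.mu == pytest.approx(mu_n, abs=1e-10)
        assert b.nu == pytest.approx(nu0 + n, abs=1e-10)
        assert b.alpha == pytest.approx(a0 + n / 2, abs=1e-10)
        assert b.beta == pytest.approx(beta_n, abs=1e-10)

    @settings(deadline=None, derandomize=True)
    @given(
        w=st.floats(0.0, 1.0),
        s=st.floats(-50.0, 50.0),
        nu=st.floats(0.5, 100.0),
    )
    def test_invariants_preserved_under_any_fractional_update(self, w, s, nu):
        beliefs = [NormalGammaBelief(1.0, nu, 2.0, 3.0), NormalGammaBelief(0, 1, 1, 1)]
        out = update_beliefs(beliefs, s, np.array([w, 1.0 - w]))
        for b in out:
            assert b.nu > 0 and b.alpha > 0 and b.beta > 0


class TestAgentStep:
    def _noiseless(self, n_ctx=2, mus=(0.0, 4.0), nu=1e12):
        return AgentConfig(
            p_self=0.9,
            sigma_r=0.5,
            sigma_u=0.0,
            eta=0.0,
            hyperpriors=tuple((m, nu, 1.0, 1e-6) for m in mus[:n_ctx]),
        )

    def test_cold_start_issues_zero_command(self, rng):
        cfg = self._noiseless(mus=(0.0, 0.0), nu=1.0)
        agent = ScoinAgent(cfg)
        rec = agent.step(None, lambda u: (4.0 - u, False, 1), rng)
        assert rec.u == 0.0

    def test_deterministic_cue_switches_prediction_same_trial(self, rng):
        agent = ScoinAgent(self._noiseless())
        agent.step(0, lambda u: (0.0 - u, False, 0), rng)
        rec = agent.step(1, lambda u: (4.0 - u, False, 1), rng)
        # the eta=0 cue makes the predictive one-hot on the new context at once
        np.testing.assert_allclose(rec.predictive, [0.0, 1.0])
        assert rec.u == pytest.approx(4.0)

    def test_uncued_switch_corrects_with_one_trial_lag(self, rng):
        cfg = AgentConfig(
            p_self=0.9,
            sigma_r=0.5,
            sigma_u=0.0,
            hyperpriors=((0.0, 1e12, 1.0, 1e-6), (4.0, 1e12, 1.0, 1e-6)),
        )
        agent = ScoinAgent(cfg)
        for _ in range(5):
            agent.step(None, lambda u: (0.0 - u, False, 0), rng)
        first = agent.step(None, lambda u: (4.0 - u, False, 1), rng)
        second = agent.step(None, lambda u: (4.0 - u, False, 1), rng)
        assert first.u < 1.0  # still acting on the old context
        assert second.u > 3.0  # corrected the trial after feedback

    def test_zero_noise_adapted_delta_agent_makes_zero_error(self):
        task = TaskConfig(
            context_adaptations=(4.0,),
            adaptation_noise=0.0,
            observation_noise=0.0,
            blocks=(Block(0, 10),),
        )
        cfg = AgentConfig(
            p_self=1.0, sigma_r=1e-9, sigma_u=0.0, hyperpriors=((4.0, 1e12, 1.0, 1e-9),)
        )
        run = simulate_run(task, cfg, seed=0)
        assert np.allclose(run["error"], 0.0)

    def test_probability_vectors_conserved_each_trial(self, two_context_task, two_context_agent):
        run = simulate_run(two_context_task, two_context_agent, seed=3)
        for prefix in ("p_pred_", "p_ctx_"):
            total = sum(run[f"{prefix}{j}"] for j in range(2))
            assert np.abs(total - 1.0).max() <= 1e-12

    def test_zero_posterior_context_is_frozen(self, rng):
        """A context held at zero posterior throughout a block keeps bitwise
        identical Normal-Gamma parameters."""
        cfg = self._noiseless(nu=1.0)
        agent = ScoinAgent(cfg)
        before = agent.beliefs[1]
        for _ in range(10):
            # eta=0 cue for context 0 gives context 1 exactly zero posterior
            agent.step(0, lambda u: (0.0 - u, False, 0), rng)
        assert agent.beliefs[1] is before
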