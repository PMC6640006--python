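"""Tests of the Bayesian adaptive engine: priors, information gain, updates,
estimates, sessions, and rescoring."""

import numpy as np
import pytest
from scipy.special import xlogy

from qcsf.engine import (
    LikelihoodCache,
    PosteriorGrid,
    Stimulus,
    StimulusSpace,
    TrialRecord,
    _node_response_probabilities,
    default_parameter_grid,
    default_stimulus_space,
    expected_information_gain,
    init_prior,
    posterior_estimates,
    rescore_session,
    response_probability,
    run_session,
    select_stimulus,
    update_posterior,
)
from qcsf.model import CSFParameters, PsychometricSpec, aulcsf, csf_sensitivity
from qcsf.observers import default_group_specs, sample_observer


def _random_posterior(grid, rng):
    w = rng.random(grid.n_nodes)
    return PosteriorGrid(grid=grid, weights=w / w.sum())


def _entropy_bits(w):
    return float(-np.sum(xlogy(w, w)) / np.log(2))


class TestPrior:
    def test_uniform(self, small_grid):
        prior = init_prior(small_grid)
        assert prior.weights.shape == (small_grid.n_nodes,)
        np.testing.assert_allclose(prior.weights, 1.0 / small_grid.n_nodes)

    def test_population_normalizes(self, small_grid, rng):
        raw = rng.random(small_grid.n_nodes)
        prior = init_prior(small_grid, "population", raw)
        np.testing.assert_allclose(prior.weights, raw / raw.sum(), rtol=1e-12)

    def test_population_all_zero_rejected(self, small_grid):
        with pytest.raises(ValueError):
            init_prior(small_grid, "population", np.zeros(small_grid.n_nodes))

    def test_shape_mismatch_rejected(self, small_grid):
        with pytest.raises(ValueError):
            init_prior(small_grid, "population", np.ones(7))


class TestResponseProbability:
    def test_threshold_contrast_gives_053(self, spec):
        theta = CSFParameters(100.0, 3.0, 0.4, 0.5)
        c = 1.0 / csf_sensitivity(2.0, theta)
        stim = Stimulus(frequency=2.0, contrast=c)
        assert response_probability(stim, theta, spec) == pytest.approx(0.53, abs=1e-12)

    def test_far_above_cutoff_is_guessing(self, spec):
        theta = CSFParameters(50.0, 1.0, 0.3, 0.5)
        stim = Stimulus(frequency=40.0, contrast=1.0)
        assert response_probability(stim, theta, spec) == pytest.approx(0.1, abs=1e-6)

    def test_monotone_in_contrast(self, spec):
        theta = CSFParameters(50.0, 2.0, 0.4, 0.5)
        probs = [
            response_probability(Stimulus(2.0, c), theta, spec)
            for c in np.logspace(-3, 0, 30)
        ]
        assert np.all(np.diff(probs) >= 0)


class TestInformationGain:
    def test_point_mass_gains_nothing(self, tiny_grid, spec):
        w = np.zeros(tiny_grid.n_nodes)
        w[5] = 1.0
        post = PosteriorGrid(grid=tiny_grid, weights=w)
        stim = Stimulus(frequency=2.0, contrast=0.1)
        assert expected_information_gain(post, stim, spec) == pytest.approx(0.0, abs=1e-15)

    def test_constant_likelihood_gains_nothing(self, tiny_grid, spec, rng):
        post = _random_posterior(tiny_grid, rng)
        stim = Stimulus(frequency=2.0, contrast=1e-12)  # every node at guessing
        assert expected_information_gain(post, stim, spec) == pytest.approx(0.0, abs=1e-12)

    def test_matches_exhaustive_two_outcome_oracle(self, tiny_grid, spec, rng):
        """MI equals prior entropy minus expected posterior entropy."""
        for _ in range(10):
            post = _random_posterior(tiny_grid, rng)
            stim = Stimulus(
                frequency=float(10 ** rng.uniform(-0.2, 1.6)),
                contrast=float(10 ** rng.uniform(-3, 0)),
            )
            p = _node_response_probabilities(tiny_grid, stim, spec)
            oracle = _entropy_bits(post.weights)
            for like in (p, 1.0 - p):
                joint = post.weights * like
                p_outcome = joint.sum()
                oracle -= p_outcome * _entropy_bits(joint / p_outcome)
            gain = expected_information_gain(post, stim, spec)
            assert gain == pytest.approx(oracle, abs=1e-9)
            assert gain >= 0.0

    def test_nonnegative_over_stimulus_space(self, tiny_grid, spec, rng):
        post = _random_posterior(tiny_grid, rng)
        space = default_stimulus_space(6, 6)
        for stim in space.stimuli():
            assert expected_information_gain(post, stim, spec) >= 0.0


class TestSelectStimulus:
    def test_single_stimulus_space(self, tiny_grid, spec):
        space = StimulusSpace(
            frequencies=np.array([2.0]), contrasts=np.array([0.3])
        )
        post = init_prior(tiny_grid)
        stim = select_stimulus(post, space, spec)
        assert stim == Stimulus(frequency=2.0, contrast=0.3)

    def test_tie_break_lowest_contrast_then_frequency(self, tiny_grid, spec):
        # a point-mass posterior makes every gain exactly zero
        w = np.zeros(tiny_grid.n_nodes)
        w[0] = 1.0
        post = PosteriorGrid(grid=tiny_grid, weights=w)
        space = default_stimulus_space(4, 5)
        stim = select_stimulus(post, space, spec)
        assert stim.contrast == pytest.approx(space.contrasts[0])
        assert stim.frequency == pytest.approx(space.frequencies[0])

    def test_argmax_matches_exhaustive_scan(self, tiny_grid, spec, rng):
        post = _random_posterior(tiny_grid, rng)
        space = default_stimulus_space(5, 6)
        chosen = select_stimulus(post, space, spec)
        gains = {
            (s.contrast, s.frequency): expected_information_gain(post, s, spec)
            for s in space.stimuli()
        }
        best = max(gains.values())
        assert gains[(chosen.contrast, chosen.frequency)] == pytest.approx(best, abs=1e-12)

    def test_empty_space_rejected(self, tiny_grid, spec):
        post = init_prior(tiny_grid)
        with pytest.raises(ValueError):
            StimulusSpace(frequencies=np.array([]), contrasts=np.array([0.5]))


class TestUpdate:
    def test_flat_likelihood_leaves_posterior_unchanged(self, tiny_grid, spec, rng):
        post = _random_posterior(tiny_grid, rng)
        trial = TrialRecord(1, Stimulus(2.0, 1e-12), correct=False)
        updated = update_posterior(post, trial, spec)
        np.testing.assert_allclose(updated.weights, post.weights, rtol=1e-12)

    def test_correct_at_low_contrast_raises_gain_belief(self, tiny_grid, spec, rng):
        """Seeing a faint target is evidence for higher sensitivity."""
        post = init_prior(tiny_grid)
        trial = TrialRecord(1, Stimulus(3.0, 0.005), correct=True)
        updated = update_posterior(post, trial, spec)
        log_gain = np.log10(tiny_grid.peak_gain)
        node_lg = np.repeat(log_gain, tiny_grid.n_nodes // 3)
        before = node_lg @ post.weights
        after = node_lg @ updated.weights
        assert after >= before

    def test_two_updates_equal_product_likelihood(self, tiny_grid, spec, rng):
        post = _random_posterior(tiny_grid, rng)
        t1 = TrialRecord(1, Stimulus(2.0, 0.1), correct=True)
        t2 = TrialRecord(2, Stimulus(5.0, 0.03), correct=False)
        seq = update_posterior(update_posterior(post, t1, spec), t2, spec)
        l1 = _node_response_probabilities(tiny_grid, t1.stimulus, spec)
        l2 = 1.0 - _node_response_probabilities(tiny_grid, t2.stimulus, spec)
        w = post.weights * l1 * l2
        np.testing.assert_allclose(seq.weights, w / w.sum(), atol=1e-12)

    def test_normalization_after_every_update(self, small_grid, spec, rng):
        post = init_prior(small_grid)
        for i in range(1, 31):
            stim = Stimulus(
                float(10 ** rng.uniform(-0.2, 1.6)),
                float(10 ** rng.uniform(-3, 0)),
            )
            post = update_posterior(
                post, TrialRecord(i, stim, bool(rng.random() < 0.6)), spec
            )
            assert abs(post.weights.sum() - 1.0) < 1e-12

    def test_degenerate_update_rejected(self, tiny_grid):
        # with no guessing floor, an impossible correct response at
        # vanishing contrast has zero likelihood everywhere
        s = PsychometricSpec(guess_rate=0.0, lapse_rate=0.0)
        post = init_prior(tiny_grid)
        trial = TrialRecord(1, Stimulus(2.0, 1e-12), correct=True)
        with pytest.raises(ValueError, match="degenerate"):
            update_posterior(post, trial, s)

    def test_expected_posterior_entropy_never_exceeds_prior(self, tiny_grid, spec, rng):
        """Data-processing inequality at the selected stimulus."""
        post = _random_posterior(tiny_grid, rng)
        space = default_stimulus_space(5, 6)
        stim = select_stimulus(post, space, spec)
        p = _node_response_probabilities(tiny_grid, stim, spec)
        expected_entropy = 0.0
        for like in (p, 1.0 - p):
            joint = post.weights * like
            expected_entropy += joint.sum() * _entropy_bits(joint / joint.sum())
        assert expected_entropy <= _entropy_bits(post.weights) + 1e-12


class TestEstimates:
    def test_point_mass_recovers_node(self, tiny_grid, spec):
        idx = 7
        w = np.zeros(tiny_grid.n_nodes)
        w[idx] = 1.0
        post = PosteriorGrid(grid=tiny_grid, weights=w)
        params, aul, acu, ciw = posterior_estimates(post)
        shape = tiny_grid.shape
        ig, jf, kb, lt = np.unravel_index(idx, shape)
        assert params.peak_gain == pytest.approx(tiny_grid.peak_gain[ig])
        assert params.peak_frequency == pytest.approx(tiny_grid.peak_frequency[jf])
        assert ciw == 0.0
        assert aul == pytest.approx(tiny_grid.node_aulcsf()[idx])

    def test_two_node_mean(self, tiny_grid, spec):
        w = np.zeros(tiny_grid.n_nodes)
        w[0] = w[-1] = 0.5
        post = PosteriorGrid(grid=tiny_grid, weights=w)
        _, aul, _, _ = posterior_estimates(post)
        node_aul = tiny_grid.node_aulcsf()
        assert aul == pytest.approx((node_aul[0] + node_aul[-1]) / 2)

    def test_ci_width_matches_weighted_quantile_oracle(self, tiny_grid, spec, rng):
        post = _random_posterior(tiny_grid, rng)
        _, _, _, ciw = posterior_estimates(post)
        vals = tiny_grid.node_aulcsf()
        order = np.argsort(vals, kind="stable")
        cw = np.cumsum(post.weights[order])

        def oracle_q(q):
            return vals[order][np.searchsorted(cw, q * cw[-1], side="left")]

        assert ciw == pytest.approx(oracle_q(0.8415) - oracle_q(0.1585), abs=1e-12)


class TestSession:
    def test_zero_trials_returns_prior_estimates(self, small_grid, small_space, spec):
        prior = init_prior(small_grid)
        res = run_session(
            lambda s, r: True, n_trials=0, prior=prior, space=small_space, spec=spec
        )
        p0, aul0, acu0, ciw0 = posterior_estimates(prior)
        assert res.aulcsf_estimate == pytest.approx(aul0)
        assert res.trials == ()
        np.testing.assert_allclose(res.posterior.weights, prior.weights)

    def test_fixed_seed_is_bitwise_reproducible(self, small_grid, small_space, spec):
        obs = sample_observer(
            default_group_specs()[2], np.random.default_rng(3), "X", True
        )
        cache = LikelihoodCache(small_grid, small_space, spec)
        r1 = run_session(obs.responder("DE"), 25, init_prior(small_grid),
                         spec=spec, seed=11, cache=cache)
        r2 = run_session(obs.responder("DE"), 25, init_prior(small_grid),
                         spec=spec, seed=11, cache=cache)
        assert r1.trials == r2.trials
        np.testing.assert_array_equal(r1.posterior.weights, r2.posterior.weights)

    def test_ci_width_shrinks_with_trials(self, recovery_cache, spec):
        obs = sample_observer(
            default_group_specs()[2], np.random.default_rng(5), "X", True
        )
        prior = init_prior(recovery_cache.grid)
        widths5, widths25 = [], []
        for seed in range(10):
            r5 = run_session(obs.responder("DE"), 5, prior, spec=spec,
                             seed=seed, cache=recovery_cache)
            r25 = run_session(obs.responder("DE"), 25, prior, spec=spec,
                              seed=seed, cache=recovery_cache)
            widths5.append(r5.ci_width)
            widths25.append(r25.ci_width)
        assert np.mean(widths25) < np.mean(widths5)


class TestRescore:
    def test_original_prior_reproduces_posterior(self, small_grid, small_space, spec):
        obs = sample_observer(
            default_group_specs()[0], np.random.default_rng(8), "X", True
        )
        cache = LikelihoodCache(small_grid, small_space, spec)
        prior = init_prior(small_grid)
        res = run_session(obs.responder("NDE"), 15, prior, spec=spec,
                          seed=2, cache=cache)
        replay = rescore_session(res.trials, prior, spec)
        np.testing.assert_allclose(
            replay.posterior.weights, res.posterior.weights, atol=1e-12
        )

    def test_empty_trial_list_returns_prior(self, small_grid, spec):
        prior = init_prior(small_grid)
        res = rescore_session([], prior, spec)
        np.testing.assert_allclose(res.posterior.weights, prior.weights)

    def test_informative_prior_reduces_error_on_short_sessions(
        self, small_grid, small_space, spec
    ):
        """A population prior concentrated near truth beats a uniform prior
        for 10-trial sessions (median absolute AULCSF error, 100 sessions)."""
        cache = LikelihoodCache(small_grid, small_space, spec)
        prior_u = init_prior(small_grid)
        gspec = default_group_specs()[2]
        # population prior: broad normal around the control group's typical
        # log parameters
        logs = np.stack(
            [
                np.broadcast_to(
                    np.log10(ax).reshape([-1 if i == j else 1 for j in range(4)]),
                    small_grid.shape,
                ).reshape(-1)
                for i, ax in enumerate(
                    [small_grid.peak_gain, small_grid.peak_frequency,
                     small_grid.bandwidth, small_grid.truncation]
                )
            ]
        )
        centers = np.array([
            gspec.de.mean_log_gain, gspec.de.mean_log_frequency,
            gspec.de.mean_log_bandwidth, gspec.de.mean_log_truncation,
        ])
        scales = np.array([0.3, 0.2, 0.15, 0.2])
        w = np.exp(-0.5 * np.sum(((logs - centers[:, None]) / scales[:, None]) ** 2, axis=0))
        prior_p = init_prior(small_grid, "population", w)
        err_u, err_p = [], []
        for seed in range(100):
            obs = sample_observer(
                gspec, np.random.default_rng(1000 + seed), "X", True
            )
            truth = aulcsf(obs.csf_de)
            ru = run_session(obs.responder("DE"), 10, prior_u, spec=spec,
                             seed=seed, cache=cache)
            rp = rescore_session(ru.trials, prior_p, spec, cache=cache)
            err_u.append(abs(ru.aulcsf_estimate - truth))
            err_p.append(abs(rp.aulcsf_estimate - truth))
        assert np.median(err_p) < np.median(err_u)
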