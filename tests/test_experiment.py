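import dataclasses

import numpy as np
import pytest

from spikering.experiment import (
    ExperimentConfig,
    LearningCurve,
    NetworkState,
    animat_streams,
    eligibility_profile,
    gradient_profile,
    run_learning_experiment,
    run_scenario,
    run_trial,
    trials_to_reward,
)


def small_config(**kw):
    """A fast configuration for protocol-level tests (not the study scale)."""
    defaults = dict(
        n_place=32, n_action=32, t_steps=64, n_animats=2,
        trials_per_block=24, analysis_trials=16, n_blocks=2, master_seed=7,
        u_theta=-55.0, delta_u=3.0, rho0=60.0, beta=2.0,
    )
    defaults.update(kw)
    return ExperimentConfig(**defaults)


class TestRunTrial:
    def test_analysis_trial_leaves_weights_bit_identical(self):
        cfg = small_config()
        state = NetworkState.initial(cfg)
        state.w_ff = np.random.default_rng(0).normal(0, 1.0, state.w_ff.shape)
        before = state.w_ff.copy()
        streams = animat_streams(cfg.master_seed, 1)[0]
        for _ in range(5):
            run_trial(state, cfg, learning=False, streams=streams)
        assert state.w_ff is before or np.array_equal(state.w_ff, before)

    def test_learning_trial_changes_weights(self):
        cfg = small_config()
        state = NetworkState.initial(cfg)
        streams = animat_streams(cfg.master_seed, 1)[0]
        run_trial(state, cfg, learning=True, streams=streams)
        assert np.abs(state.w_ff).sum() > 0

    def test_reproducible_given_seed(self):
        cfg = small_config()
        results = []
        for _ in range(2):
            state = NetworkState.initial(cfg)
            streams = animat_streams(cfg.master_seed, 1)[0]
            results.append([run_trial(state, cfg, True, streams) for _ in range(10)])
        for a, b in zip(*results):
            assert a == b

    def test_reward_consistent_with_decision(self):
        from spikering.geometry import gaussian_reward, normalized_error

        cfg = small_config()
        state = NetworkState.initial(cfg)
        streams = animat_streams(3, 1)[0]
        for _ in range(10):
            r = run_trial(state, cfg, False, streams)
            if not r.degenerate:
                assert r.reward == pytest.approx(
                    gaussian_reward(r.target, r.decision, cfg.reward_params)
                )
                assert r.error == pytest.approx(normalized_error(r.target, r.decision))

    def test_degenerate_trial_scored_conservatively(self):
        # a network that cannot spike (tiny escape rate) yields reward 0,
        # error 1 and no weight change
        cfg = small_config(rho0=1e-8)
        state = NetworkState.initial(cfg)
        streams = animat_streams(0, 1)[0]
        res = run_trial(state, cfg, learning=True, streams=streams)
        assert res.degenerate
        assert res.reward == 0.0 and res.error == 1.0
        assert not state.w_ff.any()
        assert state.degenerate_trials == 1


class TestLearningExperiment:
    def test_curve_shape_and_block_zero(self):
        cfg = small_config(n_blocks=0)
        curve = run_learning_experiment(cfg)
        assert len(curve.reward_mean) == 1
        assert curve.reward_per_animat.shape == (2, 1)

    def test_bit_identical_reproducibility(self):
        cfg = small_config()
        c1 = run_learning_experiment(cfg)
        c2 = run_learning_experiment(cfg)
        assert np.array_equal(c1.reward_per_animat, c2.reward_per_animat)
        assert np.array_equal(c1.error_per_animat, c2.error_per_animat)

    def test_animat_results_independent_of_ensemble_size(self):
        # stream isolation: animat k's trajectory must not depend on how
        # many other animats run alongside it
        cfg2 = small_config(n_animats=2)
        cfg4 = small_config(n_animats=4)
        c2 = run_learning_experiment(cfg2)
        c4 = run_learning_experiment(cfg4)
        assert np.array_equal(c2.reward_per_animat, c4.reward_per_animat[:2])

    def test_to_frame_round_trip(self):
        cfg = small_config(n_blocks=1)
        curve = run_learning_experiment(cfg)
        frame = curve.to_frame()
        mean_rows = frame[frame["kind"] == "ensemble_mean"].sort_values("block")
        assert np.allclose(mean_rows["reward"].values, curve.reward_mean)
        assert set(frame["kind"]) == {"animat", "ensemble_mean", "ensemble_std"}


class TestTrialsToReward:
    def test_interpolates_between_blocks(self):
        curve = LearningCurve(
            blocks=np.arange(3),
            reward_mean=np.array([0.2, 0.6, 0.8]),
            reward_std=np.zeros(3), error_mean=np.zeros(3), error_std=np.zeros(3),
            reward_per_animat=np.zeros((1, 3)), error_per_animat=np.zeros((1, 3)),
            trials_per_block=512,
        )
        # 0.7 is halfway between the block-1 and block-2 evaluations
        assert trials_to_reward(curve, 0.7) == pytest.approx(512 + 256)

    def test_already_above_threshold(self):
        curve = LearningCurve(
            blocks=np.arange(2), reward_mean=np.array([0.75, 0.9]),
            reward_std=np.zeros(2), error_mean=np.zeros(2), error_std=np.zeros(2),
            reward_per_animat=np.zeros((1, 2)), error_per_animat=np.zeros((1, 2)),
            trials_per_block=512,
        )
        assert trials_to_reward(curve, 0.7) == 0.0

    def test_never_reached(self):
        curve = LearningCurve(
            blocks=np.arange(2), reward_mean=np.array([0.2, 0.3]),
            reward_std=np.zeros(2), error_mean=np.zeros(2), error_std=np.zeros(2),
            reward_per_animat=np.zeros((1, 2)), error_per_animat=np.zeros((1, 2)),
            trials_per_block=512,
        )
        assert trials_to_reward(curve, 0.7) == float("inf")


class TestProfiles:
    def test_profile_shape_and_centre(self):
        cfg = small_config()
        prof = gradient_profile(cfg, n_samples=32)
        assert len(prof.values) == cfg.n_action
        assert prof.centre_index == cfg.n_action // 2
        assert prof.n_samples == 32

    def test_eligibility_profile_shared_seed_isolates_noise(self):
        # without noise, the with/without pair at the same shared seed is
        # identical (the noise stream is the only difference)
        cfg = small_config(noise_eps=0.0)
        a = eligibility_profile(cfg, with_noise=False, n_samples=16, shared_seed=5)
        b = eligibility_profile(cfg, with_noise=True, n_samples=16, shared_seed=5)
        assert np.array_equal(a.values, b.values)

    def test_gradient_profile_reproducible(self):
        cfg = small_config()
        p1 = gradient_profile(cfg, n_samples=16)
        p2 = gradient_profile(cfg, n_samples=16)
        assert np.array_equal(p1.values, p2.values)


class TestScenarios:
    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError, match="unknown scenario"):
            run_scenario("nonexistent", small_config())

    def test_lateral_strength_scenario_emits_tables(self):
        cfg = small_config(n_blocks=1, trials_per_block=8, analysis_trials=8, n_animats=1)
        tables = run_scenario("lateral_strength", cfg, n_profile_samples=8)
        assert {"curve_no_lateral", "curve_weak_lateral", "curve_strong_lateral",
                "profile_no_lateral", "profile_weak_lateral", "profile_strong_lateral"} <= set(tables)
        for frame in tables.values():
            assert len(frame) > 0

    @pytest.mark.parametrize(
        "name, expected_keys",
        [
            ("reward_width", {"curve_wide_no_lateral", "curve_narrow_lateral",
                              "profile_wide_lateral", "profile_narrow_no_lateral"}),
            ("overlap", {"curve_overlap_no_lateral", "curve_overlap_lateral",
                         "curve_reference_no_lateral", "profile_overlap_lateral"}),
            ("synaptic_noise", {"curve_noisy_no_lateral", "curve_clean_lateral",
                                "elig_profile_clean_no_lateral", "elig_profile_noisy_lateral"}),
        ],
    )
    def test_other_scenarios_emit_tables(self, name, expected_keys):
        cfg = small_config(n_blocks=1, trials_per_block=4, analysis_trials=4, n_animats=1)
        tables = run_scenario(name, cfg, n_profile_samples=4)
        assert expected_keys <= set(tables)
        for frame in tables.values():
            assert len(frame) > 0
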