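import numpy as np
import pytest

from wmring.circular import circ_diff
from wmring.rnn_core import (NetworkParams, decoder_batch, output_color,
                             population_vector_decode, response_window_mean,
                             rollout, step)
from wmring.task_env import (EnvironmentPrior, EpochSchedule, NoiseConfig,
                             TuningBank, build_trials, tuning_response)
from wmring.training import init_params


def zero_net(n=16, **kw):
    bank = TuningBank()
    return NetworkParams(np.zeros((n, n)), np.zeros((n, 13)), np.zeros(n),
                         np.zeros((12, n)), np.zeros(12), **kw)


class TestStep:
    def test_zero_network_collapses_to_zero(self):
        p = zero_net()
        x = step(p, np.ones(16) * 0.7, np.zeros(13))
        assert np.allclose(x, 0.0)

    def test_alpha_one_is_exact_discrete_map(self):
        p = init_params(16, rng=0)
        x_prev = np.random.default_rng(1).standard_normal(16)
        u = np.random.default_rng(2).standard_normal(13)
        got = step(p, x_prev, u)
        want = p.w_rec @ np.tanh(x_prev) + p.w_in @ u + p.b
        assert np.allclose(got, want, atol=1e-12)

    def test_recurrent_noise_std(self):
        # injected term per step has std sigma_rec * sqrt(2/alpha)
        p = zero_net(sigma_rec=0.2)
        sched = EpochSchedule(fixation_ms=0.0, perception_ms=20.0, delay_ms=0.0,
                              go_ms=0.0, response_ms=140.0)
        b = build_trials(EnvironmentPrior(), TuningBank(), sched, 400,
                         NoiseConfig(0.0, 0.2), rng=0)
        traj = rollout(p, b, noise_on=True, rng=5)
        draws = traj.x.reshape(-1)
        assert draws.std() == pytest.approx(0.2 * np.sqrt(2.0), rel=0.02)

    def test_nonfinite_state_raises(self):
        p = zero_net()
        with pytest.raises(FloatingPointError):
            step(p, np.full(16, np.inf), np.zeros(13))

    def test_diagonal_forced_to_zero(self):
        w = np.ones((8, 8))
        p = NetworkParams(w, np.zeros((8, 13)), np.zeros(8),
                          np.zeros((12, 8)), np.zeros(12))
        assert np.all(np.diag(p.w_rec) == 0)


class TestRollout:
    def test_zero_weights_emit_bias(self):
        p = zero_net()
        p.b_out[:] = np.arange(12, dtype=float)
        b = build_trials(EnvironmentPrior(), TuningBank(), EpochSchedule(), 2,
                         NoiseConfig(0, 0), rng=0)
        traj = rollout(p, b, noise_on=False)
        assert np.allclose(traj.z, np.arange(12.0))

    def test_same_seed_bit_identical(self):
        p = init_params(24, rng=0)
        b = build_trials(EnvironmentPrior(), TuningBank(), EpochSchedule(), 4,
                         NoiseConfig(), rng=1)
        t1 = rollout(p, b, noise_on=True, rng=9)
        t2 = rollout(p, b, noise_on=True, rng=9)
        assert np.array_equal(t1.x, t2.x)

    def test_splice_equals_full_rollout(self, small_net):
        """Re-entering the network at the end-of-delay state and running only
        go + response reproduces the full trajectory's output exactly."""
        sched = EpochSchedule(delay_ms=400.0)
        bank = TuningBank()
        b = build_trials(EnvironmentPrior(), bank, sched, 3,
                         NoiseConfig(0, 0), rng=1)
        full = rollout(small_net, b, noise_on=False)
        eod = full.states_at("end_of_delay")
        tail = rollout(small_net, decoder_batch(sched, 3, bank),
                       noise_on=False, init_state=eod)
        assert np.allclose(output_color(full), output_color(tail), atol=1e-9)

    def test_bad_init_state_shape_rejected(self, small_net):
        b = build_trials(EnvironmentPrior(), TuningBank(), EpochSchedule(), 2,
                         NoiseConfig(0, 0), rng=0)
        with pytest.raises(ValueError):
            rollout(small_net, b, init_state=np.zeros(7))


class TestPopulationVector:
    def test_one_hot_unit_three_decodes_ninety(self):
        z = np.zeros(12)
        z[3] = 1.0
        assert population_vector_decode(z) == pytest.approx(90.0)

    def test_inverts_noiseless_tuning(self):
        bank = TuningBank()
        # exact at multiples of the half-spacing (15 deg), where the
        # 12th-harmonic aliasing term vanishes
        for c in np.arange(0.0, 360.0, 15.0):
            got = population_vector_decode(tuning_response(bank, c))
            assert abs(circ_diff(got, c)) < 1e-6
        # generic colors carry a small, bounded aliasing bias
        grid = np.arange(0.0, 360.0, 0.25)
        err = np.abs(circ_diff(population_vector_decode(bank.response(grid)), grid))
        assert err.max() < 1.0

    def test_scale_invariance(self):
        z = tuning_response(TuningBank(), 211.0)
        assert population_vector_decode(3.7 * z) == pytest.approx(
            population_vector_decode(z))

    def test_antipodal_pattern_has_no_angle(self):
        bank = TuningBank()
        z = tuning_response(bank, 40.0) + tuning_response(bank, 220.0)
        with pytest.raises(ValueError):
            population_vector_decode(z)


class TestOutputColor:
    def test_constant_readout_decodes_like_constant(self):
        bank = TuningBank()
        sched = EpochSchedule(delay_ms=0.0)
        # 315 deg is on the aliasing-free grid (multiple of 15); generic
        # colors such as 310 carry the small harmonic-12 bias
        z = np.tile(tuning_response(bank, 315.0), (2, sched.n_steps, 1))
        from wmring.rnn_core import Trajectory
        traj = Trajectory(x=np.zeros((2, sched.n_steps, 1)), z=z,
                          schedules=[sched, sched])
        assert np.allclose(output_color(traj), 315.0, atol=1e-6)
        z310 = np.tile(tuning_response(bank, 310.0), (1, sched.n_steps, 1))
        traj310 = Trajectory(x=np.zeros((1, sched.n_steps, 1)), z=z310,
                             schedules=[sched])
        assert np.allclose(output_color(traj310), 310.0, atol=1.0)

    def test_window_uses_steps_three_to_seven_of_response(self):
        bank = TuningBank()
        sched = EpochSchedule(delay_ms=0.0)
        g = sched.boundaries[3]
        z = np.zeros((1, sched.n_steps, 12))
        z[0, g + 3:g + 7] = tuning_response(bank, 120.0)  # inside [60,140) ms
        z[0, g] = tuning_response(bank, 220.0)            # outside the window
        z[0, g + 7] = tuning_response(bank, 220.0)
        from wmring.rnn_core import Trajectory
        traj = Trajectory(x=np.zeros((1, sched.n_steps, 1)), z=z,
                          schedules=[sched])
        assert np.allclose(response_window_mean(traj)[0],
                           tuning_response(bank, 120.0))
        assert output_color(traj)[0] == pytest.approx(120.0, abs=1e-6)
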