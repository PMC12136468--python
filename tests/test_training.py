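import numpy as np
import pytest

from wmring.rnn_core import rollout
from wmring.task_env import (EnvironmentPrior, EpochSchedule, NoiseConfig,
                             TuningBank, build_trials)
from wmring.training import (PARAM_KEYS, StageConfig, TrainConfig, _forward_backward,
                             default_stages, init_params, loss, progressive_train,
                             train_stage)


def tiny_batch(n_trials=3, delay=100.0, sigma_x=0.1, rng=0):
    sched = EpochSchedule(fixation_ms=40.0, perception_ms=60.0, delay_ms=delay,
                          go_ms=60.0, response_ms=200.0)
    return build_trials(EnvironmentPrior(uniform=True), TuningBank(), sched,
                        n_trials, NoiseConfig(sigma_x, 0.2), rng=rng)


class TestLoss:
    def test_perfect_output_no_regularization_is_zero(self):
        p = init_params(8, rng=0)
        b = tiny_batch()
        traj = rollout(p, b, noise_on=False)
        assert loss(traj, traj.z, b.mask, p, 0.0, 0.0,
                    trial_lengths=b.trial_lengths()) == pytest.approx(0.0)

    def test_zero_mask_kills_everything(self):
        p = init_params(8, rng=0)
        b = tiny_batch()
        traj = rollout(p, b, noise_on=False)
        z = np.zeros_like(traj.z)
        assert loss(traj, b.targets, z[:, :, 0] * 0.0, p, 1.0, 1.0,
                    trial_lengths=b.trial_lengths()) == 0.0

    def test_matches_hand_computed_example(self):
        """Two steps, two units: evaluate the masked loss with plain python
        arithmetic as an independent oracle."""
        n, T, m_out = 2, 2, 2
        w_rec = np.array([[0.0, 0.3], [-0.2, 0.0]])
        p_obj = init_params(n, rng=0, bank=TuningBank(n_units=m_out))
        p_obj.w_rec[:] = w_rec
        z = np.array([[[0.5, -0.2], [0.1, 0.4]]])        # (1, 2, 2)
        ztilde = np.array([[[0.0, 0.0], [1.0, 0.0]]])
        rates = np.array([[[0.2, -0.5], [0.6, 0.1]]])
        mask = np.array([[0.0, 1.0]])
        beta, gamma = 0.25, 0.5
        # manual: only t=1 contributes; T_tot = 2, N = 2
        sq = (0.1 - 1.0) ** 2 + 0.4 ** 2
        rate_pen = (gamma / n) * ((0.6 + 1) ** 2 + (0.1 + 1) ** 2)
        w_pen = (beta / n) * T * np.sum(w_rec ** 2)
        expected = (sq + rate_pen + w_pen) / T
        got = loss(z, ztilde, mask, p_obj, beta, gamma, rates=rates)
        assert got == pytest.approx(expected, rel=1e-12)


class TestGradients:
    def test_bptt_matches_finite_differences(self):
        p = init_params(10, rng=2)
        b = tiny_batch(4, delay=60.0, sigma_x=0.05, rng=1)
        beta, gamma = 1e-3, 2e-3
        rng = np.random.default_rng(0)
        lv, grads = _forward_backward(p, b, False, beta, gamma, rng,
                                      dtype=np.float64)

        def f():
            traj = rollout(p, b, noise_on=False)
            return loss(traj, b.targets, b.mask, p, beta, gamma,
                        trial_lengths=b.trial_lengths())

        assert lv == pytest.approx(f(), rel=1e-9)
        check_rng = np.random.default_rng(7)
        h = 1e-6
        for key in PARAM_KEYS:
            arr = getattr(p, key)
            for _ in range(4):
                idx = tuple(check_rng.integers(0, s) for s in arr.shape)
                if key == "w_rec" and len(set(idx)) == 1:
                    continue
                orig = arr[idx]
                arr[idx] = orig + h
                up = f()
                arr[idx] = orig - h
                dn = f()
                arr[idx] = orig
                fd = (up - dn) / (2 * h)
                assert grads[key][idx] == pytest.approx(fd, rel=2e-4, abs=1e-9)


class TestStages:
    def test_zero_learning_rate_leaves_parameters_unchanged(self):
        p = init_params(12, rng=0)
        before = {k: getattr(p, k).copy() for k in PARAM_KEYS}
        stage = StageConfig(5, EnvironmentPrior(uniform=True), lr=0.0,
                            batch_size=8)
        p, _ = train_stage(p, stage, EpochSchedule(delay_ms=0.0), TuningBank(),
                           np.random.default_rng(0))
        for k in PARAM_KEYS:
            assert np.array_equal(before[k], getattr(p, k))

    def test_stage_is_deterministic_given_seed(self):
        stage = StageConfig(15, EnvironmentPrior(uniform=True), batch_size=16)
        outs = []
        for _ in range(2):
            p = init_params(12, rng=0)
            p, _ = train_stage(p, stage, EpochSchedule(delay_ms=0.0),
                               TuningBank(), np.random.default_rng(3))
            outs.append(p.w_rec.copy())
        assert np.array_equal(outs[0], outs[1])

    def test_diagonal_zero_after_training(self):
        p = init_params(12, rng=0)
        stage = StageConfig(10, EnvironmentPrior(uniform=True), batch_size=8)
        p, _ = train_stage(p, stage, EpochSchedule(delay_ms=0.0), TuningBank(),
                           np.random.default_rng(1))
        assert np.all(np.diag(p.w_rec) == 0.0)

    def test_first_stage_learns_the_zero_delay_task(self):
        """Stage-1 replica at reduced scale drives the loss below 10% of its
        initial value (smoke bar for the optimization path)."""
        p = init_params(48, rng=0)
        stage = StageConfig(800, EnvironmentPrior(uniform=True), noise_on=False,
                            delay_ms=0.0, batch_size=64, lr=2e-3)
        p, log = train_stage(p, stage, EpochSchedule(delay_ms=0.0), TuningBank(),
                             np.random.default_rng(0))
        assert np.mean(log["losses"][-20:]) < 0.1 * log["initial"]


class TestProtocol:
    def test_label_follows_final_prior(self):
        stages = tuple(StageConfig(2, s.prior, noise_on=s.noise_on,
                                   delay_ms=0.0, batch_size=4, lr=1e-4)
                       for s in default_stages(EnvironmentPrior(sigma_s=12.5)))
        cfg = TrainConfig(stages=stages, n_rec=8)
        assert progressive_train(cfg, 0).label == "biased"
        stages_u = stages[:-1] + (StageConfig(2, EnvironmentPrior(uniform=True),
                                              delay_ms=0.0, batch_size=4, lr=1e-4),)
        assert progressive_train(TrainConfig(stages=stages_u, n_rec=8), 0).label \
            == "uniform"

    def test_shared_pretrained_checkpoint_reproduces_final_stage(self):
        stages = tuple(StageConfig(3, s.prior, noise_on=s.noise_on,
                                   delay_ms=0.0, batch_size=4, lr=1e-3)
                       for s in default_stages(EnvironmentPrior(sigma_s=12.5)))
        cfg = TrainConfig(stages=stages, n_rec=8)
        full, pre = progressive_train(cfg, 5, return_pretrained=True)
        resumed = progressive_train(cfg, 5, pretrained=pre.params)
        assert np.array_equal(full.params.w_rec, resumed.params.w_rec)

    def test_empty_stage_list_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(stages=())
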