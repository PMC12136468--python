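import numpy as np
import pytest
from scipy import stats

from wmring.circular import circ_diff, wrap_360
from wmring.task_env import (COMMON_COLORS, EnvironmentPrior, EpochSchedule,
                             NoiseConfig, TuningBank, build_trials, sample_prior,
                             tuning_response)


class TestPrior:
    @pytest.mark.parametrize("sigma", [3.0, 10.0, 12.5, 17.5, 25.0, 90.0])
    def test_density_normalizes(self, sigma):
        grid = np.linspace(0.0, 360.0, 72001)
        p = EnvironmentPrior(sigma_s=sigma)
        assert np.trapezoid(p.density(grid), grid) == pytest.approx(1.0, abs=1e-6)

    def test_uniform_flag_density_and_samples(self):
        p = EnvironmentPrior(uniform=True)
        assert np.allclose(p.density([0.0, 123.4]), 1.0 / 360.0)
        x = sample_prior(p, 100_000, rng=0)
        ks = stats.kstest(x / 360.0, "uniform").statistic
        assert ks < 0.01

    def test_biased_density_has_four_modes(self):
        grid = np.arange(0.0, 360.0, 0.5)
        d = EnvironmentPrior(sigma_s=25.0).density(grid)
        prev, nxt = np.roll(d, 1), np.roll(d, -1)
        modes = grid[(d > prev) & (d > nxt)]
        assert len(modes) == 4
        assert np.allclose(sorted(modes), COMMON_COLORS, atol=1.0)

    def test_narrow_prior_concentrates_on_common_colors(self):
        p = EnvironmentPrior(sigma_s=3.0)
        # analytic mass of the four +-15 degree arcs
        grid = np.linspace(0.0, 360.0, 144001)
        d = p.density(grid)
        near = np.min(np.abs(circ_diff(grid[:, None], np.array(COMMON_COLORS))),
                      axis=1) <= 15.0
        mass = np.trapezoid(d * near, grid)
        assert mass > 0.999
        x = sample_prior(p, 10_000, rng=1)
        frac = np.mean(np.min(np.abs(circ_diff(x[:, None],
                                               np.array(COMMON_COLORS))),
                              axis=1) <= 15.0)
        assert frac >= 0.99

    def test_sampling_is_seed_reproducible(self):
        p = EnvironmentPrior(sigma_s=12.5)
        assert np.array_equal(sample_prior(p, 500, rng=7), sample_prior(p, 500, rng=7))

    def test_invalid_width_rejected(self):
        with pytest.raises(ValueError):
            EnvironmentPrior(sigma_s=-1.0)
        with pytest.raises(ValueError):
            sample_prior(EnvironmentPrior(), 0, rng=0)


class TestTuning:
    def test_peak_at_preferred_color(self):
        bank = TuningBank()
        assert np.argmax(tuning_response(bank, 0.0)) == 0
        assert np.argmax(tuning_response(bank, 90.0)) == 3

    def test_rotation_equivariance(self):
        bank = TuningBank()
        # one unit spacing (30 deg) cyclically permutes the pattern exactly
        assert np.allclose(tuning_response(bank, 70.0),
                           np.roll(tuning_response(bank, 40.0), 1), atol=1e-12)

    def test_sum_over_units_nearly_constant(self):
        # equal spacing cancels all circular harmonics except multiples of 12;
        # at sigma_p = 15 deg the residual harmonic leaves a ~3% ripple, and
        # shifting by exactly one unit spacing leaves the sum invariant
        bank = TuningBank()
        grid = np.arange(0.0, 360.0, 1.0)
        sums = bank.response(grid).sum(axis=1)
        assert (sums.max() - sums.min()) / sums.mean() < 0.04
        assert np.allclose(bank.response(grid).sum(axis=1),
                           bank.response(grid + 30.0).sum(axis=1), atol=1e-9)
        assert np.all(sums > 0)


class TestSchedule:
    def test_boundaries_and_window(self):
        s = EpochSchedule(delay_ms=800.0)
        f, p, d, g, t = s.boundaries
        assert (f, p, d, g, t) == (5, 15, 55, 58, 68)
        lo, hi = s.response_window
        # [60, 140) ms inside the response epoch -> 4 steps at dt = 20 ms
        assert (lo, hi) == (g + 3, g + 7)

    def test_invalid_durations_rejected(self):
        with pytest.raises(ValueError):
            EpochSchedule(delay_ms=-20.0)
        with pytest.raises(ValueError):
            EpochSchedule(perception_ms=130.0)  # not a multiple of dt
        with pytest.raises(ValueError):
            EpochSchedule(response_ms=100.0).response_window


class TestBuildTrials:
    def test_noiseless_perception_equals_tuning(self):
        bank = TuningBank()
        sched = EpochSchedule(delay_ms=0.0)
        b = build_trials(EnvironmentPrior(), bank, sched, 4,
                         NoiseConfig(0.0, 0.0), rng=0, fixed_color=40.0)
        f, p, d, g, t = sched.boundaries
        expect = tuning_response(bank, 40.0)
        assert np.allclose(b.inputs[:, f:p, :12], expect[None, None, :])
        assert np.all(b.inputs[:, :, :12][:, p:] == 0)  # silent after perception
        # go channel: 1 only during the go epoch
        go = b.inputs[:, :, 12]
        assert np.all(go[:, d:g] == 1) and go.sum() == 4 * (g - d)
        # targets: tuning pattern only in response
        assert np.allclose(b.targets[:, g:t], expect[None, None, :])
        assert np.all(b.targets[:, :g] == 0)

    def test_mask_covers_everything_but_fixation(self):
        sched = EpochSchedule(delay_ms=400.0)
        b = build_trials(EnvironmentPrior(), TuningBank(), sched, 8,
                         NoiseConfig(), rng=2)
        T = sched.n_steps
        assert np.all(b.mask.sum(axis=1) == T - sched.fixation_steps)
        assert np.all(b.noise_mask[:, :sched.fixation_steps] == 0)

    def test_per_trial_delay_distribution_uniform(self):
        sched = EpochSchedule()
        b = build_trials(EnvironmentPrior(), TuningBank(), sched, 2000,
                         NoiseConfig(), rng=3, delay_range_ms=(0, 1000))
        steps = np.array([s.delay_steps for s in b.schedules])
        counts = np.bincount(steps, minlength=51)
        assert counts.size == 51
        p = stats.chisquare(counts).pvalue
        assert p > 0.01

    def test_seed_reproducibility(self):
        args = (EnvironmentPrior(sigma_s=12.5), TuningBank(), EpochSchedule())
        a = build_trials(*args, 16, NoiseConfig(), rng=11)
        b = build_trials(*args, 16, NoiseConfig(), rng=11)
        assert np.array_equal(a.inputs, b.inputs)
        assert np.array_equal(a.input_colors, b.input_colors)


class TestSerialization:
    def test_trialbatch_roundtrip(self, tmp_path):
        from wmring.task_env import TrialBatch
        b = build_trials(EnvironmentPrior(sigma_s=12.5), TuningBank(),
                         EpochSchedule(), 5, NoiseConfig(), rng=4,
                         delay_range_ms=(0, 400))
        path = tmp_path / "batch.npz"
        b.save(path)
        b2 = TrialBatch.load(path)
        assert np.array_equal(b.inputs, b2.inputs)
        assert np.array_equal(b.mask, b2.mask)
        assert [s.delay_ms for s in b.schedules] == \
            [s.delay_ms for s in b2.schedules]

    def test_toml_config_overrides_defaults(self, tmp_path):
        from wmring.config import load_task_config
        cfg = tmp_path / "task.toml"
        cfg.write_text("""
[prior]
sigma_s = 17.5

[tuning]
sigma_p = 20.0

[schedule]
delay_ms = 400.0

[noise]
sigma_x = 0.1
""")
        prior, bank, schedule, noise = load_task_config(cfg)
        assert prior.sigma_s == 17.5 and not prior.uniform
        assert bank.sigma_p == 20.0
        assert schedule.delay_steps == 20
        assert noise.sigma_x == 0.1 and noise.sigma_rec == 0.2
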