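"""Masked-loss training of the task RNN: BPTT gradients, Adam, and the
four-stage progressive protocol producing Pretrained, Uniform, and Biased
networks.

The loss per trial is

    L = (1/T) sum_t m_t [ |z_t - z~_t|^2
                          + (1/N)( beta T |W_rec|_F^2 + gamma |r_t + 1|^2 ) ]

averaged over the batch, where m_t masks out the fixation epoch, the readout
target z~ is zero outside the response epoch and the noiseless tuning pattern
inside it, and the rate penalty pulls firing rates toward -1 (silence for tanh
units). Gradients are exact backpropagation-through-time through the realized
noise; the recurrent diagonal is re-zeroed after every update (no
self-connections). Gradients are clipped to global norm 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .rnn_core import NetworkParams, Trajectory
from .task_env import (EnvironmentPrior, EpochSchedule, NoiseConfig, TrialBatch,
                       TuningBank, build_trials)

PARAM_KEYS = ("w_rec", "w_in", "b", "w_out", "b_out")


def init_params(n_rec: int = 64, rng=0, alpha: float = 1.0, dt_ms: float = 20.0,
                sigma_rec: float = 0.2, sigma_x: float = 0.2,
                bank: TuningBank = TuningBank()) -> NetworkParams:
    """Random initial network: Gaussian recurrent weights at gain 1/sqrt(N)."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n_in = bank.n_units + 1
    w_rec = rng.standard_normal((n_rec, n_rec)) / np.sqrt(n_rec)
    w_in = rng.standard_normal((n_rec, n_in)) / np.sqrt(n_in)
    w_out = rng.standard_normal((bank.n_units, n_rec)) * (0.1 / np.sqrt(n_rec))
    return NetworkParams(w_rec, w_in, np.zeros(n_rec), w_out,
                         np.zeros(bank.n_units), alpha=alpha, dt_ms=dt_ms,
                         sigma_rec=sigma_rec, sigma_x=sigma_x)


def loss(traj_or_z, targets, mask, params: NetworkParams,
         beta: float = 0.0, gamma: float = 0.0, rates: np.ndarray | None = None,
         trial_lengths: np.ndarray | None = None) -> float:
    """Masked loss of a rolled-out batch (scalar, batch-averaged)."""
    z = traj_or_z.z if isinstance(traj_or_z, Trajectory) else np.asarray(traj_or_z)
    if rates is None:
        if not isinstance(traj_or_z, Trajectory):
            raise ValueError("rates required when passing raw readouts")
        rates = traj_or_z.r
    B, T, _ = z.shape
    if trial_lengths is None:
        trial_lengths = np.full(B, T)
    t_tot = trial_lengths.astype(float)[:, None]          # (B, 1)
    n = params.n_rec
    per_step = (np.sum((z - targets) ** 2, axis=-1)
                + (gamma / n) * np.sum((rates + 1.0) ** 2, axis=-1)
                + (beta / n) * t_tot * np.sum(params.w_rec ** 2))
    return float(np.mean(np.sum(mask * per_step / t_tot, axis=1)))


def _forward_backward(params: NetworkParams, batch: TrialBatch, noise_on: bool,
                      beta: float, gamma: float, rng,
                      dtype=np.float32) -> tuple[float, dict]:
    """Loss and exact BPTT gradients for one batch.

    Runs in float32 for speed (weights are kept in float64 by the optimizer);
    the realized noise is treated as data so the gradient is exact for the
    sampled trajectory.
    """
    B, T, _ = batch.inputs.shape
    N = params.n_rec
    alpha = dtype(params.alpha)
    u = batch.inputs.astype(dtype)
    targets = batch.targets.astype(dtype)
    w_rec = params.w_rec.astype(dtype)
    w_in = params.w_in.astype(dtype)
    w_out = params.w_out.astype(dtype)
    b = params.b.astype(dtype)
    b_out = params.b_out.astype(dtype)

    if noise_on and params.sigma_rec > 0:
        coef = np.sqrt(2.0 * params.sigma_rec**2 / params.alpha)
        noise = (coef * batch.noise_mask[:, :, None]
                 * rng.standard_normal((B, T, N))).astype(dtype)
    else:
        noise = None

    # input drive for every step in one matmul; the recurrence stays sequential
    drive_in = (u.reshape(B * T, -1) @ w_in.T + b).reshape(B, T, N)
    if noise is not None:
        drive_in += noise
    rs = np.empty((B, T, N), dtype=dtype)
    x = np.zeros((B, N), dtype=dtype)
    r_prev = np.zeros((B, N), dtype=dtype)
    w_rec_t = np.ascontiguousarray(w_rec.T)
    for t in range(T):
        x = (1 - alpha) * x + alpha * (r_prev @ w_rec_t + drive_in[:, t])
        r_prev = np.tanh(x)
        rs[:, t] = r_prev
    rs2 = rs.reshape(B * T, N)
    zs = rs2 @ w_out.T + b_out
    if not np.all(np.isfinite(zs)):
        raise FloatingPointError("NaN/Inf in training rollout")
    resid = zs - targets.reshape(B * T, -1)

    t_tot = batch.trial_lengths().astype(dtype)
    c = (batch.mask.astype(dtype) / (t_tot[:, None] * B)).reshape(B * T, 1)
    ct_sum = float(np.sum(c.reshape(B, T) * t_tot[:, None]))
    loss_val = (float(np.sum(c * resid**2))
                + (gamma / N) * float(np.sum(c * (rs2 + 1.0) ** 2))
                + (beta / N) * float(np.sum(params.w_rec**2)) * ct_sum)

    g = (2.0 * c * resid).astype(dtype)                   # dL/dz
    grads = {"w_out": g.T @ rs2, "b_out": g.sum(axis=0)}
    rho = g @ w_out + dtype(2.0 * gamma / N) * c * (rs2 + 1)
    rho3 = rho.reshape(B, T, N)

    adj = np.empty((B, T, N), dtype=dtype)                # dL/dx_t
    a_next = np.zeros((B, N), dtype=dtype)
    for t in range(T - 1, -1, -1):
        dr = rho3[:, t] + alpha * (a_next @ w_rec)
        a_next = (1 - rs[:, t] ** 2) * dr + (1 - alpha) * a_next
        adj[:, t] = a_next
    adj2 = adj.reshape(B * T, N)
    # dW_rec = sum_t a_t (x) r_{t-1}: shift rates by one step (r at t=0 is 0)
    r_shift = np.empty_like(rs)
    r_shift[:, 0] = 0.0
    r_shift[:, 1:] = rs[:, :-1]
    d_w_rec = alpha * (adj2.T @ r_shift.reshape(B * T, N))
    d_w_in = alpha * (adj2.T @ u.reshape(B * T, -1))
    d_b = alpha * adj2.sum(axis=0)
    d_w_rec += dtype((2.0 * beta / N) * ct_sum) * w_rec
    np.fill_diagonal(d_w_rec, 0.0)
    grads.update(w_rec=d_w_rec, w_in=d_w_in, b=d_b)
    grads = {k: v.astype(np.float64) for k, v in grads.items()}
    return float(loss_val), grads


class Adam:
    """Plain Adam over the parameter dict; deterministic given the data stream."""

    def __init__(self, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m, self.v, self.t = {}, {}, 0

    def update(self, params: NetworkParams, grads: dict, clip_norm: float = 1.0):
        if clip_norm is not None:
            total = np.sqrt(sum(np.sum(grads[k] ** 2) for k in PARAM_KEYS))
            if total > clip_norm:
                grads = {k: grads[k] * (clip_norm / total) for k in PARAM_KEYS}
        self.t += 1
        for k in PARAM_KEYS:
            gk = grads[k]
            self.m[k] = self.beta1 * self.m.get(k, 0.0) + (1 - self.beta1) * gk
            self.v[k] = self.beta2 * self.v.get(k, 0.0) + (1 - self.beta2) * gk**2
            mhat = self.m[k] / (1 - self.beta1**self.t)
            vhat = self.v[k] / (1 - self.beta2**self.t)
            p = getattr(params, k)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
        np.fill_diagonal(params.w_rec, 0.0)


@dataclass(frozen=True)
class StageConfig:
    """One stage of the progressive protocol."""
    n_updates: int
    prior: EnvironmentPrior
    noise_on: bool = False
    beta: float = 0.0
    gamma: float = 0.0
    delay_range_ms: tuple | None = None     # None -> fixed delay below
    delay_ms: float = 0.0
    batch_size: int = 64
    lr: float = 2e-3
    # one delay per batch (padding-free) rather than per trial; across updates
    # the delay distribution is the same uniform grid either way
    delay_shared: bool = True
    # ramp the upper delay bound linearly from ~dt to its final value over the
    # first half of the stage (a within-stage curriculum easing the jump from
    # zero-delay training to second-long delays)
    delay_ramp: bool = False


@dataclass(frozen=True)
class TrainConfig:
    """Full progressive protocol: the four stages plus shared settings."""
    stages: tuple
    n_rec: int = 64
    sigma_rec: float = 0.2
    sigma_x: float = 0.2
    schedule: EpochSchedule = EpochSchedule(delay_ms=0.0)
    bank: TuningBank = TuningBank()

    def __post_init__(self):
        if len(self.stages) == 0:
            raise ValueError("stage list must be nonempty")
        for st in self.stages:
            if st.beta < 0 or st.gamma < 0:
                raise ValueError("regularization coefficients must be >= 0")


@dataclass
class TrainedModel:
    params: NetworkParams
    config: TrainConfig
    label: str                     # pretrained | uniform | biased
    final_loss: float
    stage_history: list = field(default_factory=list)


def train_stage(params: NetworkParams, stage: StageConfig, schedule: EpochSchedule,
                bank: TuningBank, rng) -> tuple[NetworkParams, dict]:
    """Run one stage of Adam updates; returns updated params and a loss log."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    opt = Adam(lr=stage.lr)
    noise = NoiseConfig(sigma_x=params.sigma_x if stage.noise_on else 0.0,
                        sigma_rec=params.sigma_rec)
    sched = replace(schedule, delay_ms=stage.delay_ms)
    losses = []
    for k in range(stage.n_updates):
        if stage.delay_range_ms is not None and stage.delay_shared:
            lo, hi = stage.delay_range_ms
            if stage.delay_ramp:
                frac = min(1.0, 2.0 * (k + 1) / max(stage.n_updates, 1))
                hi = lo + frac * (hi - lo)
            lo_s = int(round(lo / sched.dt_ms))
            hi_s = int(round(hi / sched.dt_ms))
            d = int(rng.integers(lo_s, hi_s + 1)) * sched.dt_ms
            batch = build_trials(stage.prior, bank, sched.with_delay(d),
                                 stage.batch_size, noise, rng=rng)
        else:
            batch = build_trials(stage.prior, bank, sched, stage.batch_size, noise,
                                 rng=rng, delay_range_ms=stage.delay_range_ms)
        lv, grads = _forward_backward(params, batch, stage.noise_on,
                                      stage.beta, stage.gamma, rng)
        if not np.isfinite(lv):
            raise FloatingPointError(f"NaN loss at update {len(losses)}")
        if stage.n_updates > 0 and stage.lr > 0:
            opt.update(params, grads)
        losses.append(lv)
    assert np.all(np.diag(params.w_rec) == 0.0)
    return params, {"losses": losses,
                    "initial": losses[0] if losses else np.nan,
                    "final": losses[-1] if losses else np.nan}


def default_stages(final_prior: EnvironmentPrior,
                   updates=(800, 1500, 800, 1200), batch_size=64,
                   beta=1e-4, gamma=1e-4, lr=2e-3, lr_late=1e-3) -> tuple:
    """The four-stage progressive protocol: (1) no noise/reg, uniform prior,
    delay 0; (2) variable delay (ramped within the stage); (3) + noise +
    regularization -> pretrained; (4) retrain under the final prior. The
    noisy stages use a lower learning rate."""
    uni = EnvironmentPrior(uniform=True)
    return (
        StageConfig(updates[0], uni, noise_on=False, delay_ms=0.0,
                    batch_size=batch_size, lr=lr),
        StageConfig(updates[1], uni, noise_on=False, delay_range_ms=(0, 1000),
                    batch_size=batch_size, lr=lr, delay_ramp=True),
        StageConfig(updates[2], uni, noise_on=True, beta=beta, gamma=gamma,
                    delay_range_ms=(0, 1000), batch_size=batch_size, lr=lr_late),
        StageConfig(updates[3], final_prior, noise_on=True, beta=beta, gamma=gamma,
                    delay_range_ms=(0, 1000), batch_size=batch_size, lr=lr_late),
    )


def progressive_train(config: TrainConfig, rng_seed: int,
                      pretrained: NetworkParams | None = None,
                      return_pretrained: bool = False):
    """Train through the staged protocol.

    Stages before the last produce the "pretrained" checkpoint (prior-agnostic);
    the final stage retrains under the final prior. Passing ``pretrained``
    (params, or a (params, start_stage) tuple for an earlier checkpoint) skips
    the already-trained stages, which is how ensembles over priors or noise
    levels share their upstream training. The label is "uniform" iff the final
    prior is the uniform environment, else "biased".
    """
    n_stages = len(config.stages)
    history = []
    # one independent, seed-derived rng stream per stage, so runs that resume
    # from a cached checkpoint reproduce the from-scratch stage data exactly
    stage_rng = lambda i: np.random.default_rng([rng_seed, 1000 + i])
    if pretrained is None:
        params = init_params(config.n_rec, np.random.default_rng([rng_seed, 999]),
                             sigma_rec=config.sigma_rec, sigma_x=config.sigma_x,
                             bank=config.bank)
        start = 0
    else:
        params = pretrained[0].copy() if isinstance(pretrained, tuple) else pretrained.copy()
        start = pretrained[1] if isinstance(pretrained, tuple) else n_stages - 1
        # the checkpoint may have been produced under a different noise
        # configuration (noise-free early stages are shared across levels)
        params.sigma_rec = config.sigma_rec
        params.sigma_x = config.sigma_x
    pre = None
    for i in range(start, n_stages):
        params, log = train_stage(params, config.stages[i], config.schedule,
                                  config.bank, stage_rng(i))
        history.append(log)
        if i == n_stages - 2:
            pre = params.copy()
    final_stage = config.stages[-1]
    label = "uniform" if final_stage.prior.uniform else "biased"
    model = TrainedModel(params, config, label, history[-1]["final"], history)
    if return_pretrained:
        pre_model = TrainedModel(pre if pre is not None else model.params.copy(),
                                 config, "pretrained",
                                 history[-2]["final"] if len(history) > 1 else np.nan,
                                 history[:-1])
        return model, pre_model
    return model


def train_ensemble(final_priors: dict, n_models: int, base_seed: int = 0,
                   n_rec: int = 64, sigma: float = 0.2,
                   updates=(800, 1500, 800, 1200), lr=2e-3,
                   beta=1e-4, gamma=1e-4, progress=None) -> dict:
    """Train ``n_models`` seeds, sharing the pretrained checkpoint per seed
    across all final priors (same trial budget per final model, as the uniform
    and biased conditions must consume identical numbers of trials).

    ``final_priors`` maps label -> EnvironmentPrior. Returns
    {label: [TrainedModel, ...]}.
    """
    out = {k: [] for k in final_priors}
    for i in range(n_models):
        seed = base_seed + i
        pre = None
        for label, prior in final_priors.items():
            cfg = TrainConfig(stages=default_stages(prior, updates=updates,
                                                    beta=beta, gamma=gamma, lr=lr),
                              n_rec=n_rec, sigma_rec=sigma, sigma_x=sigma)
            if pre is None:
                model, pre_model = progressive_train(cfg, seed, return_pretrained=True)
                pre = pre_model.params
            else:
                model = progressive_train(cfg, seed, pretrained=pre)
            out[label].append(model)
            if progress is not None:
                progress(label, i)
    return out


def train_noise_sweep(noise_levels, final_prior: EnvironmentPrior, n_models: int,
                      base_seed: int = 0, n_rec: int = 64,
                      updates=(800, 1500, 800, 1200), lr=2e-3,
                      beta=1e-4, gamma=1e-4) -> dict:
    """Ensembles across noise levels sigma = sigma_x = sigma_rec.

    The first two (noise-free) stages are shared per seed across levels; the
    noisy stages are retrained per level. Returns {sigma: [TrainedModel, ...]}.
    """
    out = {nz: [] for nz in noise_levels}
    for i in range(n_models):
        seed = base_seed + i
        stages = default_stages(final_prior, updates=updates, beta=beta,
                                gamma=gamma, lr=lr)
        cfg2 = TrainConfig(stages=stages[:2], n_rec=n_rec)
        ckpt2 = progressive_train(cfg2, seed).params
        for nz in noise_levels:
            cfg = TrainConfig(stages=stages, n_rec=n_rec, sigma_rec=nz, sigma_x=nz)
            out[nz].append(progressive_train(cfg, seed, pretrained=(ckpt2, 2)))
    return out
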