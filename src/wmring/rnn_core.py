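"""Discrete-time noisy tanh RNN: dynamics, linear readout, population-vector decode.

The state update is

    x_t = (1 - alpha) x_{t-1} + alpha (W_rec tanh(x_{t-1}) + W_in u_t
                                       + sqrt(2 sigma_rec^2 / alpha) eps_t + b)

with alpha = dt / tau (default 1), zero recurrent diagonal (no
self-connections), readout z_t = W_out tanh(x_t) + b_out, and output color from
the population vector of the readout averaged over the 60-140 ms response
window.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .circular import DEG2RAD, RAD2DEG
from .task_env import EpochSchedule, TrialBatch, TuningBank


@dataclass
class NetworkParams:
    """All trainable weights plus fixed hyperparameters of one RNN."""

    w_rec: np.ndarray   # (N, N), zero diagonal
    w_in: np.ndarray    # (N, 13)
    b: np.ndarray       # (N,)
    w_out: np.ndarray   # (12, N)
    b_out: np.ndarray   # (12,)
    alpha: float = 1.0
    dt_ms: float = 20.0
    sigma_rec: float = 0.2
    sigma_x: float = 0.2

    def __post_init__(self):
        np.fill_diagonal(self.w_rec, 0.0)
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError(f"alpha must lie in (0, 1], got {self.alpha}")

    @property
    def n_rec(self) -> int:
        return self.w_rec.shape[0]

    @property
    def n_in(self) -> int:
        return self.w_in.shape[1]

    @property
    def n_out(self) -> int:
        return self.w_out.shape[0]

    def copy(self) -> "NetworkParams":
        return NetworkParams(self.w_rec.copy(), self.w_in.copy(), self.b.copy(),
                             self.w_out.copy(), self.b_out.copy(), self.alpha,
                             self.dt_ms, self.sigma_rec, self.sigma_x)

    # --- autonomous (delay-condition) dynamics: zero input, no noise ---
    def velocity(self, x: np.ndarray) -> np.ndarray:
        """F(x) = x_next - x under zero input and zero noise; x is (..., N)."""
        r = np.tanh(x)
        return self.alpha * (r @ self.w_rec.T + self.b - x)

    def jacobian(self, x: np.ndarray) -> np.ndarray:
        """Analytic Jacobian of F at a single state x: alpha (W_rec diag(1-r^2) - I)."""
        r = np.tanh(np.asarray(x, dtype=float))
        return self.alpha * (self.w_rec * (1.0 - r**2)[None, :] - np.eye(self.n_rec))

    def speed_grad(self, x: np.ndarray) -> np.ndarray:
        """Gradient of |F(x)|^2 wrt x, batched over leading axes: 2 J(x)^T F(x)."""
        r = np.tanh(x)
        f = self.alpha * (r @ self.w_rec.T + self.b - x)
        return 2.0 * self.alpha * ((1.0 - r**2) * (f @ self.w_rec) - f)

    # --- serialization: npz archive + JSON manifest ---
    def save(self, path):
        meta = dict(alpha=self.alpha, dt_ms=self.dt_ms, sigma_rec=self.sigma_rec,
                    sigma_x=self.sigma_x, n_rec=self.n_rec)
        np.savez(path, w_rec=self.w_rec, w_in=self.w_in, b=self.b,
                 w_out=self.w_out, b_out=self.b_out,
                 manifest=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8))

    @classmethod
    def load(cls, path) -> "NetworkParams":
        d = np.load(path)
        meta = json.loads(bytes(d["manifest"]).decode())
        return cls(d["w_rec"], d["w_in"], d["b"], d["w_out"], d["b_out"],
                   alpha=meta["alpha"], dt_ms=meta["dt_ms"],
                   sigma_rec=meta["sigma_rec"], sigma_x=meta["sigma_x"])


@dataclass
class Trajectory:
    """One rollout: pre-activation states x, rates r = tanh(x), readouts z."""

    x: np.ndarray        # (B, T, N)
    z: np.ndarray        # (B, T, 12)
    schedules: list
    input_colors: np.ndarray | None = None

    @property
    def r(self) -> np.ndarray:
        return np.tanh(self.x)

    def states_at(self, which: str) -> np.ndarray:
        """States at a named epoch boundary: end_of_delay | start_of_delay |
        end_of_go | start_of_response (the last two coincide)."""
        idx = []
        for s in self.schedules:
            f, p, d, g, t = s.boundaries
            idx.append({"start_of_delay": p, "end_of_delay": d,
                        "end_of_go": g, "start_of_response": g}[which])
        # state AFTER the last step of the epoch = x[t-1] with half-open [start, end)
        return np.stack([self.x[i, j - 1] for i, j in enumerate(idx)])


def step(params: NetworkParams, x_prev: np.ndarray, u_t: np.ndarray,
         noise_eps: np.ndarray | None = None) -> np.ndarray:
    """One dynamics step; ``noise_eps`` is a standard-normal draw or None."""
    r = np.tanh(x_prev)
    drive = r @ params.w_rec.T + u_t @ params.w_in.T + params.b
    if noise_eps is not None:
        drive = drive + np.sqrt(2.0 * params.sigma_rec**2 / params.alpha) * noise_eps
    x = (1.0 - params.alpha) * x_prev + params.alpha * drive
    if not np.all(np.isfinite(x)):
        raise FloatingPointError("non-finite state produced by dynamics step")
    return x


def rollout(params: NetworkParams, batch: TrialBatch, noise_on: bool = True,
            init_state: np.ndarray | None = None, rng=0,
            store_states: bool = True) -> Trajectory:
    """Run the network over a trial batch.

    ``init_state`` overrides the zero initial condition (shape (N,) or (B, N));
    combined with a batch restricted to selected epochs this supports the RNN
    decoder and cross-decoding splices.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    B, T, _ = batch.inputs.shape
    N = params.n_rec
    if init_state is None:
        x = np.zeros((B, N))
    else:
        init_state = np.asarray(init_state, dtype=float)
        if init_state.ndim == 1:
            if init_state.shape[0] != N:
                raise ValueError(f"init_state has dim {init_state.shape[0]}, expected {N}")
            x = np.tile(init_state, (B, 1))
        else:
            if init_state.shape != (B, N):
                raise ValueError(f"init_state shape {init_state.shape}, expected {(B, N)}")
            x = init_state.copy()

    xs = np.empty((B, T, N)) if store_states else None
    zs = np.empty((B, T, params.n_out))
    coef = np.sqrt(2.0 * params.sigma_rec**2 / params.alpha)
    for t in range(T):
        r = np.tanh(x)
        drive = r @ params.w_rec.T + batch.inputs[:, t] @ params.w_in.T + params.b
        if noise_on and params.sigma_rec > 0:
            drive = drive + coef * batch.noise_mask[:, t, None] * rng.standard_normal((B, N))
        x = (1.0 - params.alpha) * x + params.alpha * drive
        if xs is not None:
            xs[:, t] = x
        zs[:, t] = np.tanh(x) @ params.w_out.T + params.b_out
    if not np.all(np.isfinite(zs)):
        raise FloatingPointError("non-finite trajectory")
    return Trajectory(xs if xs is not None else np.empty((B, 0, N)), zs,
                      list(batch.schedules), batch.input_colors)


def population_vector_decode(z_mean: np.ndarray, mu_p: np.ndarray | None = None):
    """Population-vector color: angle of sum_m z_m exp(i mu_m), in [0, 360).

    ``z_mean`` is (..., 12). Raises on a (near-)zero resultant vector.
    """
    z = np.asarray(z_mean, dtype=float)
    if mu_p is None:
        mu_p = TuningBank(n_units=z.shape[-1]).mu_p
    vec = (z * np.exp(1j * mu_p * DEG2RAD)).sum(axis=-1)
    mag = np.abs(vec)
    scale = np.abs(z).sum(axis=-1) + 1e-300
    if np.any(mag / scale < 1e-12):
        raise ValueError("population vector has zero resultant: undefined angle")
    return np.angle(vec) * RAD2DEG % 360.0


def response_window_mean(traj: Trajectory) -> np.ndarray:
    """Mean readout over each trial's 60-140 ms response window: (B, 12)."""
    out = np.empty((traj.z.shape[0], traj.z.shape[-1]))
    for i, s in enumerate(traj.schedules):
        lo, hi = s.response_window
        out[i] = traj.z[i, lo:hi].mean(axis=0)
    return out


def output_color(traj: Trajectory, mu_p: np.ndarray | None = None) -> np.ndarray:
    """Decoded output color per trial (degrees)."""
    return np.atleast_1d(population_vector_decode(response_window_mean(traj), mu_p))


def decoder_batch(schedule: EpochSchedule, n_trials: int,
                  bank: TuningBank = TuningBank()) -> TrialBatch:
    """A go+response-only batch (zero-length fixation/perception/delay) used to
    re-enter the network at an arbitrary recurrent state (the RNN decoder)."""
    from dataclasses import replace
    s = replace(schedule, fixation_ms=0.0, perception_ms=0.0, delay_ms=0.0)
    T = s.n_steps
    inputs = np.zeros((n_trials, T, bank.n_units + 1))
    f, p, d, g, t = s.boundaries
    inputs[:, d:g, bank.n_units] = 1.0
    return TrialBatch(inputs=inputs,
                      targets=np.zeros((n_trials, T, bank.n_units)),
                      mask=np.ones((n_trials, T)),
                      noise_mask=np.ones((n_trials, T)),
                      input_colors=np.full(n_trials, np.nan),
                      schedules=[s] * n_trials, bank=bank)
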