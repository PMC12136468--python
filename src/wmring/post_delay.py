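"""Dissection of the post-delay epochs into go dynamics, response dynamics,
and the non-dynamic readout.

Ring-evolution experiments (uniform rings of states pushed through one epoch),
representative states (time-averaged response-epoch states), the readout
decoder (W_out tanh(x) + b_out followed by the population vector, no
dynamics), coefficient-of-variation bias metrics on 36-binned angular
functions, and the process-isolation ablation in which exactly one of the
three processes runs in the network while the other two are replaced by
uniform angle shifts.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .circular import circ_diff, wrap_360
from .task_env import EpochSchedule, TuningBank
from .rnn_core import NetworkParams, population_vector_decode, rollout
from .state_geometry import Plane, collect_states, fit_plane
from .occupancy_theory import AngleColorMap, angle_color_map


def _epoch_batch(schedule: EpochSchedule, n: int, epoch: str,
                 bank: TuningBank = TuningBank()):
    """A batch containing only the requested epoch (go or response)."""
    from .task_env import TrialBatch
    if epoch == "go":
        s = replace(schedule, fixation_ms=0.0, perception_ms=0.0, delay_ms=0.0,
                    response_ms=0.0)
    elif epoch == "response":
        s = replace(schedule, fixation_ms=0.0, perception_ms=0.0, delay_ms=0.0,
                    go_ms=0.0)
    else:
        raise ValueError(f"unknown epoch {epoch!r}")
    T = s.n_steps
    inputs = np.zeros((n, T, bank.n_units + 1))
    f, p, d, g, t = s.boundaries
    inputs[:, d:g, bank.n_units] = 1.0
    return TrialBatch(inputs=inputs, targets=np.zeros((n, T, bank.n_units)),
                      mask=np.ones((n, T)), noise_mask=np.ones((n, T)),
                      input_colors=np.full(n, np.nan), schedules=[s] * n, bank=bank)


def evolve_states(params: NetworkParams, states: np.ndarray, epoch: str,
                  schedule: EpochSchedule | None = None,
                  time_average: bool = False) -> np.ndarray:
    """Run states through one epoch with noise off; optionally return the
    temporal average over the epoch instead of the final state."""
    sched = schedule or EpochSchedule()
    batch = _epoch_batch(sched, np.atleast_2d(states).shape[0], epoch)
    traj = rollout(params, batch, noise_on=False,
                   init_state=np.atleast_2d(np.asarray(states, dtype=float)))
    if time_average:
        return traj.x.mean(axis=1)
    return traj.x[:, -1]


@dataclass
class RingEvolution:
    """A uniform ring of initial states and where one epoch carries them."""
    initial_angles: np.ndarray    # on the source plane
    final_states: np.ndarray
    final_angles: np.ndarray      # on the target plane
    target_plane: Plane
    histogram: np.ndarray         # 36-bin counts of final angles
    cv: float

    @property
    def n_states(self):
        return self.initial_angles.size


def binned_cv(values_or_angles, n_bins: int = 36, is_angles: bool = True,
              bin_range=(0.0, 360.0)) -> float:
    """Coefficient of variation of a 36-binned angular function: std of the
    bin values divided by their mean. Scale-free by construction."""
    if is_angles:
        f, _ = np.histogram(wrap_360(values_or_angles), bins=n_bins, range=bin_range)
        f = f.astype(float)
    else:
        f = np.asarray(values_or_angles, dtype=float)
        if f.size != n_bins:
            # bin a sampled function f(x) down to n_bins means
            f = f[: (f.size // n_bins) * n_bins].reshape(n_bins, -1).mean(axis=1)
    m = f.mean()
    if m == 0:
        return 0.0
    return float(f.std() / m)


def evolve_go_ring(params: NetworkParams, n_states: int = 1000, rng=0,
                   delay_ms: float = 800.0, n_fit_trials: int = 1000,
                   delay_plane: Plane | None = None) -> RingEvolution:
    """Uniform delay-plane ring evolved through the go epoch (noise off); the
    response plane is fitted on the evolved states and their angle
    distribution is returned."""
    if delay_plane is None:
        states, _ = collect_states(params, n_fit_trials, delay_ms, rng)
        delay_plane = fit_plane(states, source="delay")
    init_angles = np.arange(n_states) * 360.0 / n_states
    ring = delay_plane.ring_states(n_states)
    final = evolve_states(params, ring, "go")
    resp_plane = fit_plane(final, source="response")
    ang = resp_plane.angles(final)
    hist, _ = np.histogram(ang, bins=36, range=(0.0, 360.0))
    return RingEvolution(init_angles, final, ang, resp_plane,
                         hist.astype(float), binned_cv(ang))


def evolve_response_ring(params: NetworkParams, n_states: int = 1000, rng=0,
                         delay_ms: float = 800.0, n_fit_trials: int = 1000,
                         response_plane: Plane | None = None) -> RingEvolution:
    """Uniform response-plane ring evolved through the response epoch;
    representative states are the temporal averages over the epoch."""
    if response_plane is None:
        states, _ = collect_states(params, n_fit_trials, delay_ms, rng,
                                   at="start_of_response")
        response_plane = fit_plane(states, source="response")
    init_angles = np.arange(n_states) * 360.0 / n_states
    ring = response_plane.ring_states(n_states)
    rep = evolve_states(params, ring, "response", time_average=True)
    ang = response_plane.angles(rep)
    hist, _ = np.histogram(ang, bins=36, range=(0.0, 360.0))
    return RingEvolution(init_angles, rep, ang, response_plane,
                         hist.astype(float), binned_cv(ang))


def readout_decode(params: NetworkParams, query_states: np.ndarray,
                   states_are_rates: bool = False) -> np.ndarray:
    """The readout decoder: z = W_out tanh(x) + b_out, then the population
    vector. No time evolution; a pure function of (W_out, b_out, state)."""
    q = np.atleast_2d(np.asarray(query_states, dtype=float))
    r = q if states_are_rates else np.tanh(q)
    z = r @ params.w_out.T + params.b_out
    out = np.atleast_1d(population_vector_decode(z))
    return out if np.asarray(query_states).ndim > 1 else out[:1]


def readout_occupancy(params: NetworkParams, n_ring: int = 720, rng=0,
                      delay_ms: float = 800.0, n_fit_trials: int = 1000,
                      response_plane: Plane | None = None,
                      probe_kind: str = "manifold") -> AngleColorMap:
    """Angular occupancy of the readout decoder on the response plane."""
    states = None
    if response_plane is None or probe_kind == "manifold":
        states, _ = collect_states(params, n_fit_trials, delay_ms, rng,
                                   at="start_of_response")
    if response_plane is None:
        response_plane = fit_plane(states, source="response")
    probe = None
    if probe_kind == "manifold":
        from .state_geometry import manifold_ring
        probe = manifold_ring(states, response_plane)
    return angle_color_map(lambda s: readout_decode(params, s),
                           response_plane, n_ring, probe=probe)


@dataclass
class AngleChain:
    """Anchor angles linking the stages for one common color: theta_c on the
    delay plane, alpha_c after go, beta_c for representative states, and the
    color phi_c itself. The lifts reconstruct full states from angles along
    the corresponding data manifolds."""
    theta_c: float
    alpha_c: float
    beta_c: float
    phi_c: float
    delay_plane: Plane
    response_plane: Plane
    delay_ring: tuple = None        # (states, theta) manifold ring samples
    alpha_ring: tuple = None
    beta_ring: tuple = None

    def _lift(self, ring, plane, angles_deg):
        if ring is None:
            return _states_on_plane(plane, angles_deg)
        return interp_ring(ring[0], ring[1], angles_deg)

    def lift_theta(self, angles_deg):
        return self._lift(self.delay_ring, self.delay_plane, angles_deg)

    def lift_alpha(self, angles_deg):
        return self._lift(self.alpha_ring, self.response_plane, angles_deg)

    def lift_beta(self, angles_deg):
        return self._lift(self.beta_ring, self.response_plane, angles_deg)


def interp_ring(ring_states: np.ndarray, ring_theta: np.ndarray, query_deg):
    """Periodic per-dimension interpolation of a closed state-space curve
    parameterized by plane angle."""
    q = wrap_360(np.atleast_1d(np.asarray(query_deg, dtype=float)))
    th = np.concatenate([ring_theta, [ring_theta[0] + 360.0]])
    pts = np.vstack([ring_states, ring_states[:1]])
    out = np.empty((q.size, ring_states.shape[1]))
    qq = np.where(q < th[0], q + 360.0, q)
    for j in range(ring_states.shape[1]):
        out[:, j] = np.interp(qq, th, pts[:, j])
    return out


def build_angle_chain(params: NetworkParams, common_color: float = 130.0,
                      n_trials: int = 1000, delay_ms: float = 800.0, rng=0,
                      match_window_deg: float = 5.0) -> AngleChain:
    """Estimate the anchors from random-color noisy trials.

    Trials whose output color falls near the common color provide the anchor
    angles (circular means of their stage angles); the window widens
    automatically (up to 45 degrees) when too few trials decode nearby, as
    happens when a model's outputs cluster away from the requested color.
    """
    from .circular import circ_mean
    from .rnn_core import output_color as _oc
    from .state_geometry import manifold_ring
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    from .task_env import EnvironmentPrior, NoiseConfig, build_trials
    sched = EpochSchedule(delay_ms=delay_ms)
    batch = build_trials(EnvironmentPrior(uniform=True), TuningBank(), sched,
                         n_trials, NoiseConfig(params.sigma_x, params.sigma_rec),
                         rng=rng)
    traj = rollout(params, batch, noise_on=True, rng=rng)
    theta_states = traj.states_at("end_of_delay")
    alpha_states = traj.states_at("end_of_go")
    f, p, d, g, t = sched.boundaries
    beta_states = traj.x[:, g:t].mean(axis=1)     # representative states
    phis = _oc(traj)

    delay_plane = fit_plane(theta_states, source="delay")
    response_plane = fit_plane(alpha_states, source="response")
    w = match_window_deg
    sel = np.abs(circ_diff(phis, common_color)) <= w
    while sel.sum() < 20 and w < 45.0:
        w *= 2.0
        sel = np.abs(circ_diff(phis, common_color)) <= w
    if sel.sum() < 3:
        raise ValueError("too few trials decode near the common color; "
                         "increase n_trials or match_window_deg")
    theta_c = float(circ_mean(delay_plane.angles(theta_states[sel])))
    alpha_c = float(circ_mean(response_plane.angles(alpha_states[sel])))
    beta_c = float(circ_mean(response_plane.angles(beta_states[sel])))

    def _ring(states, plane):
        try:
            return manifold_ring(states, plane)
        except ValueError:
            return None
    return AngleChain(theta_c, alpha_c, beta_c, float(common_color),
                      delay_plane, response_plane,
                      delay_ring=_ring(theta_states, delay_plane),
                      alpha_ring=_ring(alpha_states, response_plane),
                      beta_ring=_ring(beta_states, response_plane))


def isolate_process(params: NetworkParams, process: str,
                    chain: AngleChain | None = None, common_color: float = 130.0,
                    n_angles: int = 500, delta_deg: float = 10.0, rng=0):
    """Memory error with exactly one post-delay process running in the RNN.

    Initial angles are spread uniformly over [theta_c - delta, theta_c + delta]
    on the delay plane. The chosen process (go | response | readout) runs in
    the network with noise off; the other two become uniform angle shifts
    anchored by the chain. Returns the RMSE of the final colors about the
    anchor angle's own output (no outlier removal: the grid is deterministic;
    values below the all-uniform baseline delta/sqrt(3) mean the process
    compresses errors around the common color).
    """
    if process not in ("go", "response", "readout"):
        raise ValueError(f"unknown process {process!r}")
    if chain is None:
        chain = build_angle_chain(params, common_color, rng=rng)
    # the anchor angle itself is appended; final colors are referenced to its
    # output, so a shared offset of the trial-estimated anchors cancels and
    # delta -> 0 gives exactly zero error
    thetas = np.concatenate([chain.theta_c
                             + np.linspace(-delta_deg, delta_deg, n_angles),
                             [chain.theta_c]])

    if process == "go":
        states = chain.lift_theta(thetas)
        evolved = evolve_states(params, states, "go")
        alphas = chain.response_plane.angles(evolved)
        phis = wrap_360(circ_diff(alphas, chain.alpha_c) + chain.phi_c)
    elif process == "response":
        alphas = wrap_360(circ_diff(thetas, chain.theta_c) + chain.alpha_c)
        states = chain.lift_alpha(alphas)
        rep = evolve_states(params, states, "response", time_average=True)
        betas = chain.response_plane.angles(rep)
        phis = wrap_360(circ_diff(betas, chain.beta_c) + chain.phi_c)
    else:  # readout
        betas = wrap_360(circ_diff(thetas, chain.theta_c) + chain.beta_c)
        states = chain.lift_beta(betas)
        phis = readout_decode(params, states)
    err = circ_diff(phis[:-1], phis[-1])
    return float(np.sqrt(np.mean(err**2)))


def uniform_chain_rmse(thetas_offset: np.ndarray) -> float:
    """RMSE when every process is a uniform shift (identity chain)."""
    return float(np.sqrt(np.mean(np.asarray(thetas_offset, dtype=float) ** 2)))


def _states_on_plane(plane: Plane, angles_deg: np.ndarray) -> np.ndarray:
    """Lift angles to full states at the plane's ring radius (the minimal-norm
    plane inversion)."""
    th = np.asarray(angles_deg, dtype=float) * np.pi / 180.0
    coords = plane.ring_radius * np.stack([np.cos(th), np.sin(th)], axis=-1)
    return plane.lift(coords)
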