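"""The RNN decoder, angular occupancy, dynamic dispersion, and the
Taylor-expansion decomposition of circular memory error.

The network's post-delay epochs define a decoding map from recurrent state to
output color. Along the delay-plane ring this is a map from plane angle theta
to color phi; its inverse derivative d(theta)/d(phi) is the angular occupancy:
the amount of angular state space a unit of color occupies. Around a common
color phi_c, a first-order expansion of phi(theta) predicts the squared memory
error as

    err^2(phi_c) ~= (dphi/dtheta|_c)^2 * dispersion
                    + (dphi/dtheta|_c)^2 * (theta_bar - theta_c)^2

with dispersion the variance of end-of-delay plane angles over repeated noisy
trials at the common color.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .circular import circ_diff, unwrap_about_mean, wrap_360
from .task_env import EpochSchedule, TuningBank
from .rnn_core import NetworkParams, decoder_batch, output_color, rollout
from .state_geometry import Plane, collect_states, fit_plane
from .behavior import iqr_filter, rmse_from_errors


def rnn_decode(params: NetworkParams, query_states: np.ndarray,
               schedule: EpochSchedule | None = None,
               bank: TuningBank = TuningBank()) -> np.ndarray:
    """Decode recurrent state(s) by re-entering the network and running the
    go + response epochs with noise off (the RNN decoder)."""
    q = np.atleast_2d(np.asarray(query_states, dtype=float))
    batch = decoder_batch(schedule or EpochSchedule(), q.shape[0], bank)
    traj = rollout(params, batch, noise_on=False, init_state=q)
    out = output_color(traj)
    return out if np.asarray(query_states).ndim > 1 else out[:1]


@dataclass
class AngleColorMap:
    """Sampled monotone correspondence between plane angle theta and decoded
    color phi, with the angular occupancy d(theta)/d(phi) per color.

    ``ring_theta``/``ring_phi`` are the raw decoded ring samples; the map is
    then inverted onto a uniform color grid (``color_grid``), where
    ``theta_of_color`` is theta(phi) and ``occupancy`` its derivative. A
    plateau of the decoder (many angles, one color) appears as an occupancy
    spike at that color, as it should.
    """

    ring_theta: np.ndarray      # (n,) plane angles, strictly increasing, one turn
    ring_phi: np.ndarray        # (n,) decoded colors in [0, 360)
    color_grid: np.ndarray      # (m,) colors in [0, 360), uniform in cover order
    theta_of_color: np.ndarray  # (m,) plane angle per color grid point
    occupancy: np.ndarray       # (m,) dtheta/dphi per color grid point
    ring_radius: float
    direction: int              # +1 if phi increases with theta, -1 otherwise

    # kept for symmetry with the forward samples
    @property
    def theta(self):
        return self.ring_theta

    @property
    def phi(self):
        return self.ring_phi

    def _grid_index(self, color_deg: float) -> int:
        return int(np.argmin(np.abs(circ_diff(self.color_grid, color_deg))))

    def occupancy_at(self, color_deg: float, window_deg: float = 10.0) -> float:
        """Occupancy around a color: the average slope dtheta/dphi over
        +-window_deg, i.e. (theta(c+w) - theta(c-w)) / 2w.

        Trained networks at reduced scale develop discrete attractors, making
        the pointwise occupancy a comb of near-plateau spikes; the windowed
        slope is the robust local estimator (window_deg=0 gives the raw grid
        value).
        """
        j = self._grid_index(color_deg)
        m = self.color_grid.size
        dphi = 360.0 / m
        k = int(round(window_deg / dphi))
        if k < 1:
            return float(self.occupancy[j])
        th = self.theta_of_color
        hi = th[(j + k) % m] + (360.0 if j + k >= m else 0.0)
        lo = th[(j - k) % m] - (360.0 if j - k < 0 else 0.0)
        return float((hi - lo) / (2 * k * dphi))

    def theta_at(self, color_deg: float) -> float:
        """Plane angle decoding to the requested color."""
        return float(self.theta_of_color[self._grid_index(color_deg)])

    def conservation_integral(self) -> float:
        """Integral of occupancy over one color turn; 360 for a bijection."""
        dphi = 360.0 / self.color_grid.size
        return float(np.sum(self.occupancy) * dphi)


def _monotone_unwrap(phi: np.ndarray, direction_hint: int | None = None):
    """Unwrap decoded colors phi(theta) over one ring turn into a monotone
    cover of 360 degrees. Detects the single wrap jump; more than one jump
    above 180 degrees means the map folds over."""
    phi = np.asarray(phi, dtype=float)
    d = circ_diff(phi[1:], phi[:-1])
    direction = direction_hint or (1 if np.sum(d) >= 0 else -1)
    steps = d * direction
    big_neg = np.where(steps < -180.0)[0]
    if big_neg.size > 0:
        raise ValueError(f"fold-over in angle-to-color map at sample indices "
                         f"{big_neg.tolist()}")
    # monotone-increasing cover: colors traversed in the map's own direction
    unwrapped = phi[0] + np.concatenate([[0.0], np.cumsum(steps)])
    total = unwrapped[-1] - unwrapped[0]
    if not (270.0 < total + 360.0 / len(phi) < 450.0):
        raise ValueError(f"angle-to-color map does not cover one turn "
                         f"(total {total:.1f} degrees); fold-over or degenerate ring")
    return unwrapped, direction


def angle_color_map(decode_fn, plane: Plane, n_ring: int = 720,
                    smooth_window: int | None = None, probe=None,
                    n_grid: int = 720) -> AngleColorMap:
    """Build the theta -> phi map by decoding a ring of probe states.

    ``decode_fn`` maps (n, d) states to colors: the RNN decoder for the delay
    plane, the readout decoder for the response plane. ``probe`` is an
    optional (states, theta_deg) pair of probe states and their plane angles
    (e.g. a manifold-following ring); by default a flat circle of ``n_ring``
    states at the plane's ring radius is used. Before differentiation the
    monotone cover is smoothed with a circular moving average of
    ``smooth_window`` samples (the decoder output is piecewise smooth with
    near-plateaus around strong attractors, which raw finite differences
    amplify); set to 1 to disable.
    """
    if probe is None:
        theta = np.arange(n_ring) * 360.0 / n_ring
        states = plane.ring_states(n_ring)
    else:
        states, theta = probe
        theta = np.asarray(theta, dtype=float)
    n = theta.size
    phi = np.asarray(decode_fn(states), dtype=float)
    unwrapped, direction = _monotone_unwrap(phi)
    if smooth_window is None:
        smooth_window = max(3, n // 80)     # ~4.5 degrees of ring angle
    if smooth_window > 1 and n >= smooth_window:
        w = int(smooth_window) | 1          # odd
        h = w // 2
        ext = np.concatenate([unwrapped[-h:] - 360.0, unwrapped,
                              unwrapped[:h] + 360.0])
        unwrapped = np.convolve(ext, np.ones(w) / w, mode="valid")

    # invert to theta(phi) on a uniform color grid (periodic extension of the
    # cover), then centered finite differences per color
    cover = np.maximum.accumulate(unwrapped)            # monotone nondecreasing
    cover = cover + np.arange(n) * 1e-9                 # break exact plateaus
    phi0 = float(phi[0])                                # cover-frame anchor
    m = n_grid
    grid = cover[0] + np.arange(m) * 360.0 / m          # cover-frame colors
    cov_ext = np.concatenate([cover, [cover[0] + 360.0]])
    th_ext = np.concatenate([theta, [theta[0] + 360.0]])
    theta_of = np.interp(grid, cov_ext, th_ext)
    dphi = 2.0 * 360.0 / m
    occ = np.empty(m)
    occ[1:-1] = (theta_of[2:] - theta_of[:-2]) / dphi
    occ[0] = (theta_of[1] - (theta_of[-1] - 360.0)) / dphi
    occ[-1] = ((theta_of[0] + 360.0) - theta_of[-2]) / dphi
    # real colors of the grid points (cover frame -> circle, respecting the
    # traversal direction; the raw first sample anchors the frame)
    color_grid = wrap_360(phi0 + direction * (grid - phi0))
    return AngleColorMap(ring_theta=theta, ring_phi=wrap_360(phi),
                         color_grid=color_grid, theta_of_color=theta_of,
                         occupancy=occ, ring_radius=plane.ring_radius,
                         direction=direction)


def angular_occupancy(params: NetworkParams, n_ring: int = 720, rng=0,
                      n_fit_trials: int = 1000, delay_ms: float = 800.0,
                      plane: Plane | None = None, states: np.ndarray | None = None,
                      probe_kind: str = "manifold") -> AngleColorMap:
    """Angular occupancy of the RNN decoder on the delay plane.

    The plane is fitted to end-of-delay states of random-color noisy trials;
    the ring radius is the mean distance of those states to their center.
    ``probe_kind='manifold'`` (default) traces the decode ring along the data
    manifold (angle-binned state means), which stays valid when the manifold
    is curved; ``'circle'`` probes the flat plane circle instead.
    """
    if states is None:
        states, _ = collect_states(params, n_fit_trials, delay_ms, rng)
    if plane is None:
        plane = fit_plane(states, source="delay")
    probe = None
    if probe_kind == "manifold":
        from .state_geometry import manifold_ring
        probe = manifold_ring(states, plane)
    elif probe_kind != "circle":
        raise ValueError(f"unknown probe_kind {probe_kind!r}")
    return angle_color_map(lambda s: rnn_decode(params, s), plane, n_ring,
                           probe=probe)


@dataclass
class DispersionResult:
    """Variance of delay-plane angles over repeated noisy fixed-color trials."""
    angles: np.ndarray
    mean_angle: float           # circular mean theta_bar (degrees)
    variance: float             # degrees^2, after outlier removal
    n_outliers_removed: int
    theta_c: float              # ring angle decoding exactly the common color


def dynamic_dispersion(params: NetworkParams, input_color: float = 40.0,
                       delay_ms: float = 800.0, n_trials: int = 500, rng=0,
                       plane: Plane | None = None,
                       acmap: AngleColorMap | None = None,
                       n_fit_trials: int = 1000) -> DispersionResult:
    """Dynamic dispersion at a fixed input color.

    Two-step procedure: fit the delay plane on random-color trials, then
    project end-of-delay states of fixed-color noisy trials, unwrap their
    angles about the circular mean, drop 1.5 x IQR outliers, and return the
    variance (degrees^2).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if plane is None or acmap is None:
        states, _ = collect_states(params, n_fit_trials, delay_ms, rng)
        if plane is None:
            plane = fit_plane(states, source="delay")
        if acmap is None:
            acmap = angular_occupancy(params, rng=rng, plane=plane, states=states)
    fixed_states, _ = collect_states(params, n_trials, delay_ms, rng,
                                     fixed_color=float(input_color))
    theta = plane.angles(fixed_states)
    mean, offsets = unwrap_about_mean(theta)
    keep = iqr_filter(offsets)
    kept = offsets[keep]
    var = float(np.mean((kept - kept.mean()) ** 2))
    mean_angle = wrap_360(mean + kept.mean())
    return DispersionResult(angles=theta, mean_angle=float(mean_angle),
                            variance=var, n_outliers_removed=int((~keep).sum()),
                            theta_c=acmap.theta_at(float(input_color)))


@dataclass
class ErrorDecomposition:
    """Taylor-expansion decomposition of squared memory error at a common color."""
    dphi_dtheta_sq: float       # (dphi/dtheta|_c)^2 = 1 / occupancy^2
    dispersion: float           # degrees^2
    mean_bias_correction: float  # (theta_bar - theta_c)^2 * (dphi/dtheta)^2
    theory_rmse: float
    experiment_rmse: float = np.nan
    ablated_rmse: float = np.nan  # occupancy forced to 1 (dphi/dtheta = 1)

    @property
    def identity_residual(self) -> float:
        return abs(self.theory_rmse**2
                   - (self.dphi_dtheta_sq * self.dispersion
                      + self.mean_bias_correction))


def decomposition_from_parts(occupancy_at_c: float, dispersion: float,
                             mean_angle: float, theta_c: float) -> ErrorDecomposition:
    """Assemble the decomposition from its measured ingredients."""
    dphi_dtheta_sq = 1.0 / occupancy_at_c**2
    bias = float(circ_diff(mean_angle, theta_c)) ** 2 * dphi_dtheta_sq
    theory = np.sqrt(dphi_dtheta_sq * dispersion + bias)
    ablated = np.sqrt(dispersion + float(circ_diff(mean_angle, theta_c)) ** 2)
    return ErrorDecomposition(dphi_dtheta_sq=dphi_dtheta_sq, dispersion=dispersion,
                              mean_bias_correction=bias, theory_rmse=float(theory),
                              ablated_rmse=float(ablated))


def decompose_error(params: NetworkParams, common_color: float = 40.0,
                    delay_ms: float = 800.0, n_trials_theory: int = 500,
                    n_trials_exp: int = 2000, rng=0,
                    n_fit_trials: int = 1000,
                    plane: Plane | None = None,
                    acmap: AngleColorMap | None = None) -> ErrorDecomposition:
    """Theory vs experiment at one common color for one model.

    Theory: occupancy and dispersion plugged into the expansion. Experiment:
    RMSE of (phi_i - phi_c) over noisy fixed-input trials with the 1.5 x IQR
    outlier rule. Also reports the occupancy-ablated prediction
    (dphi/dtheta := 1).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if plane is None or acmap is None:
        states, _ = collect_states(params, n_fit_trials, delay_ms, rng)
        plane = fit_plane(states, source="delay")
        acmap = angular_occupancy(params, rng=rng, plane=plane, states=states)
    disp = dynamic_dispersion(params, common_color, delay_ms, n_trials_theory,
                              rng, plane=plane, acmap=acmap)
    occ_c = acmap.occupancy_at(common_color)
    if occ_c <= 0:
        raise ValueError("nonpositive occupancy at the common color")
    dec = decomposition_from_parts(occ_c, disp.variance, disp.mean_angle,
                                   disp.theta_c)
    from .behavior import run_trials, circular_error
    ins, outs = run_trials(params, n_trials_exp, delay_ms, rng,
                           input_color=float(common_color))
    err = circ_diff(outs, common_color)
    dec.experiment_rmse = rmse_from_errors(err, f"fixed:{common_color:g}").rmse
    return dec


def sweep_conditions(models_by_condition: dict, common_color: float = 40.0,
                     delay_ms: float = 800.0, rng=0, n_trials_theory: int = 500,
                     n_trials_exp: int = 2000,
                     common_colors=(40.0, 130.0, 220.0, 310.0)) -> pd.DataFrame:
    """Per-model decomposition table over ensembles keyed by condition
    (e.g. prior width sigma_s, or noise level sigma).

    The decomposition (theory vs experiment) is evaluated at ``common_color``;
    the trend columns ``occupancy_cc`` (mean) and ``dispersion_cc`` (median)
    aggregate over all four common colors, which stabilizes the per-model
    statistic at reduced scale. Models whose angle-to-color map degenerates
    are recorded with NaNs.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    rows = []
    for cond, models in models_by_condition.items():
        for i, model in enumerate(models):
            params = model.params if hasattr(model, "params") else model
            row = dict(condition=cond, model=i)
            try:
                states, _ = collect_states(params, 1000, delay_ms, rng)
                plane = fit_plane(states, source="delay")
                acmap = angular_occupancy(params, rng=rng, plane=plane,
                                          states=states)
                dec = decompose_error(params, common_color, delay_ms,
                                      n_trials_theory, n_trials_exp, rng,
                                      plane=plane, acmap=acmap)
                disps = [dynamic_dispersion(params, c, delay_ms,
                                            n_trials_theory, rng, plane=plane,
                                            acmap=acmap).variance
                         for c in common_colors]
                row.update(dispersion=dec.dispersion,
                           dphi_dtheta_sq=dec.dphi_dtheta_sq,
                           occupancy=1.0 / np.sqrt(dec.dphi_dtheta_sq),
                           occupancy_cc=float(np.mean(
                               [acmap.occupancy_at(c) for c in common_colors])),
                           dispersion_cc=float(np.median(disps)),
                           mean_bias_correction=dec.mean_bias_correction,
                           theory_rmse=dec.theory_rmse,
                           ablated_rmse=dec.ablated_rmse,
                           experiment_rmse=dec.experiment_rmse)
            except ValueError as err:
                row.update(dispersion=np.nan, dphi_dtheta_sq=np.nan,
                           occupancy=np.nan, occupancy_cc=np.nan,
                           dispersion_cc=np.nan, mean_bias_correction=np.nan,
                           theory_rmse=np.nan, ablated_rmse=np.nan,
                           experiment_rmse=np.nan, note=str(err)[:60])
            rows.append(row)
    return pd.DataFrame(rows)
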