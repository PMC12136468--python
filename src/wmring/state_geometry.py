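"""State-space geometry of trained networks.

PCA planes (delay plane / response plane), dimensionality curves, fixed-point
search by speed minimization with analytic gradients, Jacobian classification
into attractors and saddles, and attractor color histograms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from .circular import RAD2DEG, wrap_360
from .task_env import EnvironmentPrior, EpochSchedule, NoiseConfig, TuningBank, build_trials
from .rnn_core import NetworkParams, rollout


@dataclass
class Plane:
    """A 2-D PCA embedding: mean + two orthonormal axes, with projection
    (d -> 2) and lift (2 -> d) maps."""

    mean: np.ndarray            # (d,)
    axes: np.ndarray            # (2, d), orthonormal
    explained_variance_ratio: np.ndarray = field(default_factory=lambda: np.zeros(2))
    source: str = ""
    ring_radius: float = np.nan      # mean distance of fitting states to center
    radius_spread: float = np.nan    # std of those distances

    def project(self, states: np.ndarray) -> np.ndarray:
        """(..., d) -> (..., 2) plane coordinates."""
        return (np.asarray(states) - self.mean) @ self.axes.T

    def lift(self, coords: np.ndarray) -> np.ndarray:
        """(..., 2) plane coordinates -> (..., d) minimal-norm reconstruction."""
        return np.asarray(coords) @ self.axes + self.mean

    def angles(self, states: np.ndarray) -> np.ndarray:
        """Plane angle (degrees in [0, 360)) of each state's projection."""
        p = self.project(states)
        return wrap_360(np.arctan2(p[..., 1], p[..., 0]) * RAD2DEG)

    def ring_states(self, n: int, radius: float | None = None,
                    start_deg: float = 0.0) -> np.ndarray:
        """n equally spaced full-dimensional states on the plane ring."""
        r = self.ring_radius if radius is None else radius
        th = (start_deg + np.arange(n) * 360.0 / n) / RAD2DEG
        return self.lift(r * np.stack([np.cos(th), np.sin(th)], axis=-1))


def manifold_ring(states: np.ndarray, plane: Plane, n_bins: int = 72,
                  smooth_bins: int = 5, min_filled: int = 8,
                  n_out: int | None = 720):
    """Resample a closed curve along the data manifold, parameterized by the
    plane angle.

    States are binned by their delay-plane angle; bin means (in the full state
    space) are circularly smoothed, giving probe states that stay close to the
    manifold even when the manifold is curved and a flat plane circle would
    leave it. Returns (ring_states (n_bins, d), theta_deg (n_bins,)) with
    theta the probe states' actual plane angles (monotone up to smoothing).
    """
    states = np.asarray(states, dtype=float)
    ang = plane.angles(states)
    idx = np.minimum((ang / (360.0 / n_bins)).astype(int), n_bins - 1)
    d = states.shape[1]
    sums = np.zeros((n_bins, d))
    counts = np.zeros(n_bins)
    np.add.at(sums, idx, states)
    np.add.at(counts, idx, 1.0)
    filled = counts > 0
    if filled.sum() < min_filled:
        raise ValueError("too few angular bins populated to trace the ring")
    centers = (np.arange(n_bins) + 0.5) * 360.0 / n_bins
    means = np.empty((n_bins, d))
    means[filled] = sums[filled] / counts[filled, None]
    if not np.all(filled):
        # fill gaps by periodic linear interpolation along the angle axis
        fc = centers[filled]
        for j in range(d):
            means[~filled, j] = np.interp(centers[~filled],
                                          np.concatenate([fc, fc + 360.0]),
                                          np.tile(means[filled, j], 2))
    if smooth_bins > 1:
        w = int(smooth_bins) | 1
        h = w // 2
        ext = np.concatenate([means[-h:], means, means[:h]])
        kernel = np.ones(w) / w
        means = np.apply_along_axis(lambda col: np.convolve(col, kernel, "valid"),
                                    0, ext)
    if n_out is not None and n_out > n_bins:
        # densify the closed curve by periodic linear interpolation per dim
        s_in = np.arange(n_bins + 1)
        pts = np.vstack([means, means[:1]])
        s_out = np.arange(n_out) * n_bins / n_out
        dense = np.empty((n_out, d))
        for j in range(d):
            dense[:, j] = np.interp(s_out, s_in, pts[:, j])
        means = dense
    theta = plane.angles(means)
    order = np.argsort(theta, kind="stable")
    return means[order], theta[order]


def fit_plane(states: np.ndarray, source: str = "") -> Plane:
    """Top-2 PCA plane of a cloud of states (n x d)."""
    states = np.asarray(states, dtype=float)
    if states.shape[0] < 3:
        raise ValueError("need at least 3 states to fit a plane")
    if np.allclose(states.var(axis=0).sum(), 0.0):
        raise ValueError("zero-variance state cloud")
    pca = PCA(n_components=2)
    proj = pca.fit_transform(states)
    radii = np.linalg.norm(proj, axis=1)
    return Plane(mean=pca.mean_, axes=pca.components_,
                 explained_variance_ratio=pca.explained_variance_ratio_,
                 source=source, ring_radius=float(radii.mean()),
                 radius_spread=float(radii.std()))


def collect_states(params: NetworkParams, n_trials: int = 1000,
                   delay_ms: float = 800.0, rng=0, noise_on: bool = True,
                   prior: EnvironmentPrior | None = None,
                   fixed_color: float | None = None,
                   at: str = "end_of_delay",
                   bank: TuningBank = TuningBank()):
    """Run trials and return (states at a named boundary, input colors)."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    sched = EpochSchedule(delay_ms=delay_ms)
    prior = prior or EnvironmentPrior(uniform=True)
    noise = NoiseConfig(sigma_x=params.sigma_x if noise_on else 0.0,
                        sigma_rec=params.sigma_rec)
    batch = build_trials(prior, bank, sched, n_trials, noise, rng=rng,
                         fixed_color=fixed_color)
    traj = rollout(params, batch, noise_on=noise_on, rng=rng)
    return traj.states_at(at), batch.input_colors


def fit_delay_plane(params: NetworkParams, n_trials: int = 1000,
                    delay_ms: float = 800.0, rng=0, noise_on: bool = True) -> Plane:
    """The delay plane: PCA of end-of-delay states over random-color trials."""
    states, _ = collect_states(params, n_trials, delay_ms, rng, noise_on)
    return fit_plane(states, source="delay")


def dimensionality(params: NetworkParams, n_trials: int = 1000,
                   scope: str = "full_trial", delay_ms: float = 800.0,
                   rng=0) -> np.ndarray:
    """Cumulative explained-variance curve of recurrent states (noise off)."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    sched = EpochSchedule(delay_ms=delay_ms)
    batch = build_trials(EnvironmentPrior(uniform=True), TuningBank(), sched,
                         n_trials, NoiseConfig(0.0, 0.0), rng=rng)
    traj = rollout(params, batch, noise_on=False)
    if scope == "full_trial":
        states = traj.x.reshape(-1, params.n_rec)
    elif scope == "delay_only":
        f, p, d, g, t = sched.boundaries
        states = traj.x[:, p:d].reshape(-1, params.n_rec)
    else:
        raise ValueError(f"unknown scope {scope!r}")
    pca = PCA()
    pca.fit(states)
    return np.cumsum(pca.explained_variance_ratio_)


@dataclass
class FixedPoint:
    """A located slow point of the autonomous delay dynamics."""
    x_star: np.ndarray
    speed: float                    # |F(x)| / dt, per ms
    eigenvalues: np.ndarray         # complex spectrum of J = dF/dx
    kind: str                       # attractor | saddle | neutral
    decoded_color: float = np.nan
    ring_distance: float = np.nan

    @property
    def max_real_eig(self) -> float:
        return float(np.max(self.eigenvalues.real))


def classify_spectrum(eigvals: np.ndarray, tol: float = 1e-6) -> str:
    """Attractor if all real parts < 0, saddle if any > 0, else neutral."""
    re = np.asarray(eigvals).real
    if np.all(re < -tol):
        return "attractor"
    if np.any(re > tol):
        return "saddle"
    return "neutral"


def finite_difference_jacobian(f, x: np.ndarray, h: float = 1e-5) -> np.ndarray:
    """Central finite-difference Jacobian of a vector map; oracle for the
    analytic Jacobians."""
    x = np.asarray(x, dtype=float)
    d = x.size
    J = np.empty((d, d))
    for j in range(d):
        e = np.zeros(d)
        e[j] = h
        J[:, j] = (f(x + e) - f(x - e)) / (2 * h)
    return J


def find_fixed_points(dynamics, seed_states: np.ndarray, tol_speed: float = 1e-5,
                      max_iters: int = 5000, lr: float = 1e-2,
                      dedup_radius: float = 0.1,
                      ring_filter: Plane | None = None,
                      ring_spread_factor: float = 2.0,
                      dt_ms: float = 20.0) -> list:
    """Minimize |F(x)|^2 over x with Adam from each seed state.

    ``dynamics`` exposes velocity(x), speed_grad(x) and jacobian(x) (the
    trained network or a planted fixture). Converged points (speed per step
    below ``tol_speed``) are deduplicated at ``dedup_radius`` and optionally
    restricted to the neighborhood of the delay ring.
    """
    x = np.atleast_2d(np.asarray(seed_states, dtype=float)).copy()
    m = np.zeros_like(x)
    v = np.zeros_like(x)
    b1, b2, eps = 0.9, 0.999, 1e-8
    for it in range(max_iters):
        sp = np.linalg.norm(dynamics.velocity(x), axis=-1)
        if np.all(sp < tol_speed):
            break
        g = dynamics.speed_grad(x)
        m = b1 * m + (1 - b1) * g
        v = b2 * v + (1 - b2) * g**2
        mh = m / (1 - b1 ** (it + 1))
        vh = v / (1 - b2 ** (it + 1))
        x -= lr * mh / (np.sqrt(vh) + eps)

    speeds = np.linalg.norm(dynamics.velocity(x), axis=-1)
    converged = x[speeds < tol_speed]
    if converged.shape[0] == 0:
        import warnings
        warnings.warn("no seed converged below tol_speed; returning empty list")
        return []

    # greedy dedup
    reps = []
    for pt in converged:
        if not any(np.linalg.norm(pt - r) < dedup_radius for r in reps):
            reps.append(pt)

    out = []
    for pt in reps:
        if ring_filter is not None:
            rad = np.linalg.norm(ring_filter.project(pt))
            ring_d = abs(rad - ring_filter.ring_radius)
            if ring_d > ring_spread_factor * max(ring_filter.radius_spread,
                                                 1e-6 * ring_filter.ring_radius):
                continue
        else:
            ring_d = np.nan
        eig = np.linalg.eigvals(dynamics.jacobian(pt))
        sp = float(np.linalg.norm(dynamics.velocity(pt)) / dt_ms)
        out.append(FixedPoint(pt, sp, eig, classify_spectrum(eig),
                              ring_distance=float(ring_d) if np.isfinite(ring_d) else np.nan))
    return out


def delay_start_seeds(params: NetworkParams, n_colors: int = 500,
                      delay_ms: float = 800.0, rng=0) -> np.ndarray:
    """Start-of-delay states for equally spaced input colors (noise off):
    the standard initialization set for the fixed-point search."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    sched = EpochSchedule(delay_ms=delay_ms)
    colors = np.arange(n_colors) * 360.0 / n_colors
    bank = TuningBank()
    batch = build_trials(EnvironmentPrior(uniform=True), bank, sched, n_colors,
                         NoiseConfig(0.0, 0.0), rng=rng)
    batch.inputs[:, :, : bank.n_units] = 0.0
    patterns = bank.response(colors)
    f, p, d, g, t = sched.boundaries
    batch.inputs[:, f:p, : bank.n_units] = patterns[:, None, :]
    batch.input_colors = colors
    traj = rollout(params, batch, noise_on=False)
    return traj.states_at("start_of_delay")


def attractor_colors(params: NetworkParams, fixed_points: list, rng=0) -> np.ndarray:
    """Decode each attractor's color through the go+response splice."""
    from .occupancy_theory import rnn_decode
    att = [fp for fp in fixed_points if fp.kind == "attractor"]
    if not att:
        return np.array([])
    states = np.stack([fp.x_star for fp in att])
    colors = rnn_decode(params, states)
    for fp, c in zip(att, colors):
        fp.decoded_color = float(c)
    return colors


def attractor_color_histogram(colors_concat, n_bins: int = 36):
    """Normalized circular histogram of decoded attractor colors pooled over
    an ensemble; returns (bin_centers, density)."""
    edges = np.linspace(0.0, 360.0, n_bins + 1)
    centers = (edges[:-1] + edges[1:]) / 2.0
    colors_concat = np.asarray(colors_concat, dtype=float)
    if colors_concat.size == 0:
        return centers, np.zeros(n_bins)
    counts, _ = np.histogram(wrap_360(colors_concat), bins=edges)
    return centers, counts / counts.sum()
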