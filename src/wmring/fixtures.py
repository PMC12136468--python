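"""Ground-truth synthetic dynamics for testing the analysis stages without any
training run.

All fixtures implement the same stepping/velocity interface as trained
networks, and every ground truth (fixed-point locations, Jacobian classes,
occupancy derivatives) is available in closed form, independent of the
analysis code under test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import i0

from .circular import DEG2RAD, RAD2DEG, wrap_360
from .task_env import TrialBatch, TuningBank
from .rnn_core import Trajectory


def _orthonormal_embedding(d: int, k: int, rng) -> np.ndarray:
    """A (k, d) matrix with orthonormal rows (random subspace)."""
    a = rng.standard_normal((d, k))
    q, _ = np.linalg.qr(a)
    return q[:, :k].T


@dataclass
class PlantedRingNet:
    """Synthetic dynamics with a planted ring attractor.

    The state decomposes into 2-D plane coordinates p = Q (x - c) and an
    off-plane residual. One discrete step applies, in polar plane coordinates,

        r'     = r - radial_rate * (r - ring_radius)
        theta' = theta - (strength / k) * sin(k (theta - theta0))
        rho'   = (1 - offplane_rate) * rho

    so the map has fixed points exactly on the unit-radius ring at the k
    angles where sin(k (theta - theta0)) = 0: attractors at
    theta0 + j*(360/k) and saddles midway between them. The in-plane Jacobian
    eigenvalues of F = step - identity at a fixed point are
    {-radial_rate, -strength*cos(k dtheta)} with the off-plane eigenvalue
    -offplane_rate (multiplicity d-2).
    """

    d: int = 12
    k_attractors: int = 4
    theta0: float = 40.0            # first attractor angle, degrees
    radial_rate: float = 0.3
    strength: float = 0.2           # angular contraction rate at attractors
    offplane_rate: float = 0.5
    ring_radius: float = 1.0
    rng_seed: int = 0
    dt_ms: float = 20.0
    alpha: float = 1.0
    center: np.ndarray = None
    Q: np.ndarray = None            # (2, d) orthonormal plane axes

    def __post_init__(self):
        if self.d < 3:
            raise ValueError("d must be >= 3")
        if self.k_attractors < 1:
            raise ValueError("k_attractors must be >= 1")
        rng = np.random.default_rng(self.rng_seed)
        if self.Q is None:
            self.Q = _orthonormal_embedding(self.d, 2, rng)
        if self.center is None:
            self.center = np.zeros(self.d)

    @property
    def n_rec(self):
        return self.d

    @property
    def attractor_angles(self) -> np.ndarray:
        return wrap_360(self.theta0 + np.arange(self.k_attractors)
                        * 360.0 / self.k_attractors)

    @property
    def saddle_angles(self) -> np.ndarray:
        return wrap_360(self.attractor_angles + 180.0 / self.k_attractors)

    def ring_state(self, theta_deg, radius=None) -> np.ndarray:
        r = self.ring_radius if radius is None else radius
        th = np.asarray(theta_deg, dtype=float) * DEG2RAD
        coords = r * np.stack([np.cos(th), np.sin(th)], axis=-1)
        return coords @ self.Q + self.center

    def _polar_step(self, p: np.ndarray):
        """One step of the in-plane polar map; p is (..., 2)."""
        r = np.linalg.norm(p, axis=-1)
        th = np.arctan2(p[..., 1], p[..., 0])
        k = self.k_attractors
        th0 = self.theta0 * DEG2RAD
        r2 = r - self.radial_rate * (r - self.ring_radius)
        th2 = th - (self.strength / k) * np.sin(k * (th - th0))
        return np.stack([r2 * np.cos(th2), r2 * np.sin(th2)], axis=-1)

    def step_autonomous(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        rel = x - self.center
        p = rel @ self.Q.T
        off = rel - p @ self.Q
        p2 = self._polar_step(p)
        return self.center + p2 @ self.Q + (1.0 - self.offplane_rate) * off

    def velocity(self, x: np.ndarray) -> np.ndarray:
        return self.step_autonomous(x) - np.asarray(x, dtype=float)

    def jacobian(self, x: np.ndarray) -> np.ndarray:
        """Analytic Jacobian of F = step - identity at a single state."""
        x = np.asarray(x, dtype=float)
        p = (x - self.center) @ self.Q.T
        r = float(np.linalg.norm(p))
        th = float(np.arctan2(p[1], p[0]))
        k = self.k_attractors
        th0 = self.theta0 * DEG2RAD
        r2 = r - self.radial_rate * (r - self.ring_radius)
        th2 = th - (self.strength / k) * np.sin(k * (th - th0))
        dr2_dr = 1.0 - self.radial_rate
        dth2_dth = 1.0 - self.strength * np.cos(k * (th - th0))
        e = np.array([np.cos(th2), np.sin(th2)])
        eperp = np.array([-np.sin(th2), np.cos(th2)])
        dr_dp = p / r
        dth_dp = np.array([-p[1], p[0]]) / r**2
        dg = (np.outer(e, dr_dp) * dr2_dr
              + np.outer(eperp, dth_dp) * (r2 * dth2_dth))
        P = self.Q.T @ self.Q                    # projector onto the plane
        J_step = self.Q.T @ dg @ self.Q + (1.0 - self.offplane_rate) * (np.eye(self.d) - P)
        return J_step - np.eye(self.d)

    def speed_grad(self, x: np.ndarray) -> np.ndarray:
        """Gradient of |F(x)|^2; finite differences on the closed-form map
        would also do, but the Jacobian is available analytically."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        out = np.empty_like(x)
        for i, xi in enumerate(x):
            out[i] = 2.0 * self.jacobian(xi).T @ self.velocity(xi)
        return out if out.shape[0] > 1 else out[0]

    def expected_eigenvalues(self, theta_deg: float) -> np.ndarray:
        """Closed-form spectrum of J at a planted fixed point."""
        k = self.k_attractors
        dth = (theta_deg - self.theta0) * DEG2RAD
        ang = -self.strength * np.cos(k * dth)
        return np.concatenate([[-self.radial_rate, ang],
                               np.full(self.d - 2, -self.offplane_rate)])


def make_planted_ring(d: int = 12, k_attractors: int = 4, theta0: float = 40.0,
                      radial_rate: float = 0.3, strength: float = 0.2,
                      offplane_rate: float = 0.5, rng_seed: int = 0) -> PlantedRingNet:
    return PlantedRingNet(d=d, k_attractors=k_attractors, theta0=theta0,
                          radial_rate=radial_rate, strength=strength,
                          offplane_rate=offplane_rate, rng_seed=rng_seed)


@dataclass
class WarpMap:
    """Monotone circular bijection phi(theta) built from a mixture-of-von-Mises
    CDF, with a closed-form derivative.

    theta(phi) = 360 * CDF(phi), so d(theta)/d(phi) = 360 * pdf(phi): the
    angular occupancy peaks exactly at the mixture centers. concentration = 0
    gives the identity map.
    """

    concentration: float = 2.0       # von Mises kappa of each component
    centers: tuple = (40.0, 130.0, 220.0, 310.0)
    _grid: np.ndarray = field(default=None, repr=False)
    _theta_grid: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")
        n = 72000
        self._grid = np.linspace(0.0, 360.0, n + 1)
        pdf = self.pdf(self._grid)
        cdf = np.concatenate([[0.0], np.cumsum((pdf[1:] + pdf[:-1]) / 2.0
                                               * np.diff(self._grid))])
        cdf *= 360.0 / cdf[-1]
        self._theta_grid = cdf                   # theta(phi) on the grid

    def pdf(self, phi_deg) -> np.ndarray:
        """Mixture density per degree (uniform when concentration is 0)."""
        phi = np.asarray(phi_deg, dtype=float)
        if self.concentration == 0:
            return np.full_like(phi, 1.0 / 360.0)
        kappa = self.concentration
        acc = np.zeros_like(phi)
        for c in self.centers:
            acc += np.exp(kappa * np.cos((phi - c) * DEG2RAD)) / (2 * np.pi * i0(kappa))
        return acc / len(self.centers) * DEG2RAD

    def theta_of_phi(self, phi_deg) -> np.ndarray:
        return np.interp(wrap_360(phi_deg), self._grid, self._theta_grid)

    def phi_of_theta(self, theta_deg) -> np.ndarray:
        return np.interp(wrap_360(theta_deg), self._theta_grid, self._grid)

    def occupancy(self, phi_deg) -> np.ndarray:
        """Analytic d(theta)/d(phi) = 360 * pdf(phi)."""
        return 360.0 * self.pdf(phi_deg)

    def derivative_phi_of_theta(self, theta_deg) -> np.ndarray:
        return 1.0 / self.occupancy(self.phi_of_theta(theta_deg))


def make_warp(concentration: float = 2.0,
              centers=(40.0, 130.0, 220.0, 310.0)) -> WarpMap:
    return WarpMap(concentration=concentration, centers=tuple(centers))


@dataclass
class ReplayNet:
    """A dynamics stand-in that stores the perception pattern and replays it
    during the response epoch: zero memory error with noise off. End-to-end
    harness for behavior and decoding analyses."""

    bank: TuningBank = field(default_factory=TuningBank)
    sigma_x: float = 0.0
    sigma_rec: float = 0.0

    @property
    def n_rec(self):
        return self.bank.n_units

    def rollout(self, batch: TrialBatch, noise_on: bool = False, rng=0,
                **_ignored) -> Trajectory:
        B, T, _ = batch.inputs.shape
        M = self.bank.n_units
        z = np.zeros((B, T, M))
        x = np.zeros((B, T, M))
        for i, s in enumerate(batch.schedules):
            f, p, d, g, t = s.boundaries
            stored = batch.inputs[i, f:p, :M].mean(axis=0)
            z[i, g:t] = stored
            x[i, f:, :] = np.arctanh(np.clip(stored, -0.999, 0.999))
        return Trajectory(x=x, z=z, schedules=list(batch.schedules),
                          input_colors=batch.input_colors)


def make_replay_net(bank: TuningBank | None = None) -> ReplayNet:
    return ReplayNet(bank=bank or TuningBank())
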