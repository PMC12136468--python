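"""Color delayed-response task environment.

A trial presents a color drawn from an environmental prior (a four-component
mixture of von Mises bumps, or a uniform density), encodes it through a bank of
12 von Mises-tuned perception units, holds it over a variable delay, and cues a
response with a go pulse. This module owns the prior, the tuning bank, the
epoch schedule, and assembly of complete input/target/mask trial batches.

Units: degrees externally; radians only inside von Mises kernels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import i0

from .circular import DEG2RAD, circ_diff, wrap_360

COMMON_COLORS = (40.0, 130.0, 220.0, 310.0)


def von_mises_pdf_rad(x_rad, sigma_rad):
    """Von Mises density over radians, width parameter sigma (kappa = 1/sigma^2)."""
    kappa = 1.0 / sigma_rad**2
    # log-space to stay finite for very narrow bumps (sigma -> 0, kappa large)
    log_i0 = np.log(i0(kappa)) if kappa < 700 else kappa - 0.5 * np.log(2 * np.pi * kappa)
    return np.exp(kappa * np.cos(x_rad) - np.log(2 * np.pi) - log_i0)


@dataclass(frozen=True)
class EnvironmentPrior:
    """Mixture-of-von-Mises color prior (or the uniform environment).

    ``density`` integrates to 1 over [0, 360) degrees. ``sigma_s`` controls
    the bump width; narrower priors concentrate probability on the common
    colors. ``uniform=True`` is the explicit uniform environment, which the
    wide-mixture limit (sigma_s = 90 degrees) approximates.
    """

    common_colors: tuple = COMMON_COLORS
    sigma_s: float = 25.0
    uniform: bool = False

    def __post_init__(self):
        if self.sigma_s <= 0:
            raise ValueError(f"sigma_s must be positive, got {self.sigma_s}")
        object.__setattr__(self, "common_colors",
                           tuple(float(c) % 360.0 for c in self.common_colors))

    @property
    def n_components(self) -> int:
        return len(self.common_colors)

    def density(self, colors_deg):
        """Prior density per degree, vectorized."""
        phi = np.asarray(colors_deg, dtype=float)
        if self.uniform:
            return np.full_like(phi, 1.0 / 360.0, dtype=float)
        sigma_rad = self.sigma_s * DEG2RAD
        acc = np.zeros_like(phi, dtype=float)
        for mu in self.common_colors:
            acc += von_mises_pdf_rad(circ_diff(phi, mu) * DEG2RAD, sigma_rad)
        # mixture of equal weights; convert rad-density to per-degree density
        return acc / self.n_components * DEG2RAD

    def cdf_grid(self, n: int = 36000):
        """(grid_deg, cdf) pair on a uniform grid; used for inverse-CDF sampling."""
        grid = np.linspace(0.0, 360.0, n, endpoint=False)
        pdf = self.density(grid)
        cdf = np.cumsum(pdf) * (360.0 / n)
        cdf /= cdf[-1]
        return grid, cdf


def sample_prior(prior: EnvironmentPrior, n: int, rng) -> np.ndarray:
    """Draw ``n`` colors (degrees) from the environmental prior.

    Mixture sampling: pick a component uniformly, then a wrapped von Mises
    deviate around it. Accepts an ``np.random.Generator`` or an integer seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if prior.uniform:
        return rng.uniform(0.0, 360.0, size=n)
    kappa = 1.0 / (prior.sigma_s * DEG2RAD) ** 2
    comps = rng.integers(0, prior.n_components, size=n)
    mus = np.asarray(prior.common_colors)[comps]
    dev = rng.vonmises(0.0, kappa, size=n) / DEG2RAD
    return wrap_360(mus + dev)


@dataclass(frozen=True)
class TuningBank:
    """Bank of von Mises tuning curves with equally spaced preferred colors.

    Unit i prefers mu_p[i] = (360/n_units) * i. The response of unit i to a
    color phi is VM(phi - mu_p[i]; sigma_p^2) evaluated in radians, so the
    pattern peaks at ~1.5 for the default sigma_p = 15 degrees (half of the
    30-degree unit spacing).
    """

    n_units: int = 12
    sigma_p: float = 15.0

    @property
    def mu_p(self) -> np.ndarray:
        return np.arange(self.n_units) * (360.0 / self.n_units)

    def response(self, colors_deg):
        """Tuning pattern(s): shape (..., n_units)."""
        phi = np.asarray(colors_deg, dtype=float)
        d = circ_diff(phi[..., None], self.mu_p) * DEG2RAD
        return von_mises_pdf_rad(d, self.sigma_p * DEG2RAD)


def tuning_response(bank: TuningBank, color_deg) -> np.ndarray:
    """Noiseless perception pattern for one color (wrapped into range)."""
    return bank.response(wrap_360(color_deg))


@dataclass(frozen=True)
class EpochSchedule:
    """Trial timing in ms, discretized to dt steps with half-open boundaries.

    Epoch order: fixation, perception, delay, go, response. The readout window
    is [60 ms, 140 ms) inside the response epoch.
    """

    dt_ms: float = 20.0
    fixation_ms: float = 100.0
    perception_ms: float = 200.0
    delay_ms: float = 800.0
    go_ms: float = 60.0
    response_ms: float = 200.0

    def __post_init__(self):
        for name in ("fixation_ms", "perception_ms", "delay_ms", "go_ms", "response_ms"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be nonnegative, got {v}")
            steps = v / self.dt_ms
            if abs(steps - round(steps)) > 1e-9:
                raise ValueError(f"{name}={v} is not a multiple of dt={self.dt_ms}")

    def _steps(self, ms: float) -> int:
        return int(round(ms / self.dt_ms))

    @property
    def fixation_steps(self): return self._steps(self.fixation_ms)
    @property
    def perception_steps(self): return self._steps(self.perception_ms)
    @property
    def delay_steps(self): return self._steps(self.delay_ms)
    @property
    def go_steps(self): return self._steps(self.go_ms)
    @property
    def response_steps(self): return self._steps(self.response_ms)

    @property
    def boundaries(self):
        """Cumulative step boundaries (fix_end, perc_end, delay_end, go_end, T)."""
        f = self.fixation_steps
        p = f + self.perception_steps
        d = p + self.delay_steps
        g = d + self.go_steps
        t = g + self.response_steps
        return f, p, d, g, t

    @property
    def n_steps(self): return self.boundaries[4]

    @property
    def response_window(self):
        """Half-open step range of the [60, 140) ms readout window within response."""
        g_end = self.boundaries[3]
        lo = g_end + self._steps(60.0)
        hi = g_end + self._steps(140.0)
        if hi > self.n_steps:
            raise ValueError("response epoch shorter than the 60-140 ms readout window")
        return lo, hi

    def with_delay(self, delay_ms: float) -> "EpochSchedule":
        return replace(self, delay_ms=delay_ms)


@dataclass
class TrialBatch:
    """Input/target/mask tensors for a batch of trials, padded to max length.

    inputs:  (B, T, 13)  12 perception channels + 1 go channel
    targets: (B, T, 12)  0 outside the response epoch, tuning pattern inside
    mask:    (B, T)      0 during fixation and beyond trial end, 1 elsewhere
    noise_mask: (B, T)   1 where recurrent noise is injected (all non-fixation
                         in-trial steps), 0 during fixation/padding
    """

    inputs: np.ndarray
    targets: np.ndarray
    mask: np.ndarray
    noise_mask: np.ndarray
    input_colors: np.ndarray
    schedules: list
    bank: TuningBank = field(default_factory=TuningBank)

    @property
    def n_trials(self): return self.inputs.shape[0]

    @property
    def n_steps(self): return self.inputs.shape[1]

    def trial_lengths(self):
        return np.array([s.n_steps for s in self.schedules])

    def save(self, path):
        """Array archive plus an embedded JSON sidecar of schedule metadata."""
        import json
        from dataclasses import asdict
        meta = dict(schedules=[asdict(s) for s in self.schedules],
                    bank=dict(n_units=self.bank.n_units, sigma_p=self.bank.sigma_p))
        np.savez(path, inputs=self.inputs, targets=self.targets, mask=self.mask,
                 noise_mask=self.noise_mask, input_colors=self.input_colors,
                 meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8))

    @classmethod
    def load(cls, path) -> "TrialBatch":
        import json
        d = np.load(path)
        meta = json.loads(bytes(d["meta"]).decode())
        return cls(inputs=d["inputs"], targets=d["targets"], mask=d["mask"],
                   noise_mask=d["noise_mask"], input_colors=d["input_colors"],
                   schedules=[EpochSchedule(**s) for s in meta["schedules"]],
                   bank=TuningBank(**meta["bank"]))


@dataclass(frozen=True)
class NoiseConfig:
    """Trial noise model: perception noise sigma_x on the input channels during
    the perception epoch; recurrent noise sigma_rec inside the dynamics."""
    sigma_x: float = 0.2
    sigma_rec: float = 0.2


def build_trials(prior: EnvironmentPrior, bank: TuningBank, schedule: EpochSchedule,
                 n_trials: int, noise: NoiseConfig = NoiseConfig(), rng=0,
                 fixed_color: float | None = None,
                 delay_range_ms: tuple | None = None) -> TrialBatch:
    """Assemble a complete trial batch.

    ``fixed_color`` overrides prior sampling. ``delay_range_ms=(lo, hi)`` draws
    a per-trial delay uniformly over the dt-grid of [lo, hi]; otherwise every
    trial uses ``schedule.delay_ms``.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if fixed_color is not None:
        colors = np.full(n_trials, wrap_360(fixed_color), dtype=float)
    else:
        colors = sample_prior(prior, n_trials, rng)

    if delay_range_ms is not None:
        lo, hi = delay_range_ms
        lo_s, hi_s = int(round(lo / schedule.dt_ms)), int(round(hi / schedule.dt_ms))
        delay_steps = rng.integers(lo_s, hi_s + 1, size=n_trials)
        schedules = [schedule.with_delay(int(d) * schedule.dt_ms) for d in delay_steps]
    else:
        schedules = [schedule] * n_trials

    T = max(s.n_steps for s in schedules)
    n_in = bank.n_units + 1
    bounds = np.array([s.boundaries for s in schedules])  # (B, 5)
    f, p, d, g, t = (bounds[:, j][:, None] for j in range(5))
    ar = np.arange(T)[None, :]
    perc = (ar >= f) & (ar < p)
    go = (ar >= d) & (ar < g)
    resp = (ar >= g) & (ar < t)
    in_trial = (ar >= f) & (ar < t)

    patterns = bank.response(colors)  # (B, 12)
    inputs = np.zeros((n_trials, T, n_in))
    inputs[:, :, : bank.n_units] = perc[:, :, None] * patterns[:, None, :]
    if noise.sigma_x > 0:
        inputs[:, :, : bank.n_units] += (
            noise.sigma_x * perc[:, :, None]
            * rng.standard_normal((n_trials, T, bank.n_units)))
    inputs[:, :, bank.n_units] = go  # go pulse
    targets = resp[:, :, None] * patterns[:, None, :]
    mask = in_trial.astype(float)
    noise_mask = in_trial.astype(float)  # recurrent noise everywhere except fixation
    return TrialBatch(inputs, targets, mask, noise_mask, colors, schedules, bank)
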