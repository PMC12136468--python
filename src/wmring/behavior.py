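"""Behavioral analyses of trained models.

Circular error statistics, RMSE memory error with the 1.5 x IQR outlier rule,
output-distribution peak structure, attraction-slope fits around the common
colors, and delay-length sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .circular import circ_diff, nearest_common_color, wrap_360
from .task_env import (COMMON_COLORS, EnvironmentPrior, EpochSchedule, NoiseConfig,
                       TuningBank, build_trials)
from .rnn_core import output_color, rollout


def circular_error(input_deg, output_deg):
    """Signed circular error output - input, in (-180, 180]."""
    return circ_diff(output_deg, input_deg)


def iqr_filter(values: np.ndarray) -> np.ndarray:
    """Boolean mask keeping values within 1.5 x IQR of the quartiles."""
    v = np.asarray(values, dtype=float)
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    return (v >= q1 - 1.5 * iqr) & (v <= q3 + 1.5 * iqr)


@dataclass
class MemoryError:
    """RMSE of signed circular errors after 1.5 x IQR outlier removal."""
    rmse: float
    n_trials_used: int
    n_outliers_removed: int
    input_condition: str

    def __float__(self):
        return self.rmse


def rmse_from_errors(errors: np.ndarray, condition: str = "") -> MemoryError:
    """Apply the outlier rule to signed errors, then RMSE of the survivors."""
    errors = np.asarray(errors, dtype=float)
    keep = iqr_filter(errors)
    if not np.any(keep):
        raise ValueError("all trials removed by the outlier rule")
    return MemoryError(float(np.sqrt(np.mean(errors[keep] ** 2))),
                       int(keep.sum()), int((~keep).sum()), condition)


def _params_of(model):
    return model.params if hasattr(model, "params") else model


def run_trials(model, n_trials: int, delay_ms: float, rng,
               input_color: float | None = None,
               prior: EnvironmentPrior | None = None,
               noise_on: bool = True,
               schedule: EpochSchedule | None = None,
               bank: TuningBank = TuningBank()):
    """Roll out noisy (or noise-free) trials; returns (input colors, output colors)."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    params = _params_of(model)
    sched = (schedule or EpochSchedule()).with_delay(delay_ms)
    prior = prior or EnvironmentPrior(uniform=True)
    sigma_x = getattr(params, "sigma_x", 0.2) if noise_on else 0.0
    noise = NoiseConfig(sigma_x=sigma_x, sigma_rec=getattr(params, "sigma_rec", 0.2))
    batch = build_trials(prior, bank, sched, n_trials, noise, rng=rng,
                         fixed_color=input_color)
    if hasattr(model, "rollout"):        # fixture dynamics (e.g. replay network)
        traj = model.rollout(batch, noise_on=noise_on, rng=rng)
    elif hasattr(params, "rollout"):
        traj = params.rollout(batch, noise_on=noise_on, rng=rng)
    else:
        traj = rollout(params, batch, noise_on=noise_on, rng=rng)
    return batch.input_colors, output_color(traj)


def memory_error(model, input_color, n_trials: int = 500, delay_ms: float = 800.0,
                 rng=0, noise_on: bool = True) -> MemoryError:
    """Memory error at a fixed input color (or a prior when one is passed)."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if isinstance(input_color, EnvironmentPrior):
        ins, outs = run_trials(model, n_trials, delay_ms, rng, prior=input_color,
                               noise_on=noise_on)
        cond = "prior"
    else:
        ins, outs = run_trials(model, n_trials, delay_ms, rng,
                               input_color=float(input_color), noise_on=noise_on)
        cond = f"fixed:{float(input_color):g}"
    return rmse_from_errors(circular_error(ins, outs), cond)


def attraction_slope(model, delay_ms: float = 1000.0, n_trials: int = 1000,
                     window_deg: float = 15.0, rng=0,
                     common_colors=COMMON_COLORS,
                     data: tuple | None = None):
    """OLS slope of error vs input shifted by its nearest common color.

    Only data with shifted input in [-window, window] enter the fit; a negative
    slope means attraction toward the common colors. ``data=(inputs, outputs)``
    bypasses simulation.
    """
    if data is None:
        ins, outs = run_trials(model, n_trials, delay_ms, rng)
    else:
        ins, outs = (np.asarray(a, dtype=float) for a in data)
    shifted = circ_diff(ins, nearest_common_color(ins, common_colors))
    err = circular_error(ins, outs)
    sel = np.abs(shifted) <= window_deg
    if not np.any(sel):
        raise ValueError("no trials inside the fitting window")
    res = stats.linregress(shifted[sel], err[sel])
    return float(res.slope), float(res.intercept)


def _smoothed_circular_hist(angles_deg, n_bins, smooth_bins, bin_offset_deg=0.0):
    a = wrap_360(np.asarray(angles_deg, dtype=float) - bin_offset_deg)
    counts, edges = np.histogram(a, bins=n_bins, range=(0.0, 360.0))
    kernel = np.ones(smooth_bins) / smooth_bins
    ext = np.concatenate([counts[-(smooth_bins // 2):], counts,
                          counts[: smooth_bins // 2]])
    return np.convolve(ext, kernel, mode="valid"), (edges[:-1] + edges[1:]) / 2.0


def _circular_peak_bins(sm: np.ndarray) -> np.ndarray:
    """Indices of local maxima of a circular sequence above its mean.

    Runs of equal values (plateaus, produced by boxcar smoothing of spiky
    histograms) count as one peak, located at the plateau center.
    """
    n = sm.size
    # collapse plateaus: indices of run starts
    starts = [0]
    for i in range(1, n):
        if sm[i] != sm[starts[-1]]:
            starts.append(i)
    # merge circular wrap if first and last runs are equal-valued
    if len(starts) > 1 and sm[starts[0]] == sm[starts[-1]]:
        starts = starts[:-1]
        wrap_run = True
    else:
        wrap_run = False
    k = len(starts)
    if k == 1:
        return np.array([], dtype=int)
    mean = sm.mean()
    peaks = []
    for j, s in enumerate(starts):
        prev_val = sm[starts[(j - 1) % k]]
        next_val = sm[starts[(j + 1) % k]]
        val = sm[s]
        if val > prev_val and val > next_val and val > mean:
            end = starts[(j + 1) % k]
            run_len = (end - s) % n or n
            peaks.append((s + run_len // 2) % n)
    return np.array(sorted(peaks), dtype=int)


def count_histogram_peaks(angles_deg, n_bins: int = 72, smooth_bins: int = 5,
                          bin_offset_deg: float = 0.0) -> int:
    """Number of local maxima of a smoothed circular histogram that exceed the
    mean density (circular moving-average smoothing; plateaus count once)."""
    sm, _ = _smoothed_circular_hist(angles_deg, n_bins, smooth_bins, bin_offset_deg)
    return int(_circular_peak_bins(sm).size)


def peak_locations(angles_deg, n_bins: int = 72, smooth_bins: int = 5):
    """Bin-center angles of the smoothed-histogram peaks (same rule as
    count_histogram_peaks)."""
    sm, centers = _smoothed_circular_hist(angles_deg, n_bins, smooth_bins)
    return centers[_circular_peak_bins(sm)]


def delay_sweep(model, delays_ms, n_trials: int = 1000, rng=0) -> pd.DataFrame:
    """Per-delay memory error (uniform input sampling) and attraction slope."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    rows = []
    for d in delays_ms:
        ins, outs = run_trials(model, n_trials, float(d), rng)
        err = circular_error(ins, outs)
        me = rmse_from_errors(err, "uniform")
        try:
            slope, _ = attraction_slope(model, data=(ins, outs))
        except ValueError:
            slope = np.nan
        rows.append(dict(delay_ms=float(d), rmse=me.rmse, slope=slope,
                         n_used=me.n_trials_used))
    return pd.DataFrame(rows)


def error_profile(model, input_grid, n_trials: int = 500, delay_ms: float = 800.0,
                  rng=0) -> pd.DataFrame:
    """Per-input-color memory error (outliers removed per color)."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    rows = []
    for c in input_grid:
        me = memory_error(model, float(c), n_trials, delay_ms, rng)
        rows.append(dict(input_color=float(c), rmse=me.rmse, n_used=me.n_trials_used))
    return pd.DataFrame(rows)


def rank_sum_test(a, b, alternative: str = "two-sided"):
    """Wilcoxon rank-sum between two groups of per-model statistics."""
    return stats.ranksums(np.asarray(a, float), np.asarray(b, float),
                          alternative=alternative)


def signed_rank_test(values, alternative: str = "two-sided"):
    """Wilcoxon signed-rank of per-model statistics against zero (e.g. mean
    trial error at a common color)."""
    return stats.wilcoxon(np.asarray(values, float), alternative=alternative)
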