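"""Cross-decoding: prepare end-of-delay states with one model and decode them
with another.

Two transfer methods map Model 1's recurrent state vector into Model 2's
state space: (a) one-to-one neural matching by preferred-color rank, and
(b) rotation/reflection-scaling-translation (RTS) alignment, a closed-form
Procrustes-family fit minimizing the Frobenius distance between two state
clouds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .behavior import MemoryError, rank_sum_test, rmse_from_errors
from .circular import circ_diff
from .occupancy_theory import rnn_decode
from .rnn_core import NetworkParams
from .state_geometry import collect_states, fit_plane


@dataclass
class PreferredColorTable:
    """Per-neuron preferred color and the rank order of neurons by it."""
    preferred: np.ndarray   # (n_rec,) degrees
    ranks: np.ndarray       # (n_rec,) permutation: ranks[i] = rank of neuron i

    @property
    def order(self) -> np.ndarray:
        """Neuron indices sorted by preferred color (stable in index)."""
        return np.argsort(self.preferred, kind="stable")


def preferred_colors(params: NetworkParams, delay_ms: float = 800.0,
                     n_trials: int = 1000, rng=0, n_ring: int = 360) -> PreferredColorTable:
    """Preferred color of each recurrent neuron via the delay-ring procedure.

    Fit the delay plane on random-color trials, resample a dense ring at the
    mean radius, decode each ring state through go + response, and assign each
    neuron the decoded color at which its activation is maximal. (Probing with
    ring states rather than raw inputs sidesteps the drift of biased networks
    toward attractors during the delay.)
    """
    states, _ = collect_states(params, n_trials, delay_ms, rng)
    if np.allclose(states.var(axis=0).sum(), 0.0):
        raise ValueError("degenerate state cloud: zero variance")
    plane = fit_plane(states, source="delay")
    from .state_geometry import manifold_ring
    try:
        ring, _ = manifold_ring(states, plane, n_bins=min(n_ring, 72))
    except ValueError:
        ring = plane.ring_states(n_ring)
    colors = rnn_decode(params, ring)          # (n_ring,)
    best = np.argmax(ring, axis=0)             # per-neuron ring index of max activation
    pref = colors[best]
    order = np.argsort(pref, kind="stable")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(order.size)
    return PreferredColorTable(preferred=pref, ranks=ranks)


@dataclass
class RTSTransform:
    """Orthogonal (rotation or reflection) + uniform scale + translation."""
    R: np.ndarray        # (d, d) orthogonal
    s: float
    t: np.ndarray        # (d,)

    @property
    def det_R(self) -> float:
        return float(np.sign(np.linalg.det(self.R)))

    def apply(self, X: np.ndarray) -> np.ndarray:
        """Y_hat = s X R^T + t for row-vector states X (n, d)."""
        return self.s * np.asarray(X) @ self.R.T + self.t


def fit_rts(X: np.ndarray, Y: np.ndarray) -> RTSTransform:
    """Closed-form least-squares alignment of cloud X onto cloud Y.

    R = U V^T from the SVD of M = Yc^T Xc; s = trace(Sigma) / sum |xc_i|^2;
    t = mu_y - s R mu_x. det(R) may be -1 (reflection); no sign correction.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim != 2 or X.shape != Y.shape or X.shape[0] < 2:
        raise ValueError("X and Y must be (n, d) with n >= 2 and equal shapes")
    mu_x = X.mean(axis=0)
    mu_y = Y.mean(axis=0)
    Xc = X - mu_x
    Yc = Y - mu_y
    denom = np.sum(Xc**2)
    if denom < 1e-30:
        raise ValueError("zero-variance X cloud")
    M = Yc.T @ Xc
    U, S, Vt = np.linalg.svd(M)
    R = U @ Vt
    s = float(np.sum(S) / denom)
    t = mu_y - s * R @ mu_x
    return RTSTransform(R=R, s=s, t=t)


def rank_transfer(states: np.ndarray, table1: PreferredColorTable,
                  table2: PreferredColorTable) -> np.ndarray:
    """Copy activations between rank-matched neurons (Model 1 -> Model 2)."""
    states = np.atleast_2d(np.asarray(states, dtype=float))
    if table1.preferred.size != table2.preferred.size:
        raise ValueError("models have different numbers of neurons")
    out = np.empty_like(states)
    # neuron of model 2 with rank k receives the activation of the model-1
    # neuron with rank k
    out[:, table2.order] = states[:, table1.order]
    return out


def _states_for_colors(params, colors, delay_ms, rng):
    """End-of-delay states of noisy trials at prescribed input colors."""
    from .task_env import (EnvironmentPrior, EpochSchedule, NoiseConfig,
                           TuningBank, build_trials)
    from .rnn_core import rollout
    bank = TuningBank()
    sched = EpochSchedule(delay_ms=delay_ms)
    batch = build_trials(EnvironmentPrior(uniform=True), bank, sched,
                         len(colors), NoiseConfig(params.sigma_x, params.sigma_rec),
                         rng=rng)
    f, p, d, g, t = sched.boundaries
    patterns = bank.response(np.asarray(colors, dtype=float))
    noise = batch.inputs[:, f:p, : bank.n_units] - bank.response(batch.input_colors)[:, None, :]
    batch.inputs[:, f:p, : bank.n_units] = patterns[:, None, :] + noise
    batch.input_colors = np.asarray(colors, dtype=float)
    traj = rollout(params, batch, noise_on=True, rng=rng)
    return traj.states_at("end_of_delay")


def cross_decode_pair(model1, model2, matcher: str = "rts",
                      input_color: float = 40.0, delay_ms: float = 800.0,
                      n_trials: int = 500, n_fit_trials: int = 1000,
                      rng=0, transfer_rates: bool = False) -> MemoryError:
    """One Model 1 -> Model 2 cross-decoding run.

    Model 1 runs fixation through delay at a fixed common color; its
    end-of-delay states are mapped into Model 2's state space (by rank
    matching or by an RTS fit on random-color state clouds), and Model 2 runs
    go + response only. Memory error is the RMSE after the 1.5 x IQR rule.
    By default the transferred quantity is the pre-activation state x;
    ``transfer_rates`` maps tanh(x) instead.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    p1 = model1.params if hasattr(model1, "params") else model1
    p2 = model2.params if hasattr(model2, "params") else model2

    if matcher == "rank":
        if p1.n_rec != p2.n_rec:
            raise ValueError("rank matching requires equal network sizes")
        t1 = preferred_colors(p1, delay_ms, n_fit_trials, rng)
        t2 = preferred_colors(p2, delay_ms, n_fit_trials, rng)
        transfer = lambda s: rank_transfer(s, t1, t2)
    elif matcher == "rts":
        # paired clouds: the same sampled colors drive both models, so row i
        # of X and Y encode the same color and the closed-form fit aligns the
        # two rings pointwise
        from .task_env import EnvironmentPrior, sample_prior
        colors = sample_prior(EnvironmentPrior(uniform=True), n_fit_trials, rng)
        X = _states_for_colors(p1, colors, delay_ms, rng)
        Y = _states_for_colors(p2, colors, delay_ms, rng)
        if transfer_rates:
            X, Y = np.tanh(X), np.tanh(Y)
        rts = fit_rts(X, Y)
        transfer = rts.apply
    else:
        raise ValueError(f"unknown matcher {matcher!r}; use 'rank' or 'rts'")

    X_hat, _ = collect_states(p1, n_trials, delay_ms, rng,
                              fixed_color=float(input_color))
    if transfer_rates:
        Y_hat = np.arctanh(np.clip(transfer(np.tanh(X_hat)), -0.999999, 0.999999))
    else:
        Y_hat = transfer(X_hat)
    outs = rnn_decode(p2, Y_hat)
    return rmse_from_errors(circ_diff(outs, input_color),
                            f"{matcher}:{input_color:g}")


def cross_decode_experiment(pool_biased: list, pool_uniform: list,
                            matcher: str = "rts", n_pairs: int = 50,
                            input_color: float = 40.0, delay_ms: float = 800.0,
                            n_trials: int = 500, n_fit_trials: int = 1000,
                            rng=0, share_fit_data: bool = True) -> pd.DataFrame:
    """Sample Model 1-Model 2 pairs per category combination (B&B, B&U, U&B,
    U&U) and collect per-pair memory errors.

    With ``share_fit_data`` (default) the fit clouds, preferred-color tables,
    and fixed-color source states are computed once per model on a common
    color sample and reused across pairs — a variance-reduction that leaves
    each pair's statistic unchanged in expectation and makes large pair
    counts affordable. Set False to resample everything per pair.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    pools = {"B": pool_biased, "U": pool_uniform}
    if not pool_biased or not pool_uniform:
        raise ValueError("both pools must be nonempty")
    rows = []
    if not share_fit_data:
        for c1 in ("B", "U"):
            for c2 in ("B", "U"):
                for k in range(n_pairs):
                    i = int(rng.integers(len(pools[c1])))
                    j = int(rng.integers(len(pools[c2])))
                    if c1 == c2 and len(pools[c1]) > 1:
                        while j == i:
                            j = int(rng.integers(len(pools[c2])))
                    me = cross_decode_pair(pools[c1][i], pools[c2][j], matcher,
                                           input_color, delay_ms, n_trials,
                                           n_fit_trials, rng)
                    rows.append(dict(combo=f"{c1}&{c2}", model1=i, model2=j,
                                     rmse=me.rmse, matcher=matcher))
        return pd.DataFrame(rows)

    from .task_env import EnvironmentPrior, sample_prior
    fit_colors = sample_prior(EnvironmentPrior(uniform=True), n_fit_trials, rng)
    cache = {}
    for c, pool in pools.items():
        for i, model in enumerate(pool):
            p = model.params if hasattr(model, "params") else model
            entry = dict(params=p)
            entry["fit_cloud"] = _states_for_colors(p, fit_colors, delay_ms, rng)
            entry["source"] = _states_for_colors(
                p, np.full(n_trials, float(input_color)), delay_ms, rng)
            if matcher == "rank":
                entry["table"] = preferred_colors(p, delay_ms, n_fit_trials, rng)
            cache[(c, i)] = entry
    for c1 in ("B", "U"):
        for c2 in ("B", "U"):
            for k in range(n_pairs):
                i = int(rng.integers(len(pools[c1])))
                j = int(rng.integers(len(pools[c2])))
                if c1 == c2 and len(pools[c1]) > 1:
                    while j == i:
                        j = int(rng.integers(len(pools[c2])))
                e1, e2 = cache[(c1, i)], cache[(c2, j)]
                if matcher == "rank":
                    y_hat = rank_transfer(e1["source"], e1["table"], e2["table"])
                elif matcher == "rts":
                    rts = fit_rts(e1["fit_cloud"], e2["fit_cloud"])
                    y_hat = rts.apply(e1["source"])
                else:
                    raise ValueError(f"unknown matcher {matcher!r}")
                outs = rnn_decode(e2["params"], y_hat)
                me = rmse_from_errors(circ_diff(outs, input_color), matcher)
                rows.append(dict(combo=f"{c1}&{c2}", model1=i, model2=j,
                                 rmse=me.rmse, matcher=matcher))
    return pd.DataFrame(rows)


def combo_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Median per category combination plus rank-sum p-values of the two
    headline contrasts (U&B vs U&U, B&B vs B&U)."""
    med = table.groupby("combo")["rmse"].median()
    out = med.rename("median_rmse").reset_index()
    def p(a, b):
        return rank_sum_test(table.query("combo == @a")["rmse"],
                             table.query("combo == @b")["rmse"]).pvalue
    out.attrs["p_UB_vs_UU"] = float(p("U&B", "U&U"))
    out.attrs["p_BB_vs_BU"] = float(p("B&B", "B&U"))
    return out
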