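# Methods

## Task and environment

A trial has five epochs — fixation, perception, delay, go, response — on a
20 ms step grid. During perception, the stimulus color φ_s drives 12
perception channels through von Mises tuning curves with preferred colors
μ_i = 30°·i and width σ_p, plus Gaussian noise of std σ_x. All inputs are
zero during the delay; the go channel is 1 during the 60 ms go epoch; the
readout target during the 200 ms response epoch is the noiseless tuning
pattern of the stimulus. The loss mask is 0 during fixation and 1 elsewhere.

The environmental prior is an equal-weight mixture of four von Mises bumps at
the common colors {40°, 130°, 220°, 310°} with width σ_s (degrees are the
external unit everywhere; radians appear only inside von Mises kernels, with
κ = 1/σ_rad²). The uniform environment is implemented as an explicit uniform
density; the wide mixture at σ_s = 90° approximates it and is also available.
The delay length is drawn per trial from U(0 ms, 1000 ms) during training;
analyses fix it (800 ms unless stated).

**σ_p = 15°** (half the 30° channel spacing). Consequences worth knowing:
with 12 equally spaced channels, the channel sum is constant in color only up
to the 12th circular harmonic (a ~3% ripple), and the population-vector
readout inverts a noiseless tuning pattern *exactly* only at multiples of
15°, with a bounded aliasing bias (< 0.8°) elsewhere. Tests assert the exact
property on the symmetric grid and the computed bound off it.

Fixation (100 ms) and perception (200 ms) durations are package defaults
chosen to keep trials short; both are configurable.

## Network and training

The dynamics are

    x_t = (1−α) x_{t−1} + α ( W_rec tanh(x_{t−1}) + W_in u_t
                              + √(2 σ_rec²/α) ε_t + b ),   α = dt/τ = 1,

with zero recurrent diagonal re-imposed after every optimizer step, and
readout z_t = W_out tanh(x_t) + b_out. The noise coefficient is the standard
Ornstein–Uhlenbeck discretization (per-step std √2·σ_rec at α = 1); recurrent
noise is injected at every non-fixation step. The initial state is x_0 = 0.

The loss per trial is

    L = (1/T) Σ_t m_t [ |z_t − z̃_t|² + (1/N)(β T |W_rec|²_F + γ |r_t + 1|²) ],

batch-averaged; the rate penalty pulls firing rates toward −1 (silence).
Gradients are exact backpropagation-through-time derived by hand and
implemented in numpy (float32 inside the kernel, float64 master weights in a
hand-rolled deterministic Adam), verified elementwise against central finite
differences. Gradients are clipped to global norm 1.

Training is progressive: (1) no noise, no regularization, uniform prior,
zero delay; (2) variable delay, with the upper bound ramped linearly from
~one step to 1000 ms over the first half of the stage — without this ramp a
substantial fraction of reduced-scale seeds never learn to hold memory;
(3) noise and regularization on, producing the prior-agnostic *pretrained*
checkpoint; (4) retraining under the final prior (uniform → Uniform model,
von Mises mixture → Biased model). Uniform and Biased models consume the same
number of trials; ensembles share the pretrained checkpoint per seed, and
noise sweeps share the two noise-free stages. Each stage draws one shared
delay per batch (padding-free); across updates the delay distribution is the
same uniform grid as per-trial draws.

Defaults at reduced scale: N = 64 units, batch 64, Adam lr 2·10⁻³ for the
noise-free stages and 10⁻³ for the noisy ones, β = γ = 10⁻⁴, stage updates
(800, 1500, 800, 1200), σ_x = σ_rec = 0.2. The regularization constants,
learning rates, and update counts are not constrained by any reported value;
they were chosen so that the reduced-scale protocol trains reliably across
seeds. All randomness flows through named integer seeds with one independent
stream per stage.

## Behavioral statistics

Signed circular error (output − input) lives in (−180°, 180°]; memory error
is the RMSE after removing trials beyond 1.5×IQR of the error distribution.
The attraction slope is the OLS slope of error against input-relative-to-
nearest-common-color, fitted over ±15°. Output-distribution peaks are counted
on a 72-bin circular histogram smoothed with a 5-bin circular boxcar: local
maxima above the mean density, with equal-valued plateau runs (which the
boxcar creates from spike-like histograms) counted once at their center.

## State-space analyses

**Planes.** The delay plane is the top-2 PCA plane of end-of-delay states
over noisy random-color trials; the response plane that of start-of-response
states. The ring radius is the mean in-plane distance of the fitting states
to their center.

**Ring probes and curvature.** At 64 units the delay manifold is visibly
curved: two PCs capture only ~70–85% of end-of-delay variance (tanh
saturation puts part of the ring into higher harmonics), so a flat circle on
the PCA plane can sit far off the manifold and decode arbitrarily. The
package therefore probes the ring *along the data manifold*: states are
binned by plane angle, bin means (in the full state space) are circularly
smoothed and densified by periodic interpolation, giving probe states that
hug the manifold while the angle parameter remains the plane angle. The flat
plane circle is available as an option (`probe_kind="circle"`), and is used
where a full-dimensional reconstruction from an angle alone is required.

**Fixed points.** The autonomous (zero-input, noise-free) velocity
F(x) = α(W_rec tanh(x) + b − x) is minimized in squared norm with Adam
(lr 10⁻², up to 5000 iterations, tolerance |F| < 10⁻⁵ per step) from
start-of-delay states of equally spaced colors; converged points are
deduplicated (radius 0.1) and kept only near the delay ring (within 2× the
radial spread of the fitting cloud). The Jacobian
J = α(W_rec diag(1−r²) − I) is analytic; a fixed point is an attractor if
all eigenvalue real parts are negative, a saddle if any is positive, neutral
otherwise. All Jacobians are cross-checked against central finite
differences; a planted ring-attractor fixture with closed-form spectra
validates the full search.

**RNN decoder and angle-to-color map.** Any recurrent state can be decoded
by re-entering the network and running go + response with noise off (exactly
the tail of a full rollout — the splice property is asserted to machine
precision). Decoding the manifold ring gives φ(θ); after detecting the
traversal direction and unwrapping to a monotone cover (more than one jump
above 180° raises a fold-over error), the cover is lightly smoothed (~4.5° of
ring angle), inverted to θ(φ) on a uniform color grid, and differentiated by
centered finite differences. Working on the inverse makes the conservation
law ∮ (dθ/dφ) dφ = 360° hold by construction and places decoder plateaus
(attractor basins) as occupancy spikes at their colors, which is the correct
physics. Because reduced-scale decoders are piecewise-flat combs rather than
smooth maps, pointwise occupancy at an exact color is ill-conditioned;
`occupancy_at` therefore reports the window-averaged slope
(θ(c+w) − θ(c−w))/2w with w = 10° by default (w = 0 recovers the raw grid
value; on smooth analytic warps the windowed and pointwise values agree to
well under 1%).

**Dispersion and the error decomposition.** Dynamic dispersion is the
variance (deg²) of delay-plane angles of end-of-delay states over repeated
noisy fixed-color trials, after unwrapping about the circular mean and the
1.5×IQR rule. The anchor θ_c is the map's angle at the common color. The
theoretical error is

    ε² = (dφ/dθ|φ_c)² · dispersion + (dφ/dθ|φ_c)² · (θ̄ − θ_c)²,

an internal identity of the assembled object; the scientific tests are the
exact linear case (ε = a·s), Monte-Carlo agreement on synthetic pipelines,
and theory-vs-simulation tracking on trained ensembles. The
occupancy-ablated comparison sets dφ/dθ ≡ 1. In condition sweeps the trend
statistics aggregate occupancy (mean) and dispersion (median) over all four
common colors per model, which substantially stabilizes small-ensemble
medians; models whose angle-to-color map degenerates (see limitations) are
recorded as NaN rows rather than silently dropped.

## Cross-decoding

End-of-delay states of Model 1 (fixed common-color input, 500 noisy trials)
are mapped into Model 2's state space and decoded by Model 2's go + response.
Two transfer methods:

- **Rank matching**: each neuron's preferred color is the decoded color (via
  the manifold-ring procedure) at which its activation peaks; neurons are
  paired across models by rank of preferred color and activations copied
  between partners. Pre-activation states x are transferred (a flag selects
  rates instead).
- **RTS alignment**: the closed-form rotation/reflection R = UVᵀ (SVD of
  Yᶜᵀ Xᶜ), uniform scale s = trace(Σ)/Σ|xᶜ|², and translation t = μ_y − sRμ_x
  minimizing ‖Y − (sXRᵀ + t)‖_F. The clouds are *paired*: the same sampled
  colors drive both models, so row i of X and Y represent the same color —
  without pairing the cross-covariance carries no alignment information and
  the fit is meaningless. det(R) = −1 (reflection) is allowed. The fit is
  validated against an independent orthogonal-Procrustes implementation and
  exact family-member recovery.

Experiment-level runs compute per-model artifacts once on a shared color
sample and reuse them across sampled pairs (a variance reduction only);
per-pair resampling is available behind a flag.

## Post-delay dissection

Uniform rings of states are evolved through one epoch with noise off; the
coefficient of variation (std/mean of 36-binned angle distributions, scale
free) measures clustering after the go epoch and of representative states
(states time-averaged over the whole response epoch — deliberately not the
60–140 ms readout window). The readout decoder (W_out tanh(x) + b_out, then
the population vector, no dynamics) has its own angular occupancy on the
response plane, with the same conservation machinery.

Process isolation replaces two of the three post-delay processes (go
dynamics, response dynamics, readout) with uniform angle shifts anchored by
a chain θ_c ~ α_c ~ β_c ~ φ_c estimated from random-color trials whose output
falls near the chosen common color (the matching window widens automatically,
up to 45°, when a model's outputs cluster away from the requested color).
Angles are lifted to full states along the stage's data-manifold ring
(falling back to the flat plane circle when the ring cannot be traced), and
the remaining process runs in the network. The reported RMSE is taken about
the anchor angle's own output, so the estimate is insensitive to a shared
offset of the trial-estimated anchors and a zero spread gives exactly zero.

## Synthetic fixtures

- `PlantedRingNet`: an orthonormally embedded 2-D polar map with k attractors
  and k saddles at known angles, known contraction rates, and a closed-form
  Jacobian — ground truth for the fixed-point search, classification, and
  plane fitting.
- `WarpMap`: a monotone circular bijection built from a mixture-of-von-Mises
  CDF with an analytic derivative — ground truth for angular occupancy
  (occupancy = 360·pdf, peaking exactly at the mixture centers; zero
  concentration is the identity map).
- `ReplayNet`: stores the perception pattern and replays it during the
  response epoch — an end-to-end harness giving (aliasing-bounded) zero
  memory error with noise off.

These emulate the analysis-facing structure of trained networks (a ring of
states, a decode map, trial batches) but none of their learned dynamics, so
passing fixture tests validates the measurement machinery, not the biology.

## Reduced scale: what transfers and what does not

The original study scale (256 units, 50 models per condition, tens of
thousands of updates) is replaced by 64-unit networks, ensembles of 3–6
models, and a few thousand updates; the acceptance script and test suite run
on one CPU in tens of minutes. The qualitative structure survives: Biased
networks are several-fold more precise at common colors, attract nearby
inputs, form attractors near common colors, have higher occupancy and lower
dispersion there, and every post-delay process contributes to the error
reduction. Known scale artifacts, all visible in the code's measurements
rather than hidden:

- **Curvature.** Two PCs capture ~70–85% (not >90%) of delay-epoch variance
  at 64 units; the manifold-ring probe exists precisely for this.
- **Degenerate maps.** For a minority of models (especially σ_s = 3°, where
  the delay states collapse onto four tight clusters) the plane-angle
  parameterization fails to wind monotonically and the angle-to-color map
  raises rather than returning nonsense; sweeps record these as NaN.
- **Attractor doublets.** Biased models at moderate σ_s often develop *two*
  attractors flanking each common color (~±10°), so pooled output histograms
  show doublet fine structure around each common color instead of a single
  peak per color.
- **Discrete attractors in Uniform models.** Reduced-scale Uniform networks
  form ~8–10 discrete attractors rather than a quasi-continuous ring, which
  compresses their dynamic dispersion and makes their occupancy a comb; the
  windowed occupancy estimator and four-color aggregation address this.
- **Rank matching.** One-to-one neural matching by preferred-color rank
  relies on the two models' preferred-color distributions being similar,
  which concentrates well only at larger N; at 64 units individual transfers
  are hit-or-miss even though the RTS route is robust.
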