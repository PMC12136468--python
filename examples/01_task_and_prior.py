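"""The color delayed-response task: environmental prior, tuning, trials.

Samples colors from a biased environment (four common colors), encodes one
through the von Mises tuning bank, and assembles a trial batch.
"""

import numpy as np

from wmring import (EnvironmentPrior, EpochSchedule, NoiseConfig, TuningBank,
                    build_trials, sample_prior, tuning_response)

prior = EnvironmentPrior(sigma_s=12.5)
colors = sample_prior(prior, 10_000, rng=0)
hist, edges = np.histogram(colors, bins=8, range=(0, 360))
print("prior sample histogram (45-degree bins):")
for lo, n in zip(edges[:-1], hist):
    print(f"  [{lo:5.0f}, {lo+45:5.0f}) {'#' * (n // 200)} {n}")
print("-> mass concentrates near the common colors 40, 130, 220, 310.\n")

bank = TuningBank()
pattern = tuning_response(bank, 40.0)
print("tuning pattern for color 40 deg (peaks at the unit preferring 30-60):")
print("  " + " ".join(f"{v:.2f}" for v in pattern))

sched = EpochSchedule(delay_ms=800.0)
batch = build_trials(prior, bank, sched, n_trials=5, noise=NoiseConfig(),
                     rng=1)
f, p, d, g, t = sched.boundaries
print(f"\ntrial structure at dt=20 ms: fixation [0,{f}), perception [{f},{p}),"
      f" delay [{p},{d}), go [{d},{g}), response [{g},{t})")
print(f"sampled input colors: {np.round(batch.input_colors, 1)}")
print("the go channel is active only during the go epoch:",
      bool(np.all(batch.inputs[:, d:g, 12] == 1)))
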