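"""Simulate the three clinical MS courses with the damage ODE.

Each subtype preset fixes the five rate constants (remyelination km,
acute transection kmd, chronic degeneration kd, capacity growth delta and
cooperativity q) and its attack statistics; the script integrates 20 years
of disease and prints the EDSS milestones each course reaches.
"""

import numpy as np

from msdamage import DAYS_PER_MONTH, EDSS_MAX, archetype_presets, build_lambda, simulate, ModelState
from msdamage.inflammatory import sample_pulse_train

rng = np.random.default_rng(7)
t_grid = np.arange(0.0, 20 * 365.25, 10.0)
kei = EDSS_MAX / 0.9

print(f"{'course':8} {'attacks':>7} {'EDSS@5y':>8} {'EDSS@10y':>9} {'EDSS@20y':>9}  regime")
for name in ("RRMS", "SPMS", "PPMS"):
    a = archetype_presets()[name]
    train = sample_pulse_train(
        a.interval_distribution(), a.amplitude_sampler(),
        horizon=t_grid[-1], rng=rng, amp_scale=a.amp_scale,
    )
    traj = simulate(a.params, build_lambda(train), ModelState.healthy(0.9), t_grid, step=1.0)
    edss = kei * traj.edss_s
    at = lambda yr: edss[np.searchsorted(t_grid, yr * 365.25)]
    regime = "degeneration-led (D>Ad)" if np.all(traj.d[1:] >= traj.ad[1:]) else "relapse-led (Ad>D phases)"
    print(f"{name:8} {train.n_events:7d} {at(5):8.1f} {at(10):9.1f} {edss[-1]:9.1f}  {regime}")

print(
    "\nHigher kd/kmd with weaker remyelination (PPMS) makes cumulative axon\n"
    "loss D dominate from onset; the RRMS preset shows reversible EDSS\n"
    "excursions while demyelinated axons (Ad) transiently exceed D."
)
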