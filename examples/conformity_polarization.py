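"""Conformity on a small world: rewiring turns polarization into consensus.

Builds the canonical 500-agent small world (k=10) with a correlated initial
score field (75% pro / 25% anti), runs the asynchronous theta-step learning
process at three rewiring probabilities, and prints the share of agents
ending anti-behaviour plus the final/initial score-variance ratio. Low
rewiring lets clusters reinforce themselves (variance grows: polarization);
higher rewiring lets the pro majority reach into anti clusters (consensus).
"""

import numpy as np

from crowdsim.conformity import ConformityConfig, run_learning
from crowdsim.networks import SmallWorldConfig

N_SEEDS = 5

print(f"{'p':>5} {'anti initial':>13} {'anti final':>11} {'variance ratio':>15}")
for p in (0.1, 0.2, 0.3):
    anti_i, anti_f, vr = [], [], []
    for seed in range(N_SEEDS):
        cfg = ConformityConfig(
            network_config=SmallWorldConfig(n_nodes=500, degree=10, rewiring_prob=p),
            seed=seed,
        )
        m = run_learning(cfg).metrics()
        anti_i.append(m["fraction_anti_initial"])
        anti_f.append(m["fraction_anti_final"])
        vr.append(m["variance_ratio"])
    print(
        f"{p:5.1f} {np.mean(anti_i):13.3f} {np.mean(anti_f):11.3f} {np.mean(vr):15.2f}"
    )

print(
    "\nEveryone starts with ~25% anti agents; more rewiring shrinks the "
    "entrenched anti group until almost all agents finish pro-behaviour."
)
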