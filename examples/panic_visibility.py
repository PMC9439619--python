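"""Panic-buying cascades: how product visibility sets the equilibrium.

Draws normally distributed panic thresholds scaled by 1/v, runs the
synchronous cascade to equilibrium for a low-, mid-, and high-visibility
product, and compares each simulated equilibrium with the analytic fixed
point f = Phi((v f - mu) / sigma). About 10% of consumers panic at the
start regardless of v; visibility decides whether that seed stays contained
or cascades to (almost) everyone.
"""

from crowdsim.panic import PanicConfig, analytic_fixed_point, run_cascade

print(f"{'v':>5} {'initial':>8} {'equilibrium':>12} {'fixed point':>12} {'rounds':>7}")
for v in (0.2, 0.5, 1.0, 1.5, 2.0):
    res = run_cascade(PanicConfig(n_consumers=10_000, visibility=v, seed=1))
    fp = analytic_fixed_point(v)
    print(
        f"{v:5.1f} {res.initial_fraction:8.3f} {res.equilibrium_fraction:12.3f} "
        f"{fp:12.3f} {res.rounds_to_equilibrium:7d}"
    )

print(
    "\nLow-visibility products stay near the 10% trigger; past the tipping "
    "region (v ~ 0.6) the cascade sweeps in nearly the whole population."
)
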