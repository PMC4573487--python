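"""Classify the batch-culture outcome of each social interaction.

Integrates the well-mixed two-species model (shared Monod nutrient,
interaction factors 1 - xi*density) from initial ratios on both sides of
the diagonal and prints the phase-diagram outcome per interaction, plus the
mutualistic convergence to 1:1 from a 7-fold imbalance.
"""

from socolony.wellmixed import DEFAULT_N0, OdeParams, OdeState, classify_outcome, integrate

WIRINGS = {
    "control": (0.0, 0.0),
    "commensalism": (-0.6, 0.0),
    "amensalism": (+0.6, 0.0),
    "competition": (+0.6, +0.6),
    "mutualism": (-0.6, -0.6),
    "parasitism": (-0.6, +0.6),
}

print(f"{'interaction':<14}{'(xi1, xi2)':<16}outcome")
for name, (xi1, xi2) in WIRINGS.items():
    outcome = classify_outcome(OdeParams(xi1=xi1, xi2=xi2))
    print(f"{name:<14}({xi1:+.1f}, {xi2:+.1f})   {outcome}")

print("\nmutualism from a 1:7 start (total biomass 0.01, nutrient budget "
      f"{DEFAULT_N0:g}):")
traj = integrate(OdeState(DEFAULT_N0, 0.00125, 0.00875), OdeParams(xi1=-0.6, xi2=-0.6))
final = traj.iloc[-1]
print(f"  final u = {final.u:.4g}, v = {final.v:.4g}, ratio u:v = {final.u / final.v:.4f}")
print("  the public-good coupling lets the minority catch up exactly to 1:1")
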