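"""Recover a per-arm constant PD-L1 propensity from synthetic data.

Generates one noiseless arm (NHS-muIL12 2 μg) from a known constant
ϵ = 250, then fits ϵ by bound-constrained least squares with seeded
Latin-hypercube multi-starts and reports the estimate and residual error.
"""

from pdl1dyn import BaseParams, ExperimentDesign, NoiseModel, fit_constant_eps, generate_arm

eps_true = 250.0
design = ExperimentDesign(variant="constant", constant_eps={"b": eps_true})
data = generate_arm(design, "b", NoiseModel(kind="none"))

fit = fit_constant_eps(data, BaseParams(), restarts=6, seed=0)
eps_hat = fit.params["eps"]
print(f"true eps      : {eps_true}")
print(f"fitted eps    : {eps_hat:.4f}")
print(f"relative error: {abs(eps_hat - eps_true) / eps_true:.2e}")
print(f"RSS           : {fit.total_rss:.3g} mm^6 over n={fit.n_per_therapy['b']} observations")
print(
    "\nReading: with noise-free data the fitted propensity matches the value\n"
    "used to generate the arm and the residual sum of squares is ~0, so the\n"
    "calibration pipeline is self-consistent."
)
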