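# pdl1dyn

Tumor–immune ODE modeling of PD-1/PD-L1 checkpoint dynamics under
combination immunotherapy, with nonlinear least-squares calibration and
RSS/AIC model comparison.

## The problem

Checkpoint blockade often fails because tumors adapt: immune attack
induces PD-L1 upregulation ("adaptive immune resistance"), which
deactivates the very T cells the therapy mobilized. `pdl1dyn` is for
modelers studying this feedback in the standard murine EMT-6 setting —
six therapy arms combining the anti-PD-L1 antibody Avelumab (200 μg IV
on days 0, 3, 6) with the IL-12 immunocytokine NHS-muIL12 (2 or 10 μg
subcutaneously on day 0). It asks, quantitatively: is tumor PD-L1
expression a fixed property, or a dynamically regulated variable?

## The model

State variables: tumor volume $V$ (mm³), activated T cells $T$ (mm³),
drug compartments $A_1$ (Avelumab) and $A_2$ (NHS-muIL12). The
PD-1/PD-L1 complex is algebraic,

$$Q = \frac{T\,(T + \epsilon V)}{1 + A_1/K_{A_1}},$$

where $\epsilon$ is the tumor's PD-L1 expression propensity, and

$$\dot V = rV - \frac{\eta\,T V}{1 + Q/K_Q}, \qquad
\dot T = \lambda_T + \lambda_{T8I12}\,\frac{T}{1+T/K_T}\,\frac{A_2}{K_{A_2}+A_2} - d_T T,$$

with first-order drug clearance ($\dot A_i = -d_{A_i} A_i$ between bolus
doses; half-lives 1.86 d and 9.5 d). In the **base model** $\epsilon$ is a
constant fitted per therapy arm. In the **dynamic model** it is a fifth
state encoding adaptive resistance:

$$\dot\epsilon = k_\text{basal}\frac{V}{K_V+V}
 + \alpha_{A_2}\frac{A_2}{K_{A_2}+A_2}
 - \alpha_{A_1}\frac{A_1}{K_{A_1}+A_1}\,\epsilon
 - d_\epsilon\,\epsilon .$$

Calibration minimizes the sum of squared errors on tumor volumes —
per arm for the constant $\epsilon$ (k = 1 each, 6 globally) and jointly
across all six arms for the five dynamic-ϵ parameters (k = 5) — and the
variants are compared by $\mathrm{AIC} = n\ln(\mathrm{RSS}/n) + 2k$.

A synthetic-data generator reproduces the experiment's structure
(six arms, 6 observation days, 100 mm³ baseline, multiplicative
lognormal noise) from either ground truth, so every stage is testable
without external data.

## Worked example

`python examples/04_model_comparison.py` pushes the published per-arm
residuals of the EMT-6 study through the AIC bookkeeping:

```
Therapy      n    RSS(const)  AIC(const)      RSS(dyn)    AIC(dyn)  preferred
a            6        5367.9      42.779        6555.9      51.978  constant
b            6        5664.4      43.101        8251.0      53.358  constant
c            6        3240.4      39.750        6474.1      51.903  constant
d            6       18396.0      50.169       14853.0      56.885  constant
e            6         739.9      30.889        2330.5      45.772  constant
f            6        1762.4      36.096        9161.8      53.986  constant
global      36       35171.0     259.840       47626.3     268.754  constant
```

The constant-ϵ variant is preferred overall (global AIC 259.84 vs
268.75), while the dynamic variant achieves the lower RSS on the
Avelumab monotherapy arm (d); both encode therapy-dependent PD-L1
expression. `python examples/03_dynamic_epsilon_fit.py` closes the loop
on synthetic data — the joint six-arm fit recovers every ϵ-equation
rate to a fraction of a percent:

```
parameter         true      fitted   rel err
k_basal        30.5441     30.5355  2.81e-04
K_V            50.0000     49.9945  1.10e-04
alpha_A1       38.2653     38.2556  2.54e-04
alpha_A2      643.6397    643.5630  1.19e-04
d_eps           0.4409      0.4408  2.55e-04
```

The other examples simulate the six arms (`01`), fit a single constant
ϵ (`02`) and generate a noisy dataset with its ground-truth manifest
(`05`). The same workflow is available from a shell:

```bash
pdl1dyn generate --seed 7 --out data.csv --manifest manifest.json
pdl1dyn fit --data data.csv --variant constant --out fit_const.json
pdl1dyn fit --data data.csv --variant dynamic --out fit_dyn.json
pdl1dyn compare --constant-report fit_const.json --dynamic-report fit_dyn.json
```

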