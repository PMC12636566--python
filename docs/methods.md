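# Methods

## Model

The package implements a minimal tumor–immune interaction model for the
murine EMT-6 combination-immunotherapy setting. Tumor volume `V` (mm³)
grows exponentially at rate `r` and is killed by activated T cells `T`
(mm³) by mass action; the killing is inhibited by PD-1/PD-L1 complex
signaling through the factor `1/(1 + Q/K_Q)`, which equals 1 with no
complex and vanishes as `Q → ∞`. The complex is treated as algebraic
(binding equilibrates much faster than cell-population turnover):

    Q = T (T + ε V) / (1 + A1/K_A1)

PD-1 is carried by T cells only (`Q = 0` when `T = 0`); PD-L1 is
presented by T cells and, with propensity ε, by tumor cells; Avelumab
(`A1`) competitively blocks complex formation. T cells are produced at
a constant basal rate, stimulated by NHS-muIL12 (`A2`) proportionally
to `T` at small `T` with a crowding saturation `T/(1 + T/K_T)`, and
turn over at rate `d_T`. Drug compartments follow one-compartment
first-order kinetics between doses; doses are instantaneous boluses
(the experiment used discrete IV/subcutaneous injections, so bolus
events with integrator restarts are both more faithful and numerically
kinder than narrow continuous pulses).

The crowding factor in the stimulation term is a deliberate structural
choice: with the adopted stimulation rate `λ_T8I12 = 4.15 day⁻¹` and
the slow NHS-muIL12 clearance (half-life 9.5 d), stimulation purely
proportional to `T` sustains net exponential T-cell growth for weeks in
the 10 μg arms and drives `T` to physically meaningless levels
(~10¹⁵ mm³ in direct simulation). The saturating form caps the
antigen-presentation capacity at the scale `K_T` while preserving
proportionality at small `T` and monotonicity in `A2`.

### Dynamic PD-L1 expression

The base model treats ε as a constant, fitted independently per therapy
arm. The dynamic variant promotes it to a state variable — the model's
encoding of adaptive immune resistance:

    dε/dt = k_basal·V/(K_V + V)          (tumor-size-driven upregulation,
                                          saturating at volume K_V)
          + α_A2·A2/(K_A2 + A2)          (immunostimulant-driven upregulation)
          − α_A1·A1/(K_A1 + A1)·ε        (Avelumab-mediated suppression,
                                          Michaelis–Menten in A1)
          − d_ε·ε                        (natural decay)

All ε-equation rates are in day⁻¹; the two saturation terms reuse
`K_A1` and `K_A2` as half-saturation constants so that `α_A1`, `α_A2`
keep units of day⁻¹. ε is bounded: lim sup ε(t) ≤ (k_basal + α_A2)/d_ε.
With all five parameters zero, ε stays at its initial value and the
five-state model degenerates exactly to the base model (a tested
invariant).

### Initial conditions

`V(0) = 100 mm³` (tumors were randomized into arms at that volume),
`T(0) = λ_T/d_T` (drug-free steady state), `A1(0) = A2(0) = 0` before
the day-0 boluses. For the dynamic variant, `ε(0)` defaults to the
drug-free quasi-steady state `k_basal·V(0)/(K_V + V(0))/d_ε`, which
makes the no-drug arm start on its own slow manifold and keeps the
initial condition consistent with whatever ε-parameters are being
evaluated during fitting; it is configurable.

## Parameters

| name | meaning | unit | default | source of the default |
|---|---|---|---|---|
| `r` | tumor proliferation | day⁻¹ | 0.25 | untreated EMT-6 growth, ~2.8 d doubling |
| `eta` | T-cell kill coefficient | day⁻¹·mm⁻³ | 0.1 | sets Avelumab monotherapy near stasis (η·T₀ ≈ r) |
| `lambda_T` | basal T-cell production | mm³·day⁻¹ | 4.5 | with `d_T` gives T₀ = 2.25 mm³ |
| `lambda_T8I12` | max IL-12 stimulation | day⁻¹ | 4.15 | adopted CD8⁺ stimulation rate |
| `d_T` | T-cell turnover | day⁻¹ | 2.0 | short-lived activated effector pool |
| `d_A1` | Avelumab clearance | day⁻¹ | ln2/1.86 = 0.3726 | murine half-life 44.6 h |
| `d_A2` | NHS-muIL12 clearance | day⁻¹ | ln2/9.5 = 0.0730 | murine half-life 9.5 d |
| `K_A1` | Avelumab half-saturation | compartment units | 1×10⁻¹³ | literature-derived binding constant |
| `K_A2` | NHS-muIL12 half-saturation | compartment units | 7×10⁻¹⁴ | literature-derived binding constant |
| `K_Q` | complex inhibition scale | complex units | 1×10⁴ | makes kill inhibition responsive over the fitted ε range |
| `K_T` | stimulation crowding scale | mm³ | 50 | caps T-cell expansion at tens of mm³ |
| `dose_scale_A1` | μg → compartment units | μg⁻¹ | 1×10⁻¹³ | one 200 μg dose ≈ 200·K_A1 |
| `dose_scale_A2` | μg → compartment units | μg⁻¹ | 7×10⁻¹⁴ | 2/10 μg doses straddle K_A2 |

ε-equation defaults (`EpsilonParams`): `k_basal = 30.5441`, `K_V = 50`,
`alpha_A1 = 38.2653`, `alpha_A2 = 643.6397`, `d_eps = 0.4409` (all
day⁻¹ except `K_V` in mm³) — the globally fitted values of the dynamic
model, shipped as the canonical ground truth of the synthetic
generator.

The drug compartments' absolute unit is not observable from
tumor-volume data; only the ratios `A_i/K_{A_i}` enter the dynamics.
The two `dose_scale_*` constants are therefore the single deliberate
unit bridge: their defaults place a 200 μg Avelumab dose at ~200× its
half-saturation (deep but waning blockade over ~2 weeks) and the 2 and
10 μg NHS-muIL12 doses at ~2× and ~10× theirs (dose-separated, slowly
decaying stimulation). Both are configurable.

The base rates `r, eta, lambda_T, d_T, K_Q, K_T` are package defaults
chosen once so that the six default arms reproduce the qualitative arm
phenotypes reported for this experimental system: monotone untreated
growth to a few thousand mm³ by day 20; NHS-muIL12 monotherapy escape
accompanied by a sharp, sustained ε rise; partial control under
Avelumab monotherapy with suppressed ε; regression in both
combinations, with a brief initial rise in the low-dose combination.
They are treated as fixed and known during all calibration (the
sequential protocol that would estimate them from the no-drug arm is
out of scope); only ε or its equation is fitted.

## Calibration

Loss is the plain unweighted SSE on volumes (a log-volume option
exists but is off by default). Optimization is bound-constrained
trust-region least squares (`scipy.optimize.least_squares`) with
seeded Latin-hypercube multi-starts (default 20) over the box bounds —
`[0, 5000]` for the scalar ε, `[0, 10× default]` per ε-equation
parameter. Two numerical details matter:

- the finite-difference Jacobian step is set to 1e-4 (relative), well
  above the 1e-6 relative integration tolerance used during fitting,
  so gradients are not dominated by integrator noise;
- among multi-start optima whose costs tie within a 1e-6 relative
  tolerance, the smallest-norm parameter vector is reported. This
  parsimony tie-break makes results deterministic and returns the
  minimal PD-L1 propensity consistent with the data in arms that carry
  little information about ε (see limitations).

A fit in which no restart converges is reported as a failure with the
collected diagnostics, never as a silent best-so-far. Bounds with
`lower == upper` pin a parameter rather than being optimized, so a
fully pinned fit degenerates to a single model evaluation.

Model values at observation days are obtained by linear interpolation
on the trajectory output grid; during fitting the integrator is
evaluated directly at the observation days, so no interpolation error
enters the objective.

## AIC convention

`AIC = n·ln(RSS/n) + 2k` (Gaussian least-squares form, no small-sample
correction), with n = 6 observations per arm and n = 36 globally. Per
arm the constant-ϵ model carries k = 1 and the dynamic model k = 5;
globally the constant variant counts k = 6 (one fitted ε per arm —
six free parameters even though they represent one biological
quantity) against k = 5. This convention reproduces every published
AIC in the reference EMT-6 comparison table from its published RSS to
the printed precision (≤ 10⁻³), including the global rows (259.84 and
268.75), which is also how n = 6 per arm was confirmed. The ε-equation
parameter count is kept at k = 5 (all five parameters free) even
though `K_V` is weakly identified; pinning it would change each
dynamic AIC by exactly −2 without affecting any ordering reported
here.

## Numerics

LSODA with relative tolerance 1e-8 for simulation (1e-6 inside fitting
loops) and per-component absolute tolerances: 1e-8 for `V`, `T`, ε and
`1e-6·min(K_A1, K_A2)` for the drug compartments, which live ~13
orders of magnitude below the cell-volume scale. Integration restarts
at every dose time with the bolus added to the post-restart state; the
recorded state at a dose time is the post-dose value. The solver may
probe marginally negative states; the right-hand side clamps these at
zero and outputs are clipped at zero (the exact dynamics are
invariant on the nonnegative orthant, so this affects only
round-off-scale excursions). Two half-doses at the same instant are
equivalent to one full dose; refining the output grid does not change
shared points; halving tolerances changes trajectories by less than
the coarser tolerance — all tested.

Deep-regression arms underflow: tumor volume in the combination arms
decays below 10⁻²⁰ mm³ within two weeks. Values are kept nonnegative
and the synthetic generator floors sampled volumes at the smallest
positive double so that datasets satisfy the strict-positivity
invariant.

## Synthetic data

The generator emulates the design of the source experiment: six arms
(a–f), observation days {0, 4, 8, 12, 16, 20} (six per arm, matching
the n = 6 implied by the AIC bookkeeping; the actual sampling days are
not documented, so equispaced days over a 20-day window are a
package choice), V(0) = 100 mm³, one series per arm (the digitized
data were group-level curves), and multiplicative lognormal noise with
CV 0.10 by default (unit-mean factors; the CV is exact by
construction). Additive-proportional noise resamples any draw that
would produce a nonpositive volume rather than clamping. All
randomness flows from a single seed through per-arm substreams, so
experiments are reproducible and arms are independent.

It does **not** emulate: per-mouse replicates or between-animal
variability, sacrifice/dropout censoring, measurement floors of
caliper data (the synthetic combination arms regress to numerically
tiny volumes, where a real experiment would record ~0 or "tumor-free"),
or digitization error. Passing recovery tests therefore demonstrate
correctness of the estimation machinery under the model's own
assumptions, not robustness to real-data pathologies.

## Identifiability

On noiseless synthetic data, per-arm constant-ϵ fits recover ε to
better than 1% on all six default arms, and the joint six-arm dynamic
fit recovers `k_basal`, `alpha_A1`, `alpha_A2`, `d_eps` (and `K_V`) to
a fraction of a percent. Under 10% noise the fitted constant-ϵ pattern
reproduces the adaptive-resistance signature — NHS-muIL12 arms above
control, Avelumab monotherapy below control, each combination below
its matching NHS monotherapy. In the combination arms themselves the
likelihood is nearly flat in ε: the tumor is driven to ~0 at most
observation days and checkpoint blockade removes ε from the dynamics
early on, so under noise the fitted value is unstable there. Those two
arms are therefore compared against their monotherapy counterparts,
not against control, and conclusions about ε in deeply regressing
arms should not be drawn from this design.

## Problem sizes

Tests and the reproduction script run the design at its natural size
(6 arms × 6 observations). Multi-start counts are scaled to the task:
20 by default, 3–6 in the recovery experiments and examples, which is
sufficient because the noiseless objectives have a single relevant
basin within the bounds (verified by the recovery results themselves).
The end-to-end reproduction (`scripts/acceptance.py`) completes in
about a minute on one CPU.

## Known limitations

- The constant-ϵ and dynamic-ϵ comparison on synthetic data yields RSS
  magnitudes far above the published table's (noise scales with the
  simulated volumes, which reach ~10⁴ mm³ in escaping arms), so only
  the bookkeeping — not the RSS values — is comparable to the
  published numbers.
- T-cell exhaustion, explicit IFN-γ intermediates, spatial structure
  and clonal heterogeneity are out of scope; the dynamic ε can be read
  as an effective bulk description of clonal selection, but the model
  cannot distinguish those mechanisms.
- Base-model rates are fixed defaults, not fitted; all inference about
  ε is conditional on them.
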