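# Methods

## Model structure

Both model variants share one twelve-component state vector (all in mg COD/L
except dissolved oxygen `S_O` in mg O2/L), in fixed column order: `S_I`,
`S_IC`, `X_I`, `S_S`, `S_H`, `X_S`, `S_O`, `X_P`, `S_P`, `X_SS`, `S_HC`,
`X_H`. Six processes act on it: heterotrophic growth, hydrolysis of `S_H`,
of `S_HC`, of `X_S`, of `X_SS`, and endogenous decay.

The membrane variant (`masm`) carries the size-aware fractionation: the
soluble hydrolysable and soluble inert pools are each split at the membrane's
effective filtration size into a passing and a captured component, and the
settleable biodegradable pool `X_SS` hydrolyses in two steps
(`X_SS → S_HC → S_S`), reflecting particle-size evidence that particulate
breakdown passes through larger-size soluble organics rather than jumping
straight to readily biodegradable COD. The gravity-settled reference
(`asm1_mod`, ASM1 modified for endogenous decay) uses the same vector with
the captured pools at zero influent and zero kinetics, a lumped `S_H` pool
equal to the total soluble hydrolysable COD, and one-step hydrolysis of both
`X_S` and `X_SS` directly to `S_S`. Growth and decay are identical between
variants; the two-step route is the membrane model's structural addition.

Assumptions: dissolved oxygen and nutrients are in excess, so the rate
expressions carry no switching functions and `S_O` is clamped at a reporting
setpoint (2 mg/L by default) while only the oxygen *consumption flux* is
accounted; temperature correction, nitrification, phosphorus and storage
polymers are out of scope. COD is the sole conserved currency: every process
row satisfies `Σ(COD coefficients) − S_O coefficient = 0` exactly, which the
package verifies (`continuity_defect`) and propagates into a whole-plant
balance audit.

## Parameters

| symbol | meaning | unit | default |
|---|---|---|---|
| `μ̂_H` (`mu_H_hat`) | max specific growth rate | 1/d | 3.6 |
| `K_S` | growth half-saturation | mg COD/L | 15 |
| `b_H` | endogenous decay rate | 1/d | 0.14 |
| `k_hS` | max hydrolysis rate, soluble pools | mg COD/mg cell COD/d | 2.45 |
| `K_hS` | hydrolysis half-saturation, soluble | mg COD/mg cell COD | 0.09 |
| `k_hX` | max hydrolysis rate, particulate pools | mg COD/mg cell COD/d | 0.68 |
| `K_hX` | hydrolysis half-saturation, particulate | mg COD/mg cell COD | 0.28 |
| `Y_H` | heterotrophic yield | mg cell COD/mg COD | 0.64 |
| `f_S` | soluble residual fraction of decay | — | 0.05 |
| `f_X` | particulate residual fraction of decay | — | 0.20 |

The first seven are the set selected for denim-processing textile wastewater
from respirometric studies. `Y_H`, `f_S` and `f_X` are not resolved by that
characterisation; the defaults are the conventional COD-based values for this
model family, and they also place the conventional-range effluent plateaus
(≈250 and ≈160 mg/L soluble COD for the settled and membrane systems) where
the comparative evaluation puts them. All ten are configurable through the
`kinetics` section of a run configuration.

The same holds for two flowsheet settings the published evaluation does not
print: the recycle ratio (defaults R = 1 for gravity settling, R = 4 for
membrane loops — ordinary CAS/MBR practice) and the separator thresholds
(8 nm membrane effective filtration size, the recommended default within the
experimentally observed 8–13 nm range; 450 nm for gravity settling). Because
yield, residue split and recycle are calibration-backed choices rather than
published facts, simulation regressions against the published sweep tables
are asserted within max(25%, 3 mg/L) rather than at print precision; the
defaults land every sweep row inside that band without per-row tuning.

## Flowsheet and solver

The plant is N equal CSTRs in series (N = 3 by default), fed by influent
`Q` plus return sludge `R·Q`; mixed liquor is wasted from the last tank at
the hydraulic rate `Q_w = V_total/θ_X` (identical to the retained-inventory/θ_X
law when tank concentrations are uniform), and the remainder feeds an ideal
point separator. Pass-set components leave at the last tank's concentration
with `Q_e = Q − Q_w`; retain-set components return entirely with the RAS
(optionally minus a configurable 30–60 mg COD/L particulate escape allowance
for non-ideal settling; the default is 0 because the published effluent
numbers are soluble COD).

Steady states: deterministic initial guess (influent-fed tanks with
`X_H` seeded at 500 mg/L), stiff BDF integration over `max(50·θ_X, 10·θ_H)`
(rtol = atol = 1e-8), then `scipy.optimize.root` (hybr) polishing, accepted
only if it reduces the residual. Convergence demands every tank's net
per-component accumulation below 1e-8 relative to the influent COD flux;
failure raises, whereas heterotrophic washout (`X_H < 1e-6 mg/L`) is flagged
on the result but not raised. Hydrolysis is evaluated in the rewritten form
`k_h·C·X_H/(K_h·X_H + C)`, identical for `X_H > 0` and well defined (zero) at
`X_H = 0`. Concentrations are clipped at zero before rate evaluation during
integration and on the final state.

MLSS is estimated from particulate COD (`X_I+X_S+X_SS+X_P+X_H`) with
1.42 mg COD/mg VSS and VSS/TSS = 0.8 (both configurable); the captured
soluble pools are excluded — the membrane retains them, but they are below
the 450 nm suspended-solids definition.

## Fractionation and PSD numerics

Fraction tables are validated against their seven additivity identities with
a 0.5 mg/L tolerance (printed tables are rounded to whole mg/L). Captured /
passing splits preserve the pool total bit-exactly (the split is re-rounded
until `passing + captured == total` holds in floating point). Cumulative PSD
curves are interpolated piecewise-linearly in `log10(size)` — the sequential
filtration grid spans 2–1600 nm, almost three decades — both for reading the
effective filtration size off a permeate concentration and for curve-based
splitting. Reported percentages round half away from zero; effluent
concentrations are reported at whole mg/L above 10 and one decimal below,
with raw values retained in machine output.

## Model-reduction equivalence

With the separation threshold at 450 nm and the captured pools empty, the
membrane model should collapse onto the reference model. One structural
difference survives: `X_SS` hydrolyses via `S_HC` in `masm` but directly to
`S_S` in `asm1_mod`, and at a 450 nm threshold the intermediate `S_HC` can
escape with the effluent, so the two solutions differ slightly whenever
`X_SS` is fed. The equivalence is therefore exact — and is tested — on a
primary-settled influent (`primary_settled=True`, which zeroes `X_SS`, the
same device the model family uses for plants with primary clarifiers).

## Synthetic data

`generate_synthetic_influent` draws a fully consistent fraction table around
the bundled textile or domestic characterisation: total COD within ±30%,
pool proportions jittered ±20% and renormalised, captured fractions jittered
±10%; every additivity identity holds by construction.
`generate_synthetic_psd` produces a logistic-in-log-size cumulative curve on
the 1600→2 nm sequential-filtration grid, scaled to a given pool total. Both
are deterministic per seed. They emulate the *algebraic structure* of
measured data — additive fraction tables, monotone cumulative curves — not
its measurement noise, temporal variability, or any correlation between
fractions and particle size beyond the captured-share ranges; tests passing
on them certify the arithmetic and the solver, not the field variability of
real wastewater.

## Problem sizes and test scope

The test suite and the reproduction script solve the published operating
grid: two sweeps × six sludge ages (1–8 d) × two variants on the textile
influent — 24 steady states of a 3-tank, 33-unknown flowsheet, each solving
in well under a second. The solver is cross-checked against an independent
fixed-step explicit Euler march (dt = 5·10⁻⁴ d over 200 sludge ages) on the
superfast membrane scenario to 0.5%, and against the first-order single-CSTR
closed form `S_HE = S_H1/(1 + (k_hS/K_hS)·θ_H)` to 1% in the
biomass-in-excess regime.

## Known limitations

* Membrane physics (flux, transmembrane pressure, fouling, cake-layer
  dynamics) are not modelled; the membrane enters only as a fixed size
  threshold.
* The separator is a point unit: no clarifier flux theory, no solids
  inventory in the settler, no storage dynamics.
* Kinetics are single-culture heterotrophic COD removal; no autotrophs,
  no nutrient limitation, no temperature dependence.
* Steady state only; the integrator is a means to the stationary solution,
  not a calibrated dynamic response.
* The calibration gap documented above (yield, residue split, recycle)
  bounds how literally effluent predictions should be read: structure and
  trends are the model's claims, not the third significant digit.
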