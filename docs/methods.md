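# Methods

## Scope and units

The package analyses single-metal batch sorption at equilibrium.
Canonical internal units are mg/L for concentrations, mg/g for uptake,
L and g for volume and biomass; molar inputs (mM) are converted at the
I/O boundary using the metal's molar mass (Cd 112.41, Mn 54.938 g/mol)
with 1:1 salt stoichiometry, which reproduces the conventional initial
concentrations 0.5 mM Cd ≈ 56 mg/L and 3 mM Mn ≈ 164 mg/L.  Uptake is
reported in mg/g throughout (the unit in which capacities in this field
are quoted and compared).  No speciation or pH-dependent solubility
chemistry is modelled.

## Fuzzy linear regression

The inference engine is a possibilistic regression in Tanaka's style
with crisp inputs and outputs.  Every coefficient is a symmetric
triangular fuzzy number (center `a_j`, spread `c_j ≥ 0`); the fit is the
linear program

    minimise  J = c_0 + ... + c_n
    s.t.      a0 + Σ aj xij − (1−H)(c0 + Σ cj |xij|) ≤ yi
              a0 + Σ aj xij + (1−H)(c0 + Σ cj |xij|) ≥ yi     for all i
              cj ≥ 0,  aj free

* **Constraint orientation.** The inclusion form above (band covers each
  observation) is the standard one; the inverted orientation is
  infeasible for anything but collinear data and is not meaningful.
* **Objective.** The unweighted spread sum is the default.  Tanaka's
  original data-weighted objective (`c_j` weighted by `Σ_i |x_ij|`) is
  available via `fit_tanaka(..., weighted=True)` for users who prefer
  spreads penalised in proportion to leverage.
* **h-certain factor `H`.** Dimensionless in [0, 1); default 0, the
  weakest (widest-feasible-set) level and the conventional choice when a
  study does not state its level.  Raising `H` tightens the inclusion
  constraints, so the minimal `J` is non-decreasing in `H`.
* **Solver and determinism.** HiGHS via `scipy.optimize.linprog` with
  primal/dual feasibility tolerances of 1e-10; feasibility of the
  returned model is asserted to 1e-8 in the response units.  HiGHS is
  deterministic, so repeated fits are bit-identical.
* **Tie-breaking.** When the optimum is non-unique (typically `J = 0`,
  exactly interpolable data), a secondary LP selects the minimum-L1-norm
  center vector among minimal-J solutions.  The L1 norm keeps the whole
  procedure inside linear programming; the spread budget in the
  secondary solve is slack by only 1e-12·(1+J*) so the tie-break cannot
  trade spread inflation for center-norm reduction.
* **Verification oracle.** `lp_oracle_small` solves the same program by
  exhaustive enumeration of constraint-intersection vertices (≤ 6
  observations, ≤ 2 predictors; all `C(rows, 2(n+1))` square systems are
  solved and filtered for feasibility).  It shares no code path with the
  LP solve and is used only in tests.

The crisp goodness-of-fit quoted next to each fuzzy fit is the ordinary
least-squares R² of the same linearized data.  It is reported because
practitioners compare isotherm models on linearized R²; it is not a
possibilistic quantity.

## Isotherm fitting and interval propagation

Langmuir is fitted on `Ce/Qe` vs `Ce` (slope `1/q0`, intercept
`1/(q0 b)`), Freundlich on `log10 Qe` vs `log10 Ce` (slope `1/n`,
intercept `log10 Kf`).  Base-10 logarithms are used so `Kf` is recovered
as a power of ten, the convention under which published `Kf` magnitudes
are quoted.

Parameters are read off the coefficient **supports** (membership level
0, `[a − c, a + c]`) by endpoint interval arithmetic, exploiting
monotonicity in each argument:

* `q0 = [1/s_hi, 1/s_lo]` (decreasing in the slope),
* `b = slope/intercept = [s_lo/i_hi, s_hi/i_lo]`,
* `n = [1/s_hi, 1/s_lo]` on the log–log slope,
* `Kf = 10^(intercept center)`, reported crisp — the asymmetric
  convention (point `Kf`, interval `n`) matches how Freundlich tables
  are usually printed.

A slope or intercept support touching zero makes the inversion undefined
(`q0`, `b` or `n` would be unbounded); the fit raises a
non-invertible-fit error that still carries the fuzzy model so the
report can show the band.  Note the practical reading: a slope support
nearly touching zero produces a very wide `q0` interval — wide published
capacity intervals for weakly-sorbed metals are exactly this situation.

The separation factor `R_L = 1/(1 + b C0)` is applied endpoint-wise with
reversal (it is antitone in `b`).  `C0` defaults to the lowest initial
concentration of the experimental design (the concentration at which the
favorability of the isotherm is conventionally quoted); it is
overridable everywhere.  Favorability flags: *effective* iff the `R_L`
interval lies strictly inside (0, 1); *efficient* iff the `n` interval
lies inside [1, 10].

## Synthetic experiments

The generator emulates the batch design of the study system: 50 mL test
solutions, 1 g/L dry biomass dose, cadmium series 0.5–20 mM and
manganese series 3–20 mM.  The cadmium single-factor series (0.5, 1, 2,
3, 4 mM) is extended through 6, 10, 15 to 20 mM for isotherm runs — nine
points chosen to cover the saturating region on a roughly geometric
grid; the manganese series is (3, 5, 10, 15, 20) mM.

For each initial concentration the unique equilibrium solves the mass
balance `(Ci − Ce)·V/M = Q(Ce)`:

* **Langmuir**: quadratic `b·Ce² + (1 − b·Ci + b·ρ·q0)·Ce − Ci = 0`
  (`ρ` = dose in g/L), positive root taken in the cancellation-stable
  form `2·Ci/(B + √disc)`, which stays accurate in the no-affinity limit
  `b → 0` (`Ce → Ci`).
* **Freundlich**: bracketed Brent root-finding on [0, Ci] (the residual
  has opposite signs at the ends), accepted only if
  `|residual| < 1e-10·Ci`.

Measurement noise is a unit-mean multiplicative lognormal factor on `Qe`
(`σ² = ln(1 + sd²)`, mean-corrected so the relative sd is exact),
defaulting to 2% — errors from atomic-absorption readouts scale with
signal, which an additive model would misrepresent.  `Ce` is then
recomputed from the mass balance so each noisy record remains internally
consistent, the property the fitting stages assume; a draw that pushes
`Ce` out of (0, Ci) is resampled (cap 100, then an error).  One master
seed expands into per-record streams via `SeedSequence.spawn`, so
datasets are reproducible and the records for shared concentrations do
not change when the series is extended.

What the generator does **not** emulate: pH, temperature, agitation and
dose response (no governing equations exist for them in this setting),
sorption kinetics (only equilibrium), competitive multi-metal systems,
replicate-to-replicate biomass variability, and any instrument drift or
censoring.  Passing tests on synthetic data therefore demonstrate the
correctness of the computational chain under a known isotherm with
well-behaved multiplicative noise — not the adequacy of either isotherm
for any particular organism.

## What interval coverage does and does not mean

The inclusion constraints guarantee that every *observation* lies inside
the fitted band — an invariant the tests assert to 1e-8.  They do **not**
make the coefficient supports confidence intervals for generating
parameters: the minimal-spread band's slope support has width of order
(noise scale)/|x|, while the slope center error is of order (noise
scale)/range(x), and the two are comparable.  Empirically (criterion
tests in `tests/test_acceptance.py`), with 2% noise the Langmuir `q0`
support brackets the generating value in roughly 19 of 20 replicates on
the Cd-like design, but the Freundlich `n` support does so far less
often.  Interval width here measures *possibilistic data coverage*, not
sampling uncertainty; users needing calibrated parameter uncertainty
should bootstrap or use a probabilistic model.

## Problem sizes

All analyses run on the study-scale designs (5–9 equilibrium points per
metal); LP instances have 4 variables and ≤ 18 constraints, and the
oracle comparisons use ≤ 5 observations so the exhaustive enumeration
stays below ~2 000 linear solves per instance.  The full test suite and
the analysis scripts complete in seconds on one CPU.

## Known limitations

* Only the two classical isotherms and their standard linearizations;
  no nonlinear least squares, no Temkin/Sips/D–R, no competitive
  isotherms.
* Crisp inputs and outputs only; symmetric triangular memberships only;
  no possibilistic goodness-of-fit beyond `J`.
* Interval propagation uses supports; no membership-level-α cuts are
  exposed.
* The linearizations inherit their classical variance distortions
  (e.g. `Ce/Qe` weighting); the fuzzy band does not correct for them.
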