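# biosorb

Equilibrium analysis of heavy-metal biosorption in batch experiments —
uptake bookkeeping, isotherm fitting by **possibilistic (fuzzy) linear
regression**, and interval-valued parameter reporting with favorability
diagnostics.  The package targets the common experimental setting in
environmental microbiology: a biosorbent (here, bacterial biomass) is
equilibrated with a graded series of metal solutions (e.g. Cd(II),
Mn(II)), the residual concentration is measured, and an isotherm model is
fitted to characterize capacity and affinity.

## The model

Each batch record (initial concentration `Ci`, final concentration `Cf`,
volume `V`, dry biomass `M`) yields the uptake capacity and removal ratio

```
Qe = (Ci − Cf) · V / M        [mg/g]
Re = 100 · (Ci − Cf) / Ci     [%]
```

Equilibrium (Ce, Qe) points are fitted to two isotherms on their
classical linearizations:

* **Langmuir** `Qe = q0·b·Ce / (1 + b·Ce)` → `Ce/Qe = 1/(q0·b) + Ce/q0`
  (monolayer capacity `q0` mg/g, affinity `b` L/mg);
* **Freundlich** `qe = Kf·Ce^(1/n)` → `log10 qe = log10 Kf + (1/n)·log10 Ce`
  (binding constant `Kf`, intensity `n`).

Instead of ordinary least squares, the linearized data are fitted by
Tanaka-style fuzzy linear regression: each coefficient is a symmetric
triangular fuzzy number (center `a_j`, spread `c_j ≥ 0`), and the fit
minimizes the total spread `J = Σ c_j` subject to every observation lying
inside the fuzzy band at the h-certain level `H`:

```
a0 + Σ aj·xij − (1−H)(c0 + Σ cj·|xij|) ≤ yi ≤ a0 + Σ aj·xij + (1−H)(c0 + Σ cj·|xij|)
```

This is a linear program (solved with HiGHS).  Physical parameters are
read off the coefficient *supports* `[a − c, a + c]` by monotone interval
arithmetic, so the report carries honest intervals such as
`q0 = [159.0, 238.0] mg/g` rather than a single point estimate — suited to
small, noisy datasets where a normal error model is hard to defend.

Favorability diagnostics: the separation factor `R_L = 1/(1 + b·C0)`
inside (0, 1) indicates effective sorption; a Freundlich `n` within
[1, 10] indicates efficient sorption.

A synthetic-experiment module replaces the wet lab for validation: it
couples the batch mass balance with a known isotherm, solves for the
unique equilibrium (closed-form quadratic for Langmuir, bracketed
root-finding for Freundlich), and applies seeded multiplicative lognormal
noise to `Qe` with mass-balance back-correction of `Ce`.

## Worked example

```python
from biosorb import (TrueIsotherm, NoiseSpec, paper_like_design,
                     generate_isotherm, fit_langmuir, fit_freundlich)

design = paper_like_design("Cd")            # 0.5–20 mM, 50 mL, 1 g/L biomass
truth = TrueIsotherm("langmuir", (170.0, 0.01))
ds = generate_isotherm(design, truth, NoiseSpec(relative_sd=0.02, seed=1))
lang = fit_langmuir(ds, H=0.0, C0=56.2)
print(lang.q0, lang.b, lang.RL, lang.r2)
```

prints

```
IntervalParam(low=159.01..., high=238.02..., units='mg/g')
IntervalParam(low=0.00702..., high=0.01051..., units='L/mg')
IntervalParam(low=0.629..., high=0.717..., units='')
0.99951...
```

The `q0` support [159.0, 238.0] mg/g brackets the generating capacity of
170 mg/g, the affinity support brackets the true 0.01 L/mg, the
separation factor at the lowest initial concentration (0.5 mM ≈ 56 mg/L)
lies strictly inside (0, 1) — favorable sorption — and the crisp OLS R²
on the linearized data is 0.9995.

The same pipeline is available from a shell:

```
biosorb simulate --out cd.csv --metal Cd --q0 170 --b 0.01 --sd 0.02 --seed 1
biosorb fit cd.csv --out cd_fit.json --c0 56.2
biosorb report cd_fit.json
biosorb convert batch.csv --out batch_aug.csv     # adds Qe and Re columns
```

The numbered scripts under `analysis/` run the full study-like analysis
(simulate both metals → batch uptake tables → isotherm fits → favorability
report), writing tables under `results/`.

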