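# multibatch

Design and analysis of **multi-batch preclinical tumour-efficacy
experiments**.

Small in-vivo efficacy studies (syngeneic tumour models in mice) are
classically run as one large batch. Splitting the same animals across
several small, independently run batches — separate cell preparations,
separate animal shipments — makes the treatment estimate robust to
batch-to-batch variation and, because a replicated conclusion is built into
one experiment, can cut the total number of animals needed. The catch is
that the analysis must respect the batch structure. This package provides
the full toolchain for that workflow:

* **growth rates** — each animal's calliper series (volume
  `= width²·length/2`, in mm³) is summarised by the slope *b* of the
  log-linear fit `log10(volume) = a + b·day`, using measurements up to day
  30 and clamping volumes below 50 mm³ to the floor;
* **simulation** — per-animal growth rates `Y_ijk` with batch effects
  `u_j ~ N(0, σ_batch²)`, treatment inhibition applied as a proportional
  reduction of the mean control rate, and optional between-batch
  heterogeneity of the treatment effect;
* **four competing estimators** of the treated−control rate difference:

  | method | model | test |
  |---|---|---|
  | `pooled` | `Y_ij = μ + α_i + ε_ij` (batch ignored) | two-sample *t* |
  | `fixed`  | `Y_ijk = μ + α_i + β_j + γ_ij + ε_ijk` | type III *F* / marginal-mean *t* |
  | `random` | `Y_ijk = μ + α_i + b_j + c_ij + ε_ijk`, `b_j ~ N(0,σ_b²)`, `c_ij ~ N(0,σ_c²)` | Satterthwaite *t* |
  | `meta`   | per-batch differences `T_i = μ + e_i + ε_i`, `e_i ~ N(0,v_i²)`, `ε_i ~ N(0,τ²)` | *z* |

* **operating characteristics** — a seeded Monte-Carlo engine estimating
  false-positive and false-negative rates per method over scenario grids
  (batch variation, inhibition, effect heterogeneity, group size, number of
  batches), plus a closed-form noncentral-*t* sample-size search and
  animal-budget arithmetic for comparing designs.

## Worked example

Simulate one 3-batch experiment (5 animals per arm per batch, MC38-like
baseline: mean rate 0.105 log10 mm³/day, SD 0.026, batch SD 20% of the
baseline mean, a consistent 30% growth-rate inhibition), then analyse it
with all four methods:

```bash
$ cat sim.yaml
baseline_mean: 0.105
baseline_sd: 0.026
batch_sd_prop: 0.2
gri: 0.3
seed: 11

$ multibatch simulate --config sim.yaml --out rates.csv
$ multibatch analyze --in rates.csv --method all --out results.json
```

`results.json` (abridged):

```
pooled: estimate=-0.03707  se=0.00838  t=-4.42  df=28    p=1.35e-04
fixed : estimate=-0.03707  se=0.00811  t=-4.57  df=24    p=1.24e-04
random: estimate=-0.03707  se=0.00810  t=-4.58  df=30.0  p=7.69e-05
meta  : estimate=-0.03724  se=0.01107  z=-3.36           p=7.72e-04
```

All four agree on the point estimate (a drop of ≈0.037 log10 mm³/day,
close to the simulated truth 0.3 × 0.105 = 0.0315; the balanced-design
estimate is the unweighted mean of per-batch group differences for every
method). They differ in the uncertainty they attach to it: here the mixed
model's variance components truncate at zero (no detectable batch
structure, `boundary: true`), so its inference approaches the pooled
*t*-test, while the meta-analysis — which estimates a between-batch effect
variance `tau2` from only three batches — is the most conservative call on
this dataset.

In simulation studies the ranking reverses under stress: as batch variation
grows the pooled test loses both type I error and power, the fixed-effects
and mixed models stay calibrated near 5%, and the meta-analysis *z*-test is
mildly liberal. Those rates come from the engine:

```bash
multibatch fpr --config null_grid.yaml --out fpr.csv     # gri = 0 grids
multibatch fnr --config effect_grid.yaml --out fnr.csv   # gri > 0 grids
multibatch power-grid --config design.yaml --method random --out power.csv
multibatch design-table --out designs.csv
```

`design-table` reproduces the animal-budget comparison: a 3-batch × 6 per
group × 2-group design uses 36 animals, whereas replicating a 28-animal
one-batch experiment three times uses 84 — a 57% saving.

Every result-writing command also writes `<out>.manifest.json` (resolved
config, root seed, SHA-256 of outputs) so any run can be replayed
bit-for-bit; all randomness derives from the single root seed, with each
Monte-Carlo replicate on its own deterministic child stream.

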