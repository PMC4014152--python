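# clonobranch

Branching-process analysis of abortive colony formation and clonogenic
survival after irradiation.

## The problem

In a clonogenic assay, an irradiated cell either founds a large, growing
("clonogenic", ≥ 50 cells) colony — it survives — or leaves behind a small
**abortive colony** (2–49 cells) whose lineage hit reproductive cell death
(RCD) somewhere along the way.  Abortive colonies are usually discarded as
"non-survivors", but their size distribution encodes *when* the progeny of
an irradiated cell stopped dividing: a 2-cell colony died at the first
branch point, a 40-cell colony carried damage through several generations.
`clonobranch` turns that distribution into a per-generation RCD probability
profile and uses it to predict survival, for both low-LET (γ-ray) and
high-LET (carbon-ion) exposure.

## The model

Each cell at generation *g* either dies with probability *P₁(g)* or divides
into two daughters with probability *P₂(g) = 1 − P₁(g)* (a Galton–Watson
process).  The frequency of an *n*-cell abortive colony founded at
generation *g* satisfies

```
f₁⁽ᵍ⁾ = P₁(g)
fₙ⁽ᵍ⁾ = P₂(g) · Σⱼ f₁₊ⱼ⁽ᵍ⁺¹⁾ · fₙ₋ⱼ₋₁⁽ᵍ⁺¹⁾     (n ≥ 2, j = 0..n−2)
```

For constant *P₁ = p* this has the closed form
*fₙ = Cₙ₋₁ pⁿ (1−p)ⁿ⁻¹* (Catalan numbers *Cₖ*), which at criticality
(*p = ½*) decays as *n^(−3/2)* — the origin of the straight line abortive
size distributions trace on a log–log plot.

The analysis pipeline:

1. **Imputation** — 1-cell colonies are invisible in the assay; their
   frequency is `f₁ = √F₂` from the observed 2-cell frequency.
2. **Log–log regression** with a 95 % confidence band smooths the observed
   distribution.
3. **Inversion** — the triangular system above is solved generation by
   generation (bisection) to get *P₁(0..5)*, with bounds from the band.
4. **Tail extension** — *P₁* declines linearly from generation 5 to 16,
   with *P₁(16) = (1 − c)·P₁(5)*; the constant *c* is selected by AIC
   against the observed distribution.
5. **Lattice Monte Carlo** — colonies grow on a 2D grid (31.6 µm cells,
   Moore neighborhood, contact inhibition, 16 synchronous doublings) to
   predict plating efficiency, surviving fraction SF, *D₁₀ = ln 10 / a*
   from the fit SF = exp(−a·dose), and the RBE as a *D₁₀* ratio.

Because the original colony-count tables are not published, the
`synthetic` module generates studies with the same layout (3 experiments ×
quadruplicate, doses 0–3 Gy, multinomial counting noise) from known ground
truth, so every estimator is tested by parameter recovery.

## Worked example

```python
import numpy as np
import clonobranch as cb

# generate a synthetic carbon-ion study (3 experiments x 4 replicates per dose)
study = cb.generate_study(cb.SyntheticStudyConfig(seed=42))
obs = cb.pool_counts(study.table, 3.0)          # pooled counts at 3 Gy

est = cb.estimate_rcd_profile(obs, mode="smoothed", fit_range=(1, 8))
print("log-log slope :", round(est.fit.slope, 3), " R^2:", round(est.fit.r_squared, 4))
print("P1(0..5)      :", np.round(est.profile.p1, 3))
print("truth         :", np.round(study.truth[3.0].p1[:6], 3))

profile = cb.extend_profile(est, c=0.4)          # linear tail to generation 16
print("P1(16)        :", round(profile.p1[16], 3))

cfg = cb.SimulationConfig(seed=7, n_colonies_per_run=10_000, n_runs=5)
control = cb.simulate_experiment(cb.default_dose_profiles()[0.0], cfg)
res = cb.simulate_experiment(profile, cfg)
print("plating eff.  :", round(res.plating_efficiency(), 3))
print("SF at 3 Gy    :", round(cb.surviving_fraction(res, control), 3))
```

prints

```
log-log slope : -1.985  R^2: 0.9998
P1(0..5)      : [0.471 0.475 0.449 0.43  0.418 0.412]
truth         : [0.48  0.48  0.453 0.432 0.419 0.412]
P1(16)        : 0.247
plating eff.  : 0.217
SF at 3 Gy    : 0.263
```

The estimated death probabilities track the generating truth to ~0.01; the
extended profile then drives the lattice assay, where 21.7 % of inoculated
cells still form clonogenic colonies at 3 Gy, i.e. a surviving fraction of
0.26 against the unirradiated control.

The same stages are available on the command line
(`clonobranch synth | estimate | simulate | select-c | rbe |
threshold-scan | secondary`); each stage reads and writes TSV/JSON files
and drops a manifest with seeds and versions next to its outputs.

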