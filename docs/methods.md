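# Methods

## Branching model

A colony founded by one cell evolves by synchronous generations: at
generation *g* every live cell independently dies (reproductive cell
death, RCD) with probability *P₁(g)* or divides with probability
*1 − P₁(g)*.  Colony size counts terminal cells — a mother is replaced by
its two daughters, and dead cells stay visible — so the size of a fully
abortive colony equals the number of leaves of its binary lineage tree.
The size pmf is computed by the convolution recursion

    f₁⁽ᵍ⁾ = P₁(g),
    fₙ⁽ᵍ⁾ = (1 − P₁(g)) Σⱼ f₁₊ⱼ⁽ᵍ⁺¹⁾ fₙ₋ⱼ₋₁⁽ᵍ⁺¹⁾,

reported at *g = 0*.  The recursion runs top-down from the deepest level
that can matter (a subtree rooted at depth *g* inside an *n*-cell colony
has at most *n − g* leaves), costs O(n²·G), and reduces exactly to the
classical constant-*p* recursion, for which a dedicated O(n²) path exists
(needed for the *n* ≤ 1000 critical-slope computation).  Profiles are
continued at their last stored value beyond the defined horizon.

Tests validate the recursion against two independent oracles: exhaustive
enumeration of all binary death/division tree shapes (n ≤ 6, any profile)
and the Catalan closed form *fₙ = Cₙ₋₁ pⁿ(1−p)ⁿ⁻¹* for constant *p*.  The
total abortive mass equals the extinction probability
min(1, p/(1−p)); at criticality the pmf decays as *n^(−3/2)*, which is
what makes observed abortive distributions straight on a log–log plot.

## Estimating P₁(g) from colony counts

The assay observes colonies with ≥ 2 cells.  The pipeline:

1. *f₁ = √F₂* imputes the unobservable 1-cell frequency from the observed
   2-cell frequency, assuming equal RCD probability at generations 0 and 1
   (under that assumption *F₂ = f₂/(1 − f₁) = p²* exactly).
2. Observed frequencies are rescaled to the all-colony scale,
   *fₙ = Fₙ(1 − f₁)*.
3. Unweighted OLS of log₁₀ fₙ on log₁₀ n (base-10; the base only shifts
   the intercept).  Zero-count classes are dropped — no pseudo-counts.
   The 95 % band is the confidence interval of the regression mean
   (t distribution, n−2 df).
4. Fitted frequencies f̂₁..f̂₆ are inverted generation-by-generation:
   *f₁* fixes *P₁(0)*; given earlier generations, *f_{g+1}* is a
   polynomial strictly increasing in *P₁(g)* on [0, 1] (every depth-*g*
   cell of a (g+1)-cell colony is necessarily terminal), so bisection is
   exact.  Bisection runs to machine precision: the triangular system can
   amplify early round-off by ~10⁵ at the deepest generations, so a loose
   tolerance would visibly bias *P₁(4..5)*.
5. The inversion is repeated at the band edges for per-generation 95 %
   bounds (clamped to [0, 1] and ordered around the point estimate).

A `raw` mode inverts the renormalized frequencies directly.  When the
input carries counts, its bounds re-invert each generation's own
frequency at ±1.96 multinomial standard errors (the triangular structure
makes this the per-generation profile of the counting uncertainty).  A
sampled frequency can fall below the attainable floor of the recursion —
e.g. an under-sampled f₆ in a weakly-lethal control; the
`on_infeasible="clamp"` option then returns the boundary probability, the
usual constrained-estimator convention, while the default raises an error
naming the generation.

**Fit range.**  The regression's default range is the full abortive span
(1–49), but the estimation and acceptance pipelines fit sizes 1–8.  The
branching pmf of a profile with a declining tail departs from a pure power
law beyond the head — late generations with low *P₁* make large abortive
colonies rarer than the head power law predicts — and a full-range fit on
densely sampled data picks up that curvature (up to intercept overshoot
past f₁ = 1).  Sizes 1–8 are the region actually informative about
generations 0–5, and the choice mirrors the earlier observation that the
log–log linearity is cleanest below ~16 cells.

**Tail extension.**  Beyond generation 5 the profile declines linearly to
*P₁(16) = (1 − c)·P₁(5)*.  *c* is selected by least-squares AIC,
N·ln(RSS/N) + 2k with k = 1, on log₁₀ residuals between observed and
model distributions over the abortive sizes; frequencies are normalized
first, so the selection is invariant to count rescaling.  A perfect fit is
reported as −∞ with a flag.

**Excess RCD** is irradiated minus control, per generation — positive when
irradiation increases death.  (Describing it the other way round flips
every sign; the convention here makes dose-dependent excess positive.)

## Lattice simulator

One cell starts at the origin of an unbounded square lattice (sparse
occupancy; the 31.6 µm grid cell and 20 h doubling time are bookkeeping).
Each synchronous step *g*: cells act in creation order; a cell with at
least one free Moore neighbor is at a *branch point* — it dies with
probability *P₁(g)* (remaining on the lattice as a permanent blocker by
default) or divides, placing one daughter uniformly on a free neighbor.
A contact-inhibited cell has no branch point: it neither dies nor divides
(`blocked_cells_die=True` restores a death draw for blocked cells;
`retain_dead_cells=False` lets dead cells vacate their site).  Daughters
born in a step act from the next step.  After `n_generations` (default 16)
steps the occupied-site count is the colony size; plating efficiency is
the fraction of colonies at or above the clonogenic threshold (50 cells),
and SF is the plating-efficiency ratio against the same-quality 0 Gy
control.

The per-colony loop is a numba kernel.  Runs are reproducible: run *r* of
a simulation draws its RNG stream from `SeedSequence(master_seed,
spawn_key=(r,))`.  With contact inhibition off the model is exactly the
branching process and is simulated by vectorized binomial draws.

**Horizon in the equivalence check.**  The analytic pmf is the
infinite-horizon distribution.  At *p* = 0.6 about 0.7 % of colonies are
still mid-growth at generation 16 and would be recorded at intermediate
sizes, so the simulator-vs-model goodness-of-fit runs 48 generations
(residual live fraction ≈ 5×10⁻⁶ — under one colony in 50 000).  The
16-generation horizon is used everywhere else; it is part of the assay
being modeled.

**Secondary colonies** re-plate cells harvested after primary growth:
their residual RCD probability is the primary profile's value at
generation 16, held constant through secondary growth, and SF is
normalized to the control's secondary plating efficiency.

## Synthetic studies

`generate_study` emulates the assay layout: 3 independent experiments ×
4 replicate dishes per dose, ~4 167 inoculated cells per replicate
(≈ 50 000 colonies per dose), counts per size class 1–49 plus a ≥ 50
bucket, pure multinomial noise (no overdispersion — none is modeled in
the analysis either), deterministic sub-seeding per (dose, experiment,
replicate).  A `lattice` generator runs every inoculated cell through the
grid simulator instead of the analytic pmf.

**Truth profiles.**  The observed abortive distributions are straight on
log–log axes (R² ≈ 0.98); an arbitrary smooth profile does *not* have that
property, and feeding such data to the smoothing step would bias it by
construction.  The default truths are therefore built *from* power laws:
for head probability *p*, the distribution *fₙ = p·n^s* with
*s = log₂(p(1−p))* is the unique power law consistent with *f₁ = p* and
the imputation identity *f₁ = √F₂*; inverting f₁..f₆ yields P₁(0..5).
Carbon-ion heads are p = 0.42 / 0.45 / 0.48 at 1 / 2 / 3 Gy (near-critical,
matching the steep lethality of high-LET exposure), the unirradiated
control keeps constant P₁ = 0.15, and all profiles extend with c = 0.4.
A matched γ study reuses the carbon heads at four-fold doses
(interpolating head probabilities between the anchors), emulating the
observed equivalence of excess-RCD kinetics at 1 Gy carbon and 4 Gy γ.

Calibration at this scale (50 seeds): smoothed-mode recovery of P₁(0..5)
is within ±0.03 per generation with ~100 % coverage of the 95 % bounds at
the irradiated doses.  The control's P₁(5) is intrinsically
ill-determined — f₆ of a weakly-lethal profile has ~10 expected counts in
50 000 colonies and a sensitivity of ~5×10⁻⁴ per unit probability — so
control recovery is assessed through its (wide) raw-mode bounds.

**Dissociation experiment.**  Varying *c* between 0.1 and 0.4 at the top
dose with fixed P₁(0..5) changes the abortive distribution over n ≤ 15 by
≈ 0.002 absolute frequency but shifts survival by ≈ +23 % (percent change
from the first-listed condition, c = 0.1; both variants share one master
seed, so the head generations use common random numbers).  Short-term RCD
sets the abortive distribution; long-lasting RCD sets the surviving
fraction.

## Downstream statistics

- Survival fits: least squares of ln SF = −a·dose through the origin
  (no shoulder term), SF = 0 points excluded with a warning; R² on the
  log scale; D₁₀ = ln 10/a; RBE = D₁₀(reference)/D₁₀(test).
- Curve comparisons: per dose, a 1-df chi-squared on
  (clonogenic, non-clonogenic) counts, expected values scaled from the
  simulated clonogenic proportion; Bonferroni correction over the doses
  compared.
- Threshold scans recompute SF and refit at clonogenic criteria 10–100
  cells; the exponential fit degrades as the threshold shrinks.

## Problem sizes

Acceptance-style checks use 50 000 colonies per simulated condition
(10 000 × 5 runs), 50 000-colony synthetic studies, 10 seeds for the AIC
round trip, and 200 000 colonies per arm of the dissociation experiment;
unit tests use smaller sizes.  The full suite runs in well under a minute
after the numba kernel compiles.

## Known limitations

- The default truth heads compress the carbon dose response (head
  probabilities 0.42–0.48 over 1–3 Gy), so the synthetic study's survival
  curve saturates rather than following a clean single-hit exponential;
  the through-origin exponential fit can then have low or negative R² at
  the default threshold.  The fit, D₁₀ and RBE are still well-defined
  summaries and the dissociation/threshold-scan properties are unaffected.
- Cell-cycle asynchrony, cell loss before counting, migration and
  non-binary division are not modeled; generations are a global clock.
- Replicate noise is purely multinomial; real assays show between-dish
  overdispersion.
- Passing recovery tests on these synthetic studies demonstrates that the
  estimators invert the model they assume — it cannot certify the model
  against real colony-count data, which are not publicly available.
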