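# Methods

## The model

`mitoflux` analyzes enterocyte mitochondrial energy metabolism as a
constraint-based (stoichiometric) model. A metabolic network with
stoichiometric matrix **S** (metabolites × reactions) is assumed to
operate at steady state, so admissible flux vectors **v** form the
polytope

    P = { v : S·v = 0,  lb ≤ v ≤ ub },

with bounds in mmol per g dry intestinal tissue per hour. No kinetic
parameters enter; diet acts purely through the lower bounds of the
`EX_` exchange reactions (uptake is negative flux, BiGG convention).
Reversibility is encoded by the bounds alone: a reaction is reversible
iff its lower bound is negative.

Three compartments are modeled: lumen `u`, cytosol `c` and
mitochondrial matrix `m`. The mitochondrial outer membrane is treated
as freely permeable, so the intermembrane space is merged into the
cytosol; protons pumped by the respiratory chain therefore land in `c`.

## The fixture network

`build_fixture_model()` emits a reduced, fully documented enterocyte
mitochondrial network (~110 metabolites, ~110 reactions) covering
luminal TAG hydrolysis and absorption, glucose uptake, lumped
glycolysis, lactate fermentation, glycerol utilization, the carnitine
shuttle per fatty-acid species, lumped β-oxidation per species, the
full TCA cycle, the electron transport chain over explicit quinone and
cytochrome-c pools, ATP synthase and the adenine-nucleotide/phosphate
carriers, with a cytosolic ATP demand as objective. Each dietary
fatty-acid species is supplied as a *uniform triacylglyceride* (three
identical acyl chains), one exchange per species.

Species formulas for the acyl intermediates are derived arithmetically
from chain length *n* and double-bond count *d* (e.g. acyl-CoA is
C(n+21) H(2n+30−2d) N7 O17 P3 S), so every non-boundary reaction is
balanced for C, H, N, O, P, S, Fe and charge **by construction**; the
test suite audits this per reaction.

### β-oxidation stoichiometry

A C(2k) acyl-CoA takes k−1 cycles and yields k acetyl-CoA. Every cycle
reduces one NAD⁺; every cycle except those consuming a pre-existing
double bond (handled by the isomerase route) reduces one FAD:

    acetyl-CoA = n/2,  cycles = n/2 − 1,  NADH = cycles,
    FADH2 = cycles − d.

This is a deliberate simplification: the NADPH-consuming
2,4-dienoyl-CoA reductase steps required for even-numbered double bonds
are *not* modeled, and DHA is oxidized entirely in the matrix with no
peroxisomal pre-shortening. Both choices keep the lumped reactions
linear in the classical cofactors; they slightly overestimate the
energy yield of PUFAs relative to full biochemistry.

### Proton economy and ATP yields

Default pumping stoichiometry (all configurable via `FixtureConfig`):
complex I 4 H⁺/NADH, complex III 4 H⁺/QH₂, complex IV 4 H⁺/O₂ (2 per
electron pair), ATP synthase 4 H⁺ from the cytosolic face per ATP
(3 returned to the matrix by the condensation chemistry), phosphate
carrier 1 H⁺ symported, ANT modeled proton-neutral. Per matrix NADH
this pumps 10 H⁺ and per FADH₂-level quinol 6 H⁺, at an effective cost
of 4 H⁺ per ATP delivered to the cytosol — P/O ratios of 2.5 and 1.5.

The resulting maximal yields have closed forms, used as independent
oracles in the tests:

    ATP/glucose   = (10·10 + 6·2)/4 + 4           = 32
    ATP/FA(n,d)   = (10·N + 6·Q)/4 + n/2 − 2,
                     N = cycles + 3·(n/2), Q = (cycles − d) + n/2
    ATP/glycerol  = (10·6 + 6·1)/4 + 1             = 18.5
    ATP/TAG(n,d)  = 3·ATP/FA + ATP/glycerol

e.g. 336.5 per tripalmitin and 435.5 per tri-DHA TAG. Anaerobically
(O₂ exchange closed) only fermentation to lactate remains: 2
ATP/glucose. Deleting the ATP synthase blocks all matrix proton return
and with it the entire respiratory chain, so the optimum also collapses
to the fermentative 2 ATP/glucose.

Phosphorus is conserved by every internal cycle, so the phosphate
exchange and absorption reactions are structurally zero ("blocked" in
flux-variability terms). They are retained because the inorganic pools
must remain exchangeable when the model is extended.

## Diet constraints

Seven diets are built in, transcribed from the feed-composition table of
the two underlying mouse studies: FISH0/15/44 (isocaloric high fat,
35.2% lipid wt/wt, increasing fish-oil fraction) and FAT10/20/30/45
(increasing lipid/carbohydrate ratio). For fatty-acid species *f* with
profile p_f (g per 100 g lipid) the daily uniform-TAG supply is

    grams_f = food_intake · lipid_frac · p_f / 100
    bound_f = absorption_fraction · 1000·grams_f / MW_TAG(f)
              / (intestinal_dry_mass · 24 h)      [mmol gDW⁻¹ h⁻¹]

with MW_TAG = 3·MW_FA + MW_glycerol − 3·MW_water; glucose analogously
from its g/100 g diet content with MW 180.16. Bounds are uptake
**ceilings** (lower bounds on exchanges), not forced rates. A FISH diet
constrains nine exchanges (glucose + 8 TAG species), a FAT diet seven.

Default physiology, required because the source studies report intake
only in their own supplements: isoenergetic feeding at ≈60 kJ/day gives
FAT10→FAT45 intakes of 3.7/3.5/3.3/3.0 g/day (60 ÷ energy density);
the FISH diets (identical energy density) are assigned 2.7/2.6/2.5
g/day, a slight dose-dependent decrease reflecting the reported
(non-significant) intake differences under fish-oil feeding. Intestinal
dry mass defaults to 0.25 g and absorption to 1.0. All of these are
assumptions, configurable per run, and publication-grade work should
supply measured values; the directional cross-diet comparisons below
are insensitive to the common scale factors (dry mass, absorption) and,
for the FAT series, to plausible intake variation, but the FISH-series
PDHm ordering rests on the assumed intake gradient, since composition
and energy density are identical across the FISH diets.

## Flux balance analysis

Maximal ATP production (the demand reaction `DM_atp_c`) is the
objective for every simulation. LPs are solved with HiGHS through
scipy; the returned flux vector at a degenerate optimum is **one**
optimal vertex — only the objective value is contract-stable. The
integrity check verifies ATP producibility and absence of dead-end
metabolites (a metabolite producible but not consumable or vice versa,
accounting for reversibility), and reports blocked reactions from
flux-variability analysis with all exchanges opened.

## ACHR sampling

The near-optimal flux space is characterized with artificial-centering
hit-and-run. Warm-up points are stored as columns of a matrix W with
running center s; each iteration picks a random warm-up column y, steps
from the current point along (y−s)/‖y−s‖ by a length drawn uniformly on
the feasible chord (with a relative inset of 1e-10 to avoid sticking to
faces), substitutes the new point into W at a random column and updates
the center. Every `steps_per_point`-th iterate is recorded.

Numerical choices:

* Sampling runs in an orthonormal basis of null(S) (augmented with any
  fixed-flux equalities), so S·v = 0 holds to machine precision and
  only box bounds remain as inequalities; recorded samples satisfy
  ‖S·v‖∞ < 1e-6 and bounds within 1e-9 by contract.
* The chain starts from a Chebyshev-style interior LP solution.
* `n_warmup` defaults to max(2 × dim, 200) capped at 5000. The floor
  matters: with very few warm-up columns the direction set is too
  coarse and the stationary distribution is measurably non-uniform on
  low-dimensional polytopes (one-sample KS against the analytic
  marginal of a 2-D test polytope: D ≈ 0.047 at 2×dim = 4 columns,
  D ≈ 0.009 at 200).
* Direction vectors are normalized; this re-parameterizes the step
  length only and does not change the sampled distribution.
* By default the ATP demand is first constrained to ≥ 99% of its FBA
  maximum, so the sampler describes the flux space *under the
  maximal-ATP objective*; `fraction_of_optimum=None` (CLI
  `--no-optimality`) samples the unconstrained polytope. Both modes are
  first-class; the default reconciles an objective-driven simulation
  with a sampling-based characterization.
* A zero-volume polytope (all fluxes fixed) returns the single feasible
  point with a warning.

The full-scale protocol is 2000 recorded points with 500 iterations
between points; the pipeline's default reduced scale is 500 points ×
100 iterations (`--paper-scale` restores the full protocol), which is
the problem size used throughout the test suite and the acceptance
script.

## Statistics

Per-reaction flux distributions are summarized by median and quartiles
(linear-interpolation convention) and compared across diets with
one-way ANOVA followed by the Tukey–Kramer HSD post hoc test (unequal n
supported, via the studentized-range distribution). Pairwise outcomes
are condensed into a compact letter display by the insert-and-absorb
algorithm, with ties broken by the supplied group order; groups sharing
no letter differ at α (letters are keyed to the mean-based post hoc
comparison; medians are what the boxplots show). Sampled points are
treated as independent observations, replicating the source procedure —
MCMC autocorrelation inflates the effective sample size, so a `thin`
factor is available for more conservative inference. Pearson
correlation uses the t-transform for the two-sided p and the Fisher-z
95% CI, with an exact fast path returning r = ±1 on exactly collinear
input. If every group has zero variance, equal means give the p = 1
path and shared letters.

## What the fixture does and does not show

The fixture reproduces the *structure* of the published analysis — a
gap-free three-compartment network whose maximal-ATP flux space
responds directionally to diet: β-oxidation fluxes of the supplied
species rise and PDH/TCA fluxes fall as the lipid/carbohydrate ratio
increases, and the EPA/DHA β-oxidation fluxes rise with the fish-oil
fraction. It does not reproduce the published model's inventory (311
reactions, 127 genes) or its absolute flux magnitudes, which depend on
intake and tissue parameters not printed in the source; the loaders
accept the published supplementary tables (tabular dialect) when
available. Passing tests therefore demonstrate correctness of the
machinery and the direction of diet responses, not quantitative flux
predictions for real tissue. The statistics also inherit the source
procedure's caveat that "significance" across 500–2000 sampled points
reflects sampling resolution, not biological replication.
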