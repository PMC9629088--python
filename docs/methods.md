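# Methods

`microdiet` re-implements, as a tested analysis pipeline, an AI-based
personalized-nutrition workflow for irritable bowel syndrome (IBS-M): a
microbiome-derived disease index, a Monte-Carlo search for a minimal
microbiome modulation that lowers that index, an inversion step that turns
the modulation into micronutrient doses, and the community-level and
clinical statistics used to evaluate the intervention. The original trial's
cohort data are not public, so every data-dependent stage runs on synthetic
compositional data whose construction is documented here, together with the
choices made where the design was genuinely open.

## The IBS index

Genus-level relative-abundance profiles `x` (vectors on the simplex) are
scored by a gradient-boosted-tree binary classifier (XGBoost, DART booster,
binary logistic objective) trained to separate IBS from healthy profiles.
The classifier's logistic output in [0, 1] is the *IBS index*; higher means
a more IBS-like community. Features are the raw relative abundances — tree
splits are scale-free, so no log-ratio transform is applied before the
model. Defaults: `max_depth 4`, `learning_rate 0.1`, `n_estimators 150`,
`subsample 0.8`, `rate_drop 0.1`. Hyperparameters can instead come from a
seeded random search over a fixed space (depth 2–6, log-uniform learning
rate 0.01–0.3, 50–300 rounds, subsample 0.5–1, dropout 0–0.3), the best
trial selected by mean inner-CV ROC-AUC with ties broken toward the earlier
trial. Performance is reported by stratified k-fold cross-validation
repeated over seeds (default 5 folds × 10 seeds); accuracy uses a fixed 0.5
threshold on the index.

## Modulation search

For a patient baseline `x₀` (pseudocounted once, see *Numerical policies*),
the walk iterates:

1. **Propose.** Each taxon is independently selected with probability
   `p_perturb` (default 0.1); selected taxa are multiplied by
   `exp(N(0, kernel_sd²))` (default `kernel_sd` 0.25) and the vector is
   re-closed. The multiplicative kernel preserves positivity on the simplex.
2. **Constrain.** Proposals farther than `distance_budget` (default 2.0
   Aitchison units) from the baseline are rejected outright — the hard-budget
   formalization of "a nearby composition with minimal modulation".
3. **Accept.** Metropolis rule `min(1, exp((s_cur − s_prop)/T))` on the index
   `s`, temperature `T` = 0.02. Every strictly-improving proposal is
   accepted; occasional worsening moves let the walk cross the flat plateaus
   a tree ensemble's piecewise-constant score surface produces. A literal
   "probability proportional to the decrease" is not a normalizable rule, so
   the standard Metropolis form is used.

The walk runs a fixed `n_iterations` (default 2000; no convergence
heuristic, for reproducibility) and returns the best-scoring accepted state.
It is an optimizer, not a posterior sampler. The temperature default was
picked so that a typical plateau-crossing move (index increase ≈ 0.01–0.05)
is accepted a few percent of the time; with `T → 0` the walk degenerates to
greedy descent (covered by tests).

## Nutrient inversion

The mapping from daily micronutrient intake to microbiome change is modeled
as a linear operator in clr space: response matrix `B` (taxa × nutrients,
clr shift per g/day) with per-nutrient dose bounds. The real
nutrient→microbiome database behind the original workflow is proprietary
and undisclosed; the linear model is an explicit, swappable stand-in and
every synthetic instance is labeled as such. Doses solve

    min_η ‖Bη − Δ‖²  s.t. 0 ≤ η ≤ bounds,  Δ = clr(target) − clr(baseline)

via the exact BVLS active-set method (`scipy.optimize.lsq_linear`), which is
deterministic. The predicted post-diet composition is
`clr⁻¹(clr(x₀) + Bη)` and is rescored by the index model. Because `B` has
far fewer columns than there are taxa, the achieved shift is the projection
of Δ onto the bounded cone spanned by `B` — the realized index drop is
typically smaller than the walk's best index, which is the honest behaviour
of the chain.

## Synthetic data: what it emulates, and what it does not

**Cohorts** are logistic-normal: per-taxon independent Gaussians on the
natural-log scale (`base_log_mean` ~ N(0, 1.5) fixed per world seed,
`log_sd` 0.6), exponentiated and closed. Disease effects enter as log2
fold-changes added to the IBS group's log-means *before* closure, so
injected effects are exact on the unclosed scale and re-estimable in sign.
The default signature is a 10-genus dysbiosis axis led by *Faecalibacterium*
depletion (−1.5 log2) and *Ruminococcus* enrichment (+1.5 log2), padded with
eight moderate effects (±0.5–1 log2 on *Clostridium*, *Bacteroides*,
*Bifidobacterium*, *Roseburia*, *Prevotella*, *Streptococcus*,
*Akkermansia*, *Blautia*). These defaults are set so the synthetic cohorts
reproduce the qualitative study conditions — clearly separated beta
diversity and a cross-validated AUC near 0.95 — not any particular printed
number.

**Zeros** are generated as a per-sample detection limit: the lowest
`zero_inflation` fraction (default 0.3) of a sample's raw abundances reads
as zero before closure. This makes rare and depleted taxa go unobserved more
often, which is both the actual sequencing mechanism and the only way
presence/absence metrics (unweighted UniFrac) can carry group signal; a
uniform Bernoulli dropout would decouple presence from the disease axis.

**Trees** are random rooted binary taxonomies (uniform [0.1, 1] branch
lengths) — they give UniFrac a branch-length structure but encode no real
phylogeny.

**Interventions** push compositions through the same linear response model
the diet-design stage inverts: `post = clr⁻¹(clr(pre) + Bη + noise)`,
`noise` i.i.d. N(0, 0.05) in clr coordinates. Synthetic response models can
include "signature" nutrients whose columns align with ± the dysbiosis
axis, emulating a curated database that contains ingredients known to act
on disease-relevant taxa; purely random sparse columns (the other
nutrients) rarely span the index-relevant directions.

**Clinical scores** couple the five-item symptom instrument linearly to the
index: `total = clip(150 + 300·index + N(0, 40), 0, 500)`, allocated across
items with fixed weights (0.21, 0.17, 0.21, 0.21, 0.20) matching typical
pre-intervention item proportions, each item clipped to [0, 100]. Noise is
added before clipping so totals stay in the instrument's range. With these
defaults a 0.9-index patient sits around 420 (severe) and a 0.3-index
subject around 240 (moderate), spanning the clinically relevant range.

What passing tests on this generator do **not** show: real gut profiles
have taxon-taxon correlations, compositional covariance and overdispersion
the independent-log-normal model lacks; the real nutrient response is
neither linear nor known; and the symptom coupling in reality is far
noisier than a single linear band. The suite validates the *machinery* —
calibration of the tests, correctness of the oracles, direction of the
end-to-end effect — not clinical effect sizes.

## Statistics

* **Alpha diversity**: Shannon entropy (base 2) and observed richness; the
  instrument used in the original analysis is unnamed, so Shannon is fixed
  here.
* **Beta diversity**: Bray-Curtis, and unweighted UniFrac with presence
  defined as abundance strictly greater than the pseudocount (1e-6), so
  pseudocounting can never create presence. Both delegate to scikit-bio and
  are checked against an exhaustive branch-set oracle on all trees with ≤ 6
  leaves.
* **PERMANOVA** (scikit-bio, seeded): `p = (1 + #{F* ≥ F}) / (1 + n_perm)`;
  default 9,999 permutations at desk scale (the original used 10⁶, which
  remains available by flag). Validity is established by simulation: the
  type-I error at α = 0.05 stays inside the binomial 99% band over 200 null
  cohorts.
* **Per-taxon screen**: two-sided Mann-Whitney U (exact null when both
  groups ≤ 8 without ties, else tie-corrected normal approximation), BH
  step-up q-values checked against a literal step-up oracle. Constant taxa
  record p = 1 rather than erroring.
* **Paired contrasts**: two-sided paired t, also available from summary
  statistics (`t = m/(s/√n)`); zero-variance nonzero-mean differences are
  reported as p = 0 with a degenerate-variance flag.
* **Effect sizes**: for the one-predictor regression of symptom totals on
  index scores, `ω² = (SS_effect − MS_error)/(SS_total + MS_error)` (may be
  negative), and `f² = ω²/(1 − ω²)` — from ω², not R², because the published
  combined-group f² matches the ω² form. ω² = 1 (perfect fit) yields
  f² = +∞ rather than an error.

## Numerical policies

* Pseudocount 1e-6 added to every part, then re-closure, before any
  log-ratio transform; applied only to rows that actually contain zeros so
  a no-op transform chain reproduces its input to float precision. Applied
  once before a Metropolis walk.
* Severity cut-offs 75/175/300 with left-closed bands
  (remission < 75 ≤ mild < 175 ≤ moderate < 300 ≤ severe).
* Significance level 0.05 throughout.
* All randomness flows from one master seed; each stage derives its own
  31-bit stream as `SeedSequence([master, crc32(stage_name)])`, so adding or
  reordering stages never shifts another stage's draws. Fixed seed implies
  bit-identical outputs, including the study report JSON.
* Leave-one-out cross-validation (k = n) uses unstratified folds, since
  stratified folds of size 1 are impossible.

## Problem sizes

The shipped configuration mirrors the trial layout: 34 healthy controls,
25 IBS-M patients, 14 personalized-arm and 11 standard-diet-arm, 50 genera.
The test and acceptance runs use desk-scale sizes chosen once: 60/60
cohorts for classifier checks, 200 null replicates × 999 permutations for
PERMANOVA calibration, 5,000-iteration walks against a 0.01-step simplex
grid for the optimizer oracle, and 30 patients per arm for the end-to-end
intervention contrast.

## Known limitations

* The linear clr-space nutrient response is a declared fiction; nothing
  here estimates a real diet-microbiome mapping.
* The walk optimizes a tree-ensemble score whose plateaus make progress
  seed-dependent; runs are reproducible but individual patients can see
  little improvement within the distance budget.
* The published control-group Cohen's f² (3.09) is inconsistent with its
  printed negative ω² (−0.33) under any of the standard identities and is
  not reproduced.
* The published change table prints the control quality-of-life delta as
  −1.4 while the arm-level means give +1.4; the recomputed sign is kept.
* Between-arm contrasts in the original tables are labeled "paired t-test"
  although the arms are independent groups; this package reports two-sample
  tests for between-arm contrasts.
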