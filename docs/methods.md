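# Methods

This note documents the models, defaults and numerical choices behind
`oralmark`, and what the synthetic-cohort generator does and does not
emulate.

## Data model

An `OtuTable` is an integer taxa × samples count matrix with one
semicolon-delimited taxonomy lineage per taxon (Greengenes/SILVA-style
`k__;p__;…;s__` prefixes are understood but not required). Clinical
metadata is one CSV row per stool sample: subject id, cohort
(discovery/validation), PPI exposure, Child-Pugh (5–11), MELD, follow-up
months, event (`liver_death`/`censored`) with an optional censor reason
(transplant, lost, alive at end of window), and optional barrier markers
(faecal calprotectin and zonulin in ng/mg, serum LPS in EU/ml).

## Preprocessing

**Low-abundance filter.** A taxon is dropped if it is present (count > 0)
in fewer than 2 samples of the pooled discovery cohort, or if its summed
reads are below 0.05% of all reads. The 0.05% boundary is read strictly: a
taxon at exactly 0.05% is retained. Both the prevalence unit (samples vs
subjects, for designs with repeated sampling) and the thresholds are
config keys.

**Rarefaction.** Each sample is subsampled without replacement to a fixed
depth (a single multivariate-hypergeometric draw per sample, seeded);
samples below depth are dropped and logged, never imputed. Two depths
coexist as config defaults: 27,332 reads for composition/diversity
analyses and 16,703 reads for biomarker screening. A mean-of-k-draws
variant (`rarefy_mean`) exists for sensitivity analysis only.

**Composition test.** Group effects on community composition are tested
by one-way PERMANOVA on the Bray-Curtis dissimilarity matrix:
pseudo-F from among/within sums of squared distances
(SS_total = N⁻¹Σ_{i<j} d²ᵢⱼ, SS_within = Σ_g n_g⁻¹Σ_{i<j∈g} d²ᵢⱼ), with
p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm) over seeded label permutations
(default 999). This is a deliberate stand-in for distance-based RDA
ordination with a permutation test: the inferential target (no
compositional difference between PPI groups on the same dissimilarity) is
identical and the permutation test is fully specifiable; ordination plots
are out of scope. Samples that are all identical give SS_within = 0 and a
flagged degenerate result. Alpha diversity is Shannon entropy in nats
(the index choice is a package default, not a data-derived fact).

## Biomarker cascade

1. **Screen.** Per-taxon two-sided Mann-Whitney U between PPI users and
   non-users on relative abundance at the screening depth; exact
   enumeration when both groups have ≤ 8 tie-free observations, otherwise
   the tie-corrected normal approximation. Benjamini-Hochberg adjustment
   across taxa; significance at q < 0.05 (the pipeline's global α).
2. **Rank.** Random forest (default 1,000 trees, √m features per split)
   on samples × taxa; importance is the Breiman mean decrease in accuracy:
   the drop in each tree's out-of-bag accuracy when one taxon's column is
   permuted, averaged over trees and permutation repeats (default 10),
   fully seeded.
3. **Select.** Data-driven candidates are taxa in the top
   ceil(0.05·m) of the importance ranking (minimum one taxon) that are
   also significant after adjustment. Literature-prior taxa are appended
   unconditionally and flagged as such; they are evaluated at their stated
   rank (family/genus/species) after taxonomy aggregation.
4. **Calibrate.** AUROC = U/(n₁n₀) (ties count half) with the
   Mann-Whitney p as its significance; candidates whose AUROC is not
   significant at α are not carried to validation. The decision threshold
   maximises J = sensitivity + specificity − 1 over all midpoints between
   consecutive distinct scores plus sentinels, in both decision
   directions. Ties in J are broken toward the direction agreeing with the
   AUROC (≥ 0.5 means high abundance predicts PPI use), then toward
   higher specificity, then toward the larger threshold — these biomarkers
   are specificity-leaning, so ties should not drift toward sensitivity.
   Predicted-positive is the ≥ side of the threshold. Thresholds are
   stored as relative abundance (with the count-equivalent at the
   screening depth alongside) so they transfer across cohorts sequenced at
   different depths.
5. **Gate.** The frozen threshold and direction are applied unchanged to
   the validation cohort; raw accuracy ≥ 70% (boundary inclusive) passes.
   Balanced accuracy is reported alongside but does not gate; raw accuracy
   is the gating metric. Validation-cohort subjects who switched PPI status
   between samplings are labelled by their status at the validation
   sampling.
6. **Classify.** With one gated biomarker: non-users → `no_ppi`; users
   predicted positive → `ppi_dysbiosis` (true positives); users predicted
   negative → `ppi_no_dysbiosis` (false negatives). Classification with an
   ungated model requires an explicit override and warns.

Whether the forest is trained on rarefied counts or relative abundance is
a free choice; relative abundance is the default (rank-based screening is
unaffected either way).

## Matching

The propensity score is a main-effects maximum-likelihood logistic
regression of PPI exposure on Child-Pugh and MELD (the two severity scores
the matching is designed to balance); separation or non-convergence falls back to an L2-penalized
fit with a flag. Matching is greedy nearest-neighbour on the score, with
replacement, cases processed in descending score order (the order is
irrelevant to the optimum under replacement but fixed for determinism);
control-score ties break by control position. Unmatched controls are
excluded. Each pair's coefficient of variation is sd/mean·100 with the
two-point sample sd (|a−b|/√2). No caliper by default (none is part of the
design); one is available in the matching call. Balance is summarised as
standardized mean differences (mean difference over the pooled pre-match
sd, so pre and post are on one scale); zero-variance covariates report
SMD 0 with a flag.

## Survival

Follow-up is administratively truncated at 36 months; events beyond the
horizon become censorings. Kaplan-Meier curves use the product-limit
estimator with the standard censored-after-events convention at tied
times. Cox models are fitted by lifelines with Efron tie handling;
forced entry means all covariates stay in. Inference is Wald on the log
scale (HR = e^β, CI = e^{β±1.96·se}). The headline model has two
indicators — PPI with dysbiosis, PPI without dysbiosis, reference no PPI
use — plus Child-Pugh and MELD; a two-indicator univariate model is fitted
alongside (a pairwise-model mode would answer the same question; the
two-indicator form is the default). Degenerate designs (e.g. every PPI
user dysbiotic) drop the constant column with a warning. Monotone partial
likelihood (few events, separated groups — the regime behind very wide
CIs) is surfaced via `converged=False` rather than silently reported.
Liver-unrelated endings are censorings; there is no competing-risks model.

## Group comparisons

Continuous variables: median with a distribution-free 95% CI from order
statistics (bounds x₍ₗ₎, x₍ᵤ₎ with l the largest integer such that
P(Binom(n,½) < l) ≤ 0.025, u = n+1−l; below n = 6 the full range is
reported with a flag). Omnibus: tie-corrected Kruskal-Wallis. Post hoc:
the three pairwise Mann-Whitney contrasts (a: dysbiosis vs no PPI, b: no
dysbiosis vs no PPI, c: dysbiosis vs no dysbiosis) with Bonferroni
multiplier 3, capped at 1 (reported as "> 0.999" at the cap). Categorical:
Pearson chi-square without continuity correction, warning on expected
counts < 5. Correlations: Spearman with average ranks; exact permutation p
by full enumeration for n ≤ 9, t approximation otherwise; marker-severity
correlations are computed within PPI strata by default.

## Synthetic cohorts

The generator produces the statistical structure the analysis assumes,
with known ground truth, so every stage is testable without external data.

* **Counts.** Per-subject Dirichlet-multinomial: a log-normal (σ = 2)
  population mean profile over m = 200 taxa, per-subject proportions
  Dirichlet(θ·profile) with concentration θ = 50 (overdispersion in the
  range estimated for human stool), depths log-uniform on 20,000–60,000.
  Three planted "oral" taxa (base relative abundance 0.5% each, with
  *S. salivarius* / *V. parvula* / *S. parasanguinis* lineages) are
  multiplied by `fold_change` (default 8) in exposed, susceptible
  subjects, then renormalized — the realized enrichment is therefore
  slightly below the nominal fold change.
* **Cohorts.** 50 PPI users and 40 non-users at discovery; 68 subjects
  redrawn as the validation cohort with 10% switching exposure between
  samplings (a switcher's enrichment follows the new exposure, modelling
  reversibility). `susceptible_fraction` controls how many PPI users are
  truly dysbiotic; 1.0 by default (every exposed subject carries the
  signal), 0.6 in the three-group scenarios (a 30/20 dysbiosis split among
  50 exposed subjects).
* **Severity.** MELD ~ Normal(11 + γ·exposed, 3), Child-Pugh derived from
  MELD plus noise, clipped to 5–11. The confounding coefficient γ defaults
  to 1.0 MELD point, chosen so that matching quality in the default
  scenario looks like a well-matched observational cohort (median
  propensity pair CV ≈ 0.4–0.7%, severity comparable after matching)
  while exposure-severity confounding remains clearly present.
* **Survival.** Exponential event times (Weibull shape available) with
  monthly baseline hazard λ₀ = 4·10⁻⁴ at the reference covariates and
  multiplicative effects: HR 8 for true dysbiosis, 1 for exposed
  non-dysbiotic, 1.6 per Child-Pugh point, 1.05 per MELD point; random
  censoring at 5·10⁻³/month (transplant/lost), administrative censoring at
  36 months. These defaults yield (~2%
  three-year liver mortality without PPI, ~18% with, ~10% overall).
* **Markers.** Log-normal calprotectin/zonulin/LPS (medians 20 ng/mg,
  70 ng/mg, 0.5 EU/ml; log-sd 1.3, 0.45, 1.2) with the dysbiotic location
  shifted by δ = 2 log-sd; δ = 0 gives exchangeable groups.

What it does **not** emulate: read-level 16S sequencing and taxonomy
assignment error; subject-level composition persistence between samplings
beyond shared exposure effects (validation draws are fresh Dirichlet
samples); drug co-exposures; non-proportional hazards; competing risks;
marker-severity correlation structure. Passing tests therefore show the
pipeline recovers planted signal under compositional noise and realistic
censoring — not that any particular real cohort's effect sizes are
recoverable.

## Problem sizes in the test suite

Oracle-equivalence checks run at full size (1,000 random instances each).
Simulation checks use sizes at which the tested claim is identified:

* End-to-end planted recovery and the all-null control run at the default
  cohort shape (50/40 discovery, 68 validation, 200 taxa), 50 seeds per arm, with
  the forest at 200 trees × 2 permutation repeats — ranking at fold
  change 8 is insensitive to forest size well below the library defaults.
* Covariate-balance checks for matching use 600 cases/480 controls: a
  50-pair matched mean has SMD sampling noise of sd ≈ 0.1, so a < 0.1
  balance claim is not decidable at the 50-pair size even under perfect
  matching.
* The survival-linkage pattern check uses 150/120 subjects with
  λ₀ = 10⁻³/month, and the null type-I calibration 200/160 with
  2·10⁻³/month (~15–20% events): Wald tests on a handful of events are
  structurally conservative, which would measure the event count, not the
  implementation.

## Known limitations

* `cox_fit` delegates estimation to lifelines; the monotone-likelihood
  diagnostic is a convergence flag plus a tiny-ridge refit, not a Firth
  correction.
* Only single-taxon threshold classifiers are modelled — no multi-taxon
  composites, mirroring the design this package implements.
* The BIOM reader covers the JSON (1.0) dialect only; HDF5 BIOM files
  should be exported to JSON or TSV first.
* PERMANOVA is one-way; no strata or covariate adjustment.
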