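# Methods

`gmci` implements a species-level case/control gut-metagenome analysis
whose centerpiece is a per-sample **gut microbiome cancer index**: a
GMHI-family dysbiosis score built from cohort-specific marker species.
This note records the models, the statistical procedures, the defaults and
the design choices, and what the synthetic cohorts do and do not show
about real data.

## Study design being modelled

Seven malignancy groups (colorectal, stomach, breast, lung cancer,
melanoma, lymphoid neoplasms, acute myeloid leukemia), each compared
against its own sex- and age-matched healthy-control (HC) subset.  Inputs
are species-level shotgun-metagenomic read counts (e.g. merged Bracken
species reports), per-sample metadata, and a fixed 16-metabolite fecal
panel (7 short-chain fatty acids, 9 amino acids, µg per g stool).
Matching is by design, not by covariate adjustment: no model in the
package conditions on sex or age.

## Marker-species selection

For one cohort:

1. **Universe filter.**  Species carrying more than 0.01% of all reads
   (across the whole dataset) form the detectable universe — at
   production depth this yields a universe of a few hundred species.
2. **Group filter.**  A species is testable if its mean read count
   strictly exceeds 50 in the case group *or* in the control group.
3. **Test.**  Two-sided Mann–Whitney U on per-sample *relative*
   abundances (depths differ between samples; counts are compositional).
   Exact enumeration p-value for tie-free inputs with n₁+n₂ ≤ 12,
   otherwise the normal approximation with midrank-tie and continuity
   corrections.  A perfectly balanced U (U = n₁n₂/2) reports p = 1.
4. **Multiplicity.**  Benjamini–Hochberg across the testable species of
   this one cohort (the family is the per-comparison species list, not a
   pool over the seven cohorts).
5. **Direction.**  Species with q < α (default 0.05) enter
   H (control-associated) when the control-group mean relative abundance
   exceeds the case-group mean, C (case-associated) in the opposite case;
   exactly equal means give no direction and the species is dropped with
   a log message.

A note on the test choice: for this table type a compositional linear
model is a common alternative; the rank test is used here because it is
assumption-light, exactly matches the downstream index's rank-based
evaluation, and has a tractable exact null for the oracle tests.

## The cancer index

Given marker sets (H, C) and a sample's relative-abundance profile:

    f_H = |{h ∈ H : a_h ≥ θ}| / |H|      (0 if H is empty)
    f_C = |{c ∈ C : a_c ≥ θ}| / |C|      (0 if C is empty)
    index = log₂((f_H + ε) / (f_C + ε))

* **θ (detection threshold)** — relative abundance 1e-5, ≈ 1 read at the
  default 100 000-read depth.  Detection by proportion rather than raw
  count makes the index invariant to sequencing depth.
* **ε (regularizer)** — 0.01; bounds the index to ±log₂(1.01/0.01) ≈ ±6.66
  and keeps it defined when either set is entirely undetected or empty.
* **log₂** — makes 0 the balance point and the score antisymmetric under
  swapping H and C.  A raw-ratio variant (`log_base=0`) and an
  abundance-weighted variant (mean relative abundance of detected markers
  instead of the detected fraction, `weighting="abundance"`) are exposed
  as parameters.

Higher values mean a healthier-looking profile.  Algebraic properties
(exact, covered by tests): H↔C antisymmetry; adding a detected H-marker
never lowers a sample's index and adding a detected C-marker never raises
it; depth invariance on proportion input.

### Evaluation: cross-validated by default

Deriving markers and scoring the same samples is circular — under a null
cohort the in-sample AUC sits visibly above 0.5 (a property test
demonstrates this at a permissive α where markers always exist).  The
default evaluation therefore uses stratified k-fold cross-validation
(k = 5): markers are re-derived on each training fold (including the
read-count filters, so no information from held-out samples leaks into
selection) and only held-out samples are scored.  Separation is
summarized by a two-sided Mann–Whitney p on the held-out indices and the
rank AUC of the control > case ordering.  The in-sample design remains
available as a labelled mode (`mode="in_sample"`) for comparison with
studies that evaluated markers on the samples that produced them.

A training fold that yields no markers (the norm under a true null at
α = 0.05) scores its held-out samples 0 — uninformative by construction —
which keeps the rank statistics defined and the null CV AUC unbiased
at 0.5.  `CancerIndexClassifier` follows the scikit-learn contract
(`decision_function` scores the positive = case class, i.e. the negated
index; the domain-facing `cancer_index(X)` returns the index proper), so
`cross_val_score(..., scoring="roc_auc")` and friends work directly.

## Diversity

* **α-diversity**: Shannon index in nats on relative abundances, plain
  estimator with no rarefaction or coverage extrapolation — the package
  deliberately implements the estimator itself, not
  extrapolation machinery; group comparison by two-sided Mann–Whitney,
  BH-adjusted across the cohorts when all are run together.
* **β-diversity**: counts + 0.5 pseudocount → centered log-ratio (CLR)
  transform → Euclidean geometry (Aitchison).  Ordination by plain PCA
  with a deterministic sign convention (largest-magnitude loading of each
  component made positive).  Group separation by a two-group PERMANOVA on
  the Aitchison distance matrix: pseudo-F with 999 seeded label
  permutations, p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm).  The
  pseudo-F agrees with scikit-bio's implementation to machine precision
  (cross-checked in a test).  The source study asserts β-diversity
  significance without naming its test; PERMANOVA here is this package's
  choice of a standard, seedable test, not a reproduction of an
  unspecified one.

## Metabolite comparisons

Two independent modes per cohort: raw concentrations (µg/g stool) and
proportions of the 16-metabolite panel total (rows summing to 100 before
testing).  The two modes answer different questions and are never coerced
to agree.  The reference group is the *whole* HC pool, not the cohort's
matched subset (metabolite availability, unlike sequencing, does not
support per-cohort matching).  Per metabolite: two-sided Mann–Whitney,
BH across the 16-metabolite family within cohort × mode, direction by
median difference, and a significance code on the adjusted p:
1 (q < 0.05), 2 (q < 0.01), 3 (q < 0.001), 4 (q < 0.0001).  Missing
values exclude a sample per-metabolite in concentration mode and entirely
in proportion mode (the denominator is undefined).

## Taxa–metabolite associations

Taxa with mean reads > 1000 (strict) and prevalence ≥ 10% are correlated
(Spearman, midranks) with each metabolite over the pooled case + HC
samples.  Taxa are grouped into correlation modules by Ward agglomeration
on the correlation distance (1 − Pearson r) between their
correlation-profile rows; metabolites likewise on columns.  Cuts default
to 5 taxa modules and 2 metabolite clusters.  A fixed-k cut was chosen
over dynamic tree cutting for determinism; k is a parameter.  Constant
taxa/metabolites (undefined correlation) are excluded with a log message.

## Synthetic cohorts

The generator exists so every stage is testable without sequencing data.
One cohort is drawn as follows (single integer seed; bit-identical
reruns):

* **Baseline profile**: one log-normal draw (σ = 2.0) over the species
  universe (default 260 species), normalized — heavy-tailed, so a handful
  of species dominate (top ten ≈ half the reads, matching the emulated
  community's concentration of mass).
* **Planted effects**: `n_depleted` control-associated and `n_enriched`
  case-associated species; the case profile divides/multiplies their
  proportions by `effect_fold` and renormalizes.  Planted species are
  drawn only from the detectable mid-tail (baseline proportion in
  [1e-3, 0.02]): below the band a marker could never pass the pipeline's
  own read-count filters at desk-scale depth; above it, a several-fold
  shift on a community-dominant species rescales the entire composition
  and scrambles the direction of every other species — not the marker
  structure of the studies this emulates, whose markers are mid-tail
  commensals and pathobionts rather than the dominant backbone taxa.
* **Counts**: per-sample composition ~ Dirichlet(500 × group profile)
  — the concentration parameter sets sample-to-sample overdispersion —
  then counts ~ Multinomial(depth), depth ~ Poisson(100 000).  The
  Dirichlet-multinomial respects the compositional sum constraint, so
  depleting many species implicitly enriches the rest — exactly the
  regime a ratio-type index exploits.  The 100k default depth is a
  desk-scale stand-in for production depths (~14M reads); depth is a
  config knob and every depth-sensitive statistic operates on
  proportions.
* **Metadata**: sexes at each group's enrolment-table ratio, ages uniform
  over the group's enrolment range, controls matched in distribution.
* **Metabolites**: log-normal around fixed per-metabolite baselines
  (plausible but arbitrary µg/g scales; only relative shifts matter),
  log-scale σ = 0.5 (~50% CV), with multiplicative case-side shifts
  (`formic_shift` plants the formic-acid elevation).

Presets: `null` (no effects anywhere, 20/20 — exchangeable groups, used
for FDR/type-I calibration), `paper_like` (45 depleted : 6 enriched at
260 species — the 179:24 asymmetry scaled proportionally to the universe
— 2× effects, 2× formic shift, 40/40), `strong_dysbiosis` (20:5 markers
at 4× effects, 40/40, for recovery and AUC-ceiling tests).

**What passing tests do and do not show.**  The synthetic cohorts have no
batch effects, no covariate-driven structure (age/sex shift nothing), no
longitudinal component, no read-level error, and planted effects that are
independent and uniform in size.  Tests on them validate the *procedures*
— error control, recovery power at stated effect sizes, invariances,
determinism — not the biological claims of any real dataset.

## Numerical and degenerate-input choices

* Pseudocount 0.5 reads for CLR (conventional half-count), exposed.
* PCA refuses k above the matrix rank; component signs fixed as above.
* All-zero count rows are rejected at table construction; all-zero
  metabolite rows are an error in proportion mode.
* BH and rank tests are delegated to statsmodels/scipy; the exact
  Mann–Whitney path is verified against full rank-split enumeration for
  every input shape with n₁+n₂ ≤ 10.
* Every simulation, fold split and permutation consumes an explicit seed;
  pipeline outputs embed the seed and a configuration hash, and a rerun
  with the same configuration and seed is byte-identical.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run entirely on synthetic
cohorts at the preset sizes above: 200 null cohorts for error-control
calibration in the suite (50 in the acceptance script), 5 strong-signal
cohorts for recovery, 50 cohorts for the formic-acid direction rate, and
one full seven-cohort study-like run at the enrolment-table group sizes.

## Known limitations

* The rank-test marker selection ignores compositional coupling between
  species; strongly coupled communities can shift apparent directions
  (the generator's mid-tail planting keeps this regime out of scope).
* The index treats markers as exchangeable within H and C; no weighting
  by effect size or abundance beyond the optional abundance variant.
* PERMANOVA assumes exchangeability under the null; with strongly
  unbalanced dispersions it tests dispersion as much as location.
* The whole-HC metabolite reference means metabolite comparisons are not
  age/sex matched, unlike the taxonomic ones.
* No batch-effect handling anywhere: inputs are assumed to come from one
  processing pipeline.
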