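# Methods

## Phenotype indices

The neocortex ratio is `Nr = V_neo / (V_brain − V_neo)` with both volumes in
cm³ and `V_brain` the TOTAL brain volume. The packaged 28-species table stores
total brain volume, neocortex volume, `Nr`, `Ei` and MLSP as published;
`validate_nr_consistency` recomputes `Nr` from the volumes and flags rows
whose stored ratio differs by more than a tolerance (default 0.01, i.e. the
printed two-decimal precision). Exactly one row — the mouse, computed 0.333
vs stored 0.32 — fails this check; the stored value is kept as data and the
disagreement is only reported, never silently corrected.

The encephalization index is `Ei = log(brain) − b·log(body)`, natural log,
masses in grams, `b = 0.64` (an allometric slope estimated elsewhere from a
large brain/body regression and treated here as a given constant). For the
real table `Ei` is consumed as published — the body masses behind it are not
part of the table and the regression's intercept convention is not
recoverable — so `compute_ei` exists for the synthetic pathway and for users
with their own mass data.

## Family filtering

A family enters the analysis if it has ≥ `min_species` (default 6 of 28)
species with ≥ 1 member, and non-zero variance of size across **all** species
columns, zeros included. "Present" means size ≥ 1. Filtering is idempotent.

## Per-family association and the distribution-shift tests

Family sizes are correlated with a species-aligned phenotype by plain Pearson
correlation. Species without members contribute size 0 by default
(`absent_policy="zero"`; a count of zero is a real observation of the
family's size). The alternative `"drop"` policy restricts each family to the
species where it is present; families left with < 3 species or zero variance
are reported NaN and excluded from the joint BH correction and the global
tests. Two-sided `p` comes from `t = r·sqrt((n−2)/(1−r²))`.

The global null for the MEAN of the per-family correlations is built by
permutation. The default `joint` scheme applies one species permutation per
replicate to every family — equivalently it permutes the phenotype — which
preserves the inter-family covariance that the mean inherits; `per_family`
(independent shuffles) is available for sensitivity analysis but its null is
too narrow when families covary. The observed mean is summarized as
`z = (mean_r − mean(null)) / sd(null)`, reported with the **upper one-tailed**
normal probability (this sidedness reproduces the published Z→p pairs
0.013/2.2258 and 0.044/1.7094) and with the add-one empirical rank
probability `(1 + #{null ≥ obs}) / (1 + R)`.

The sign test is a Pearson χ² of (positive, negative) correlation counts
against equal expectation, df = 1; exact zeros and NaNs are excluded from
both counts (the choice is documented rather than inferred — it changes
nothing at realistic sizes, where exact zeros have measure zero).

Seeding: one integer seed expands through `numpy.random.SeedSequence.spawn`
into one substream per permutation replicate, so runs are reproducible and
any replicate can be replayed in isolation.

### Calibration caveat

The permutation null assumes species are exchangeable. When family sizes are
phylogenetically autocorrelated **and** the phenotype evolves on the same
tree, close species resemble each other in both variables, the observed mean
r is overdispersed relative to the permutation null, and the Z-test rejects
somewhat above its nominal rate. This is the classic phylogenetic
pseudoreplication problem and is precisely why the pipeline's inferential
stage is the PIC-corrected association, not the raw shift test. The
calibration test therefore draws its no-signal data without phylogenetic
noise (`phylo_noise_sd = 0`), which is the exchangeable null the permutation
scheme actually targets.

## Confound and phylogeny correction

Order is fixed and matters: residualize across species first, then contrasts.
Both the target (`Nr ~ Ei + MLSP`) and every family (`GFS ~ Ei + MLSP`) are
residualized by OLS with intercept; the residual vectors are transformed into
Felsenstein independent contrasts on the time tree; each family's contrasts
are correlated with the target's through the origin (no intercept — contrasts
have zero expectation by construction) with `df = n_contrasts − 1`, the
standard through-origin convention.

The pruning recursion at a node joining children `(x1, v1)` and `(x2, v2)`:
contrast `(x1−x2)/√(v1+v2)`, ancestral value the `1/v`-weighted mean, parent
branch incremented by `v1·v2/(v1+v2)`. Because contrasts are linear in the
tip values, the transform is materialized once per tree as an
`(n−1) × n` matrix and applied to thousands of families by matrix product;
the same code path (pruning over vector payloads) yields both the matrix and
single-trait contrasts, and tests check it against an independent naive
recursion. Multifurcations are resolved arbitrarily with zero-length
branches, and zero lengths are replaced by `1e-10 ×` tree height — small
enough that a star tree reproduces the ordinary residual correlation to
1e-9, large enough to keep denominators finite. Tip matching is exact string
match after replacing spaces with underscores; any mismatch aborts rather
than silently subsetting.

## Enrichment

Terms are counted over the BACKGROUND (all filtered families): terms with
≥ `min_families` (default 200) background families are retained, smaller
terms are merged into a `SMALL_BP` bucket, and families without any
annotation form `NOT_ANNOTATED`; buckets are tested like ordinary terms (the
unannotated bucket is biologically meaningful — poorly characterized families
can be the most enriched class) and each bucket membership counts as one
annotation. The test statistic is the annotation-density-adjusted count:
`|sample ∩ term| / mean annotations per family in the sample`, which stops
samples rich in heavily annotated families from looking enriched everywhere.
The null draws `n_samples` (default 1000) family sets of the test set's size
**without replacement** from the background (a family set is a set);
`p = (1 + #{null ≥ obs}) / (1 + n_samples)` with a non-strict ≥ and the
add-one correction, so 1000 resamples can never claim `p < 1/1001`. BH-FDR
is applied across retained terms plus buckets jointly.

## Expression contrast

Samples are normalized to their total expression (columns sum to 1), split
into windows at `age ≤ 13` years (the age at which human cortical thickness
peaks; a sample at exactly 13 falls "before" since peak thickness has just
been reached). Prenatal ages are stored as negative years,
`(pcw − 40)/52`. Per-gene window means are a simple mean over the window's
samples; a `cell_means` flag instead averages each (age, region) cell first,
weighting developmental stages equally. The paired Wilcoxon signed-rank test
runs on the per-gene (before − after) differences, zeros dropped, exact null
up to 25 non-zero pairs and the continuity-corrected normal approximation
above; the default alternative is one-tailed "greater" (elevated before
maturation), with two-sided also emitted.

## Synthetic data

The generators define the study conditions for all recovery and calibration
tests; every generator is a pure function of its seed.

- **Tree**: Yule (pure birth), `n_tips = 28`, rescaled to unit height. The
  birth–death sampler stops at the n-th speciation, which would leave a
  zero-length cherry; every tip branch is extended by the `Exp(n·λ)` waiting
  time to the next (uncounted) event, keeping the tree ultrametric with
  strictly positive branches. (Zero terminal branches are not a cosmetic
  problem: a PIC divides the tip difference by √branch length, so a
  zero-length cherry turns pure sampling noise into an unbounded contrast.)
- **Traits**: correlated Brownian motion of (log Nr, Ei, log MLSP), default
  rate matrix `[[.25,.15,.10],[.15,.25,.10],[.10,.10,.25]]` — the positive
  Nr–Ei coupling (correlation 0.6) reproduces the real identifiability
  problem in which an Nr-driven family also correlates with Ei until the
  shared variance is residualized out. Roots (0, −2, 3) put the traits in the
  observed ranges (Nr ≈ 1, Ei ≈ −2, MLSP ≈ 20 y). Volumes are back-computed
  so `compute_nr` inverts exactly.
- **Family sizes**: `Poisson(exp(a_j + β_j·z(Nr_i) + ε_ij))`, with baseline
  `a_j ~ N(1, 0.5)` (mean size ≈ 3, the order of real family sizes), planted
  effect `β = 1.5` on 10% of 1000 families, and Brownian species noise
  (sd 0.3) giving unplanted families realistic phylogenetic autocorrelation.
  An overdispersion option gamma-mixes the rate. At these defaults the
  corrected association recovers ≥ 80% of planted families while swapping
  target and covariate (Ei as target, Nr as covariate) recovers essentially
  none — the directional asymmetry the method is meant to resolve.
- **Annotations**: 10 terms drawing 22–38% of families each (above the
  200-family retention threshold at the default 1000 families), 3 of them
  oversampling planted families 10:1, 20% of families unannotated.
- **Expression**: one sample per (age, region) over 13 ages × 11 cortical
  regions = 143 samples, log-normal gene baselines with log-normal
  measurement noise, and a ×1.5 early-window multiplier on planted-family
  genes.

What the generators do **not** emulate: real gene-family-size marginals
beyond order of magnitude, gene gain/loss as a birth–death process along the
tree (the planted effect acts through the tip phenotype directly),
ontology-graph structure among terms, region-specific expression profiles, or
donor-level variation. Passing recovery tests therefore demonstrate that the
statistics detect the planted generative signal at realistic sizes — not that
the biological effect exists or that real data meet the models' assumptions.

## Problem sizes

Simulation-based tests run at deliberately chosen sizes: the null
calibrations use 200 replicate datasets of 100 families with 500 permutation
replicates / 500 enrichment resamples; the recovery test uses the full
default study (1000 families, 10 000-permutation-scale statistics are
exercised in the pipeline tests at 500–2000 replicates). These sizes give
binomial error bars tight enough for 3-SD acceptance bands while keeping the
whole suite in a few seconds.

## Known limitations

- The Z shift test over-rejects under strong phylogenetic autocorrelation
  (see calibration caveat); interpret it as descriptive, and rely on the
  PIC-corrected per-family inference.
- PIC assumes Brownian evolution of the residualized quantities; count data
  with observation noise violate this on very short branches. No λ/OU
  transformation is offered — the pipeline intentionally mirrors the plain
  residual-PIC design.
- The enrichment null conditions only on test-set size, not on any structure
  (e.g. family size) of the test set.
- The BH procedure assumes the usual positive-dependence conditions; per-family
  tests across a shared phenotype are correlated, so FDR control is
  approximate.
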