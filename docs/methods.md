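# Methods

## Network model

Each cohort is an independent gene-by-sample matrix of normalized
abundances. Coexpression is measured by Pearson correlation on
pairwise-complete observations (every gene pair must share at least 3
samples; pairs whose shared observations are constant get correlation 0,
since no linear signal is estimable). The correlation is soft-thresholded
into a weighted adjacency: `a_ij = |r_ij|^β` for the default unsigned
network, `a_ij = ((1 + r_ij)/2)^β` for the signed variant. Soft
thresholding preserves the continuous nature of coexpression while
suppressing weak, noise-dominated correlations.

β is selected by the scale-free topology criterion: for each candidate
power in the grid 1–20, whole-network connectivities `k_i = Σ_{j≠i} a_ij`
are histogrammed into 10 equal-width bins and `log10 p(k)` is regressed
on `log10 k̄`; the signed fit index is `−sign(slope)·R²`. Empty bins stay
in the regression with frequency 0 (represented by the bin midpoint and a
`1e-9` offset inside the logarithm), which penalizes gappy connectivity
spectra; without this, low powers can pass the criterion spuriously on
module-structured data, and the resulting weak thresholding lets noise
genes agglomerate with real modules under the static tree cut. A power
whose connectivity spread is degenerate, or that leaves fewer than 3
non-empty bins, is recorded as undefined and skipped. The chosen β is the
smallest power with signed R² ≥ 0.8; if none passes, β = 6 — the
community's standard unsigned default — is used and flagged in the run
log. Both the threshold and the fallback are configurable.

Gene similarity is the unsigned topological overlap
`ω_ij = (ℓ_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij)` with
`ℓ_ij = Σ_{u≠i,j} a_iu a_uj`: two genes are similar when they are
directly connected *and* share neighbors, which is considerably more
robust to single spurious correlations than the raw adjacency. Modules
are obtained by average-linkage hierarchical clustering of `1 − ω`.

## Tree cut

Instead of the dynamic hybrid tree cut, the dendrogram is cut statically
at a fixed fraction (default 0.995) of its maximum merge height, and
clusters of at least `min_module_size` (default 10) genes become modules;
everything else is unassigned (label 0). The static cut is fully
specifiable and deterministic: since unstructured genes join the tree
only at heights very close to the maximum, cutting just below it isolates
coherent modules while leaving noise genes as unassigned singletons. The
small default minimum module size is deliberate — published liver
cholesterol modules go down to roughly a dozen genes. The cut fraction,
minimum size, and eigengene merge height (default 0.25, i.e. modules
whose eigengenes correlate above 0.75 are merged) are all exposed.

Module numbering and merge order resolve ties by module size and then by
the alphabetically smallest member symbol, so a partition is a pure
function of its inputs. Eigengenes are the first principal component of
the module's standardized (per-gene zero-mean/unit-variance,
mean-imputed) expression, unit-norm, sign-oriented so they correlate
non-negatively with the module's mean profile.

## Enrichment and calling

Modules are scored against the target gene set by the one-sided
hypergeometric upper tail `P(X ≥ k)` — the canonical gene-set
over-representation statistic (equivalent to one-sided Fisher exact).
The universe is the set of genes measured in that cohort after
preprocessing, not a global annotation universe: platforms differ in gene
content, and enrichment must be judged against what the cohort could have
shown. Probabilities are accumulated in log space (log-gamma binomial
terms with log-sum-exp), which keeps extreme enrichments (p ~ 1e-80)
finite and accurate; the implementation agrees with exact integer
enumeration to better than 1e-12 relative error over all configurations
with universes up to 60 genes (see the test suite). The per-cohort call
is the module with the smallest p below α = 0.05 (ties: larger overlap,
then smaller label); no multiple-testing correction is applied for
calling, matching how such per-cohort module enrichments are
conventionally reported, but the per-cohort enrichment report carries a
Bonferroni-adjusted column (across that cohort's modules) for
information alongside n, k, K, N, p and the called flag.

## Replication ranking

A gene's replication count is the number of cohorts whose called target
module contains it — membership in *any* module does not count. The
candidate threshold defaults to 11 ("more than ten times"). Because a
gene can be absent from a platform entirely, the table reports
`n_datasets_measured` alongside the count, letting users distinguish
"measured but outside the module" from "never measured". External overlap
(e.g. against a human liver cholesterol module) is reported as
`|external ∩ pool| / |external|`, printed as a whole percent, matching
the convention for cross-cohort module comparisons.

## Synthetic collections

The generator plants one latent factor per module and per cohort: module
gene `g` in cohort `d` has profile `loading · f_m + ε`,
`ε ~ N(0, noise_sd²)`, background genes are `N(0,1)` noise. The expected
within-module correlation is therefore `loading²/(loading² + noise_sd²)`
— about 0.81 at the default loading 0.9 and noise 0.44, with 0.8-loading
background modules at about 0.77; strong but realistic for a tightly
co-regulated biosynthetic program. Platform heterogeneity is emulated by
keeping each gene in each cohort with probability 0.9. Known target genes
are always measured, and a novel gene that joins the target module in a
cohort is measured there as well — inclusion implies measurement — so a
novel gene's expected replication count is its inclusion probability
times the number of cohorts, and replication statistics reflect module
membership rather than platform luck. All randomness flows from one seeded
generator; identical specs yield byte-identical collections.

The reference benchmark is 8 cohorts × 120 samples with 2,000 global
genes: five 80-gene background modules, one 60-gene target module (45
known-role genes named after the actual cholesterol/fatty-acid program,
15 novel genes: 5 at inclusion probability 1.0 and 10 at 0.5), seed
20240228. These sizes sit inside the ranges of real mouse liver cohorts
(25–300 animals, thousands of measured genes) while keeping a full
multi-cohort run at about half a minute on one CPU; the test suite runs
the benchmark at this scale, and a 12-cohort variant exercises the
published ">10 replications" threshold.

What the generator does *not* emulate: raw array/sequencing counts and
their mean–variance structure, batch and covariate effects (sex, diet),
correlated background modules, or between-module overlap. Passing the
recovery benchmark therefore demonstrates that the pipeline's machinery
(thresholding, TOM clustering, enrichment calling, replication ranking)
recovers a planted co-regulation structure under realistic noise — not
that any particular real compendium would yield the same gene list.

## Numerical and degenerate-input choices

- Correlations are clipped to [−1, 1] and symmetrized; adjacency and TOM
  are clipped to [0, 1] with exact unit diagonals.
- A matrix of exactly duplicated profiles produces correlation exactly 1,
  TOM dissimilarity exactly 0, and a single module; the scale-free fit is
  undefined there (constant connectivity) and falls back to β = 6.
- Duplicate gene symbols on read collapse to the highest-variance row
  (deterministic; ties keep the first file row). Missing cells are the
  empty string or `NA`.
- Preprocessing drops genes observed in fewer than half the samples or
  with zero variance, and is idempotent; an optional `max_genes` keeps
  the highest-MAD genes.
- Expression files written by the package use a float format that
  round-trips IEEE doubles exactly; generated collections use 6
  significant digits (ample for correlation structure) to keep files
  compact.

## Known limitations

- The static tree cut is simpler than the dynamic hybrid cut and can
  split very unevenly sized modules differently than the dynamic
  algorithm would; it is the documented trade-off for exact
  reproducibility.
- Very high selected powers (the criterion occasionally passes only at
  β ≈ 15–20 on strongly modular data) slightly shrink module boundaries;
  members are still detected but weakly attached genes may drop to
  label 0.
- Pairwise-complete correlation is not positive semi-definite in general;
  downstream steps do not require PSD-ness.
- No block-wise construction: cohorts beyond ~30k genes would need more
  memory than a desk machine typically has.
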