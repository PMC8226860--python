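# Methods

## Study design assumed

The package targets a three-stand, replicated-plot soil survey: a young
plantation, an older plantation and a primeval forest, each with three
plots, each plot yielding one shotgun-metagenome profile per microbial
group (bacteria, fungi, archaea) at several taxonomic ranks and one KEGG
pathway level-3 functional profile. The statistics themselves are generic:
any number of groups ≥ 2 with ≥ 2 samples each is accepted.

All tables are samples-as-rows TSV; proportions are stored as fractions and
converted to percent only in reports. Validation is strict and total:
negative or non-finite abundances, duplicate labels, singleton stands and
non-numeric environmental values raise typed errors rather than being
coerced.

## Diversity

Shannon H = −Σ pᵢ ln pᵢ in natural-log units, computed per sample after
internal conversion to proportions, with 0·ln 0 = 0. No rarefaction or
coverage correction is applied: gene-catalog relative profiles from deep
shotgun data are treated as depth-stable, and the downstream distances are
computed on proportions anyway. If profiles with strongly unequal depths
are supplied, the user should subsample beforehand. Per-stand summaries are
mean ± SE (sd/√n, ddof = 1). `percent_decrease` is 100·(ref − x)/ref
rounded to the nearest integer percent, matching how such contrasts are
normally quoted.

## Distances and ordination

Bray–Curtis is computed on relative abundances — this makes it invariant to
per-sample depth — and Euclidean distance requires an explicitly relative
table. Single-variable environmental distance is |vᵢ − vⱼ| on raw values by
default; a `standardize` flag z-scores first (the default is documented
rather than hidden because Mantel r is scale-invariant for a single
variable, so the flag matters only when variables are combined upstream).

PCoA uses Gower double-centering B = −½ J D² J, a symmetric
eigendecomposition, and coordinates uᵢ√λᵢ for eigenvalues above a relative
tolerance of 1e−10·max(1, |λ|max). Negative eigenvalues (from non-Euclidean
dissimilarities such as Bray–Curtis) are reported in the spectrum but get
no axis and no Lingoes/Cailliez correction — transparency over adjustment.
`proportion_explained` is normalised over the positive eigenvalues only.
Eigenvector sign is arbitrary, so each axis is oriented to make its
largest-magnitude loading positive, which makes reports reproducible.

## Permutation tests

**ANOSIM.** Distances are ranked once with average ranks for ties;
R = (r̄_between − r̄_within)/(M/2) with M = n(n−1)/2. The null permutes
group labels with the distance matrix fixed. When the number of *distinct*
label arrangements n!/Πn_g! is ≤ 20 000 the null is enumerated exactly and
p = #{R* ≥ R}/N (the identity arrangement is in the enumeration, so p > 0);
otherwise B Monte-Carlo draws give p = (hits + 1)/(B + 1). Comparisons use
a 1e−12 slack so ties in R count as ≥. R is rank-based, hence invariant
under strictly monotone transforms of the distances. A constant matrix
yields R = 0 with a warning.

**Mantel.** r is the Pearson correlation of the two condensed upper
triangles (Spearman by flag; ranking commutes with sample relabelling, so
it reduces to Pearson on a rank-transformed matrix). The one-sided
"greater" null permutes the sample order of the first matrix: all n!
orderings when n ≤ 7, Monte-Carlo otherwise. One-sided "greater" is the
convention of the common ecology implementations; with n = 9 samples the
full 362 880-permutation space is enumerable but slow, so the default stays
Monte-Carlo with an `exact` override. No multiple-testing correction is
applied across environmental variables — deliberate, mirroring common
practice in this literature, and a known caveat when 14 variables are
screened.

**ANOVA + Tukey.** One-way F (scipy), Tukey–Kramer pairwise p from the
studentized-range distribution, and a compact letter display built by
insert-and-absorb over the significance graph, letter columns ordered by
the highest group mean. The letter invariant — two groups share a letter
iff their pairwise p > α — is property-tested. Zero within-group variance
with unequal means is reported as p at machine epsilon with a warning
rather than an error. Shapiro–Wilk and Levene checks are advisory output
only and never gate the test.

## Importance of chance

With reference-stand internal variation R₀ (mean of its k(k−1)/2 pairwise
distances), deterministic change D = (mean of all reference×focal sample
pair distances) − R₀ and stochastic change S = (mean within-focal pairwise
distance) − R₀; importance of chance = |S|/(|D|+|S|), and the regime is
deterministic below 0.5, stochastic above. Choices made where the
definition leaves room:

* D is a *difference* from R₀, symmetric with S's definition; this makes
  D = 0 when the focal stand sits at reference-like distance, which the
  importance semantics require.
* "Variation between" is the mean over cross-stand sample pairs, consistent
  with "variation within" being a mean pairwise distance. A centroid-based
  cross term is available as `cross_method="centroid"` for sensitivity
  analysis.
* Importance exactly 0.5 is classified stochastic (the deterministic regime
  is defined strictly below 0.5); measure-zero in practice.
* |D|+|S| = 0 (all three means equal) gets importance 1 with a warning,
  mirroring the reference convention.
* The reference stand itself: importance 1, regime "reference".
* Study-level runs use Euclidean distance on class-level taxonomic and
  KEGG level-3 functional relative abundances, renormalised per table after
  any rank collapse.

Importance is exactly invariant to rescaling every distance by c > 0
(D and S scale by c), which is property-tested and makes the
fraction-vs-percent representation of proportions immaterial.

## Dominant features

A taxon is *dominant* when its relative abundance exceeds 1% (strict) in
every sample of its group's table; the remainder is pooled as "Others".
Dominance is evaluated per microbial group independently, each table
renormalised to 1. Reported abundances are means of per-sample proportions,
not proportions of pooled counts — with balanced designs the two differ
only slightly, but the per-sample mean weights plots equally.

## Synthetic generator

`SimConfig` defaults encode the emulated study: 3 stands × 3 plots;
feature counts 40 phylum / 120 class / 300 order / 2000 species-like taxa
and 300 KEGG level-3 categories; multinomial depth 50 000 per sample;
within-stand Dirichlet concentration 200; between-stand effects fungi 1.0,
bacteria 0.4, archaea 0.15 — chosen so the downstream ANOSIM pattern
(fungi strongly structured, bacteria intermediate, archaea weak) emerges,
with magnitudes a soil-metagenome practitioner would call realistic.
Mechanism: an ancestor composition per (group, feature kind) is a softmax
of N(0, 2) logits (a log-normal-like rank-abundance curve); each stand
shifts the ancestor logits by effect·N(0, 1) per feature; each plot is a
Dirichlet draw around the stand composition, multinomially sampled at
depth. Any displacement mechanism monotone in the effect would do; this one
is simple and property-tested for monotonicity of mean between-stand
Bray–Curtis distance.

Random streams are derived per (group, feature kind, stand) from the master
seed by SHA-256 hashing into a `SeedSequence` spawn key, so generating an
additional table never perturbs existing draws, and identical config + seed
reproduces tables bit-for-bit.

Environment tables: plot values are Normal(mean, SE·√n) per stand and
variable — the configured SE is the standard error of a stand mean over n
plots — floored at 0 for the physical variables, with the C/N column
recomputed per plot as SOC/TN. Defaults are per-stand means/SEs on the
scale of a high-elevation conifer soil survey (e.g. available potassium
398/390/160 mg kg⁻¹ across the three stands).

What the generator does **not** emulate: phylogenetic or co-occurrence
structure among taxa, correlated environment–community coupling (Mantel
power studies therefore need effects injected by the user), subsample
pooling within plots, and sequencing/annotation error. Passing tests show
the statistics are correct and well-calibrated on study-shaped
compositional data, not that any particular field result is reproduced.

## Problem sizes and numerics

The packaged simulation studies use 500 replicates at B = 199 for null
calibration of ANOSIM and Mantel (nominal 5% level, accepted band
3–7%) and 100 synthetic studies for parameter recovery; the acceptance
script runs the calibration at 300 replicates, a size at which the
binomial standard error (~1.2%) still resolves the band comfortably.
Calibration replicates use 400-feature species tables — the permutation
null depends on exchangeability, not table width — while recovery runs use
the full generator defaults. Permutation p-values never report 0
(+1/(B+1) Monte-Carlo convention; identity included under enumeration).
Comparisons of permuted statistics to the observed one use a 1e−12
absolute slack to keep exact ties on the ≥ side across platforms.

## Limitations

* No PERMANOVA, NMDS, db-RDA, partial Mantel, or null-model assembly
  inference (βNTI/RC_bray); the chance partition is a descriptive
  two-component split, not a process model, and carries no confidence
  interval.
* No multiple-testing correction across environmental variables or KEGG
  categories (the per-category ANOVA table reports raw p).
* Shannon values are depth-sensitive if inputs are raw counts at very
  unequal depths; no rarefaction is provided.
* The compact letter display can be non-unique when the significance graph
  is intransitive; the insert-and-absorb order used here is deterministic.
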