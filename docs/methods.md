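# Methods

## Coordinates and interval conventions

All intervals are 0-based, half-open (`[start, end)`), the BED convention;
GFF3 input is converted on read (1-based inclusive → half-open). Strand is
carried on records but no metric conditions on it. A gene's span is the
full annotated gene body; exon structure is not modeled. Distances between
gene pairs are gap distances between nearest ends (overlapping spans and
different chromosomes are reported as sentinels); abutting genes have gap
0.

## TE neighborhood metrics

For each gene the region is the gene body extended by `flank` bp (default
2000, chosen to take in the proximal promoter) on both sides, clipped at
position 0 and — when a chromosome-sizes table is available — at the
chromosome end; the clipped length is the denominator of both metrics.
Density counts a TE insertion whenever its interval intersects the region
at all (no prorating of partially overlapping insertions): intersection is
the only parameter-free reading of "insertions in a region". Coverage uses
union semantics, so nested or overlapping insertions cannot push it above
1. Both metrics are monotone under adding insertions.

## Category model

Genes at exactly (0, 0) are TE-free by rule and never enter the
clustering. The remaining genes are clustered on their raw
(density, coverage) points by PAM k-medoids with k = 4: greedy BUILD
initialization, then SWAP passes accepting the single best
medoid/non-medoid exchange until no exchange lowers the summed Euclidean
distance to the nearest medoid. No standardization is applied by default
(a `standardize` switch z-scores both axes); the two axes have very
different scales (density ~10⁻³, coverage ~10⁻¹), so the unscaled fit is
dominated by coverage — this mirrors the default behavior of the standard
PAM implementation the analysis builds on. Determinism: BUILD and SWAP
break ties by lowest point index, and assignment ties between equidistant
medoids go to the lower (less TE-dense) label. Clusters are relabeled by
medoid density ascending: TE-very-poor, TE-poor, TE-rich, TE-very-rich.
On small separable instances the SWAP optimum coincides with the
exhaustive-search optimum over all medoid subsets; the test suite asserts
this on n ≤ 10 fixtures. PAM is O(n²) per pass; at ~19k genes a fit takes
minutes, at the few-thousand-gene scale used in the tests, seconds.

## Epigenetic summaries

Histone enrichment per gene and mark is Σ(fold × covered bases)/gene
length: a mean over the *whole* gene body with uncovered positions at fold
0, so genes in signal deserts score near zero rather than being dropped.
Tracks are assumed non-overlapping within one mark (bedGraph semantics).

Gene methylation is the overlap-length-weighted mean ratio of the
hypo-/hyper-methylated region calls intersecting the gene; region calls
are taken as disjoint (overlapping calls would be weighted by their
summed overlap). Thresholds: mean < 0.25 → hypo, > 0.75 → hyper, else
standard. Genes intersected by no region get an undefined mean, status
standard, and are excluded from correlation analyses rather than imputed.
Length-weighting (as opposed to counting each region once) is a design
choice: it makes the gene call invariant to splitting a region into
abutting pieces with the same ratio.

## Expression

FPKM → TPM conversion is column-wise within each cell type. The expressed
flag is FPKM ≥ 0.5, boundary inclusive. d_m is computed on TPM; since d_m
normalizes each gene's 4-vector, it equals the total-variation distance
between profiles and is invariant to positive rescaling of either gene.
Families with both members silent in all four cell types are excluded
upstream; when exactly one member is silent, its normalized profile is
taken as the zero vector, which forces d_m = 0.5 — the case is flagged
per family in the output. Divergence classes are left-closed bins
[0, 0.25), [0.25, 0.5), [0.5, 0.75), [0.75, 1].

## Family statistics

Age classes: young dS < 1, middle-age 1 ≤ dS < 2, old dS ≥ 2 (the
boundary dS = 2 is assigned to old; the point is measure-zero in
practice). ω = dN/dS is undefined (flagged) at dS = 0.

The pair-context null derives cell probabilities from the duplicated
genes' own marginal category counts (qᵢᵢ = pᵢ², qᵢⱼ = 2pᵢpⱼ); a parameter
switches to genome-wide marginals. The Monte-Carlo p-value draws B
multinomial(n, q) tables and uses the add-one convention
(1 + exceedances)/(B + 1), which is a valid (slightly conservative)
p-value and bounds it below by 1/(B + 1). The test suite verifies type-I
calibration (rejection rate 0.05 ± 0.02 over 500 null simulations at
n = 1420, B = 2000) and power ≥ 90% against a diagonal-excess alternative
(same-category mass 0.32 versus the ≈ 0.25 independence baseline).

Within-family Spearman correlations randomize which member plays "gene 1"
per family under a seed: rank correlation over pairs is
orientation-sensitive in principle, and the members carry no intrinsic
order. p-values use the standard large-sample approximation; fewer than
three complete pairs (or a constant member vector) is flagged
not-computable. BH q-values are computed within four batteries — histone
tests pooled over ages, methylation tests pooled over ages, and the two
age-stratified counterparts — since a single global battery would mix
heterogeneous hypothesis families; the battery definition is echoed in
the output metadata. Distribution comparisons use the two-sample
Kolmogorov–Smirnov test and the Kruskal–Wallis test (H reported as a
chi-squared with k − 1 degrees of freedom).

## Synthetic data generator

The generator emulates the *structure* of the real inputs at study scale
by default: 22 chromosomes, ~19k genes (log-normal lengths, median 20 kb,
packed without overlap and with flanked regions separated), 1420 two-gene
families, age mixture 99/189/1132 (young/middle/old) with dS drawn per
class (young: Beta(0.55, 1); middle: uniform [1, 2); old: 2 + Γ(2, 0.82),
overall mean dS ≈ 3.1), ω log-normal around a median of 0.129.

Each gene carries a latent TE-neighborhood component: TE-free plus four
classes whose (density, coverage) profiles default to the values observed
for the human gene set ((0.0003, 0.086) … (0.0025, 0.419)) and whose
mixture weights default to the observed category proportions. TE
insertions are laid down inside the flanked region to realize the
component's profile (Poisson count at the component density, forced ≥ 1;
piece lengths Dirichlet-split to hit the coverage target; placement
non-overlapping), plus Poisson background insertions strictly in
intergenic space, so TE-free genes stay TE-free. A `uniform` mode instead
scatters insertions homogeneously at `te_rate` along each chromosome; in
that mode per-gene density concentrates on `te_rate` up to an edge
inflation of roughly (mean TE length)/(region length), which the
rate-recovery test keeps small by using short insertions.

Family members share their component with probability
p_copy = (p_target − s)/(1 − s), where s = Σπ_c² is the collision
probability of two independent component draws: copied pairs land in the
same realized category almost surely (the components are well separated),
independent pairs collide with probability ≈ s, so the realized
same-category fraction targets `p_same_category` (default 0.319). The
test suite checks recovery within ±0.03 at 2000 families.

Within-family epigenetic dependence uses a Gaussian copula per mark and
cell type: the latent correlation is r = 2·sin(π·ρ_s/6) so that the
*Spearman* correlation of any monotone transform equals the configured
ρ_s (default 0.4). Enrichment marginals are Γ(2, 1), written as three
abutting bedGraph pieces per gene whose length-weighted mean equals the
target (piece-level jitter adds a small attenuation, ≲ 0.01 on ρ).
Methylation marginals are Beta(2.5, 1.5); intermediate gene-level targets
are realized as one hypo (0.08) plus one hyper (0.92) region with lengths
solving the weighted mean, since only hypo/hyper region calls exist in
the input format; 10% of genes get no region (undefined mean).

Expression: each family draws a shared Dirichlet(1.2) mean profile over
the four cell types; members draw their profile from a Dirichlet
concentrated on that mean with concentration κ decreasing by age class
(60/15/5), so d_m increases stochastically with dS. Family silence states
(both silent 18.8%, one silent 13.7%) match the observed rates; silent
genes are all-zero FPKM.

What the generator does *not* emulate: real TE family composition and
length spectra, sequence context, chromosomal clustering of gene
families, mark-specific enrichment distributions, or any causal coupling
between TE content and epigenetic state — the copula ties family members
to each other, not to their TE environment. Passing parameter-recovery
tests therefore shows the estimators and tests are correct and
calibrated, not that the biological effect sizes are realistic.

## Problem sizes used in tests and scripts

The default test suite and the acceptance script run scaled-down
configurations chosen to exercise every code path at comfortable runtime:
the shared synthetic bundle uses 4100 genes / 2000 families on 8
chromosomes of 45 Mb (8 kb median genes); structural tests use 120–600
genes; the Monte-Carlo calibration uses 500 null and 200 alternative
datasets at the study's n = 1420 with B = 2000. The published-count
analyses (X² = 226.52, p = 1/2001, 31.9% diagonal) are exact and run on
the printed tables themselves.

## Known limitations

- PAM is a heuristic; optimality is only guaranteed (and asserted) on
  small separable instances.
- The enrichment summary assumes non-overlapping segments per track;
  overlapping bedGraph input would double-count.
- The one-member-silent d_m = 0.5 convention is a documented choice, not
  a published rule; downstream summaries flag those families.
- Density's intersection rule lets a single long insertion spanning the
  whole region contribute density 1/L with coverage 1; density and
  coverage are deliberately complementary in this respect.
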