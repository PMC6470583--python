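# teneigh

Transposable-element (TE) neighborhood metrics and epigenome-conservation
analysis for duplicated gene families.

## The question

More than half of the human genome is repetitive DNA, most of it derived
from transposable elements. TE insertions carry their own epigenetic state
(DNA methylation, repressive histone marks), and that state can spread into
neighboring sequence. For a pair of duplicated genes — a two-copy gene
family — the TE content of each copy's neighborhood may therefore shape how
similar the two copies' epigenomes and expression patterns remain after
duplication. `teneigh` implements the full analysis chain for this
question: quantify each gene's TE neighborhood, classify it, summarize the
gene's epigenetic and expression state, and test whether family members
share TE context and epigenetic state beyond what chance pairing predicts.

## What it computes

**Per-gene TE neighborhood** over the gene body extended by a 2 kb flank
(region length *L*):

- density = (# TE insertions intersecting the region) / *L*, in
  insertions/bp;
- coverage = (bases of the region inside the union of TE intervals) / *L*.

Genes with density = coverage = 0 are *TE-free*; the rest are partitioned
into four classes (TE-very-poor → TE-very-rich) by k-medoids (PAM,
BUILD + SWAP, k = 4) on the raw (density, coverage) points, labels ordered
by medoid density.

**Per-gene epigenetic summaries**, per cell type: mean fold enrichment of
six histone marks (H3K27me3, H3K9me3, H3K27ac, H3K4me1, H3K4me3, H3K36me3)
over the gene body, uncovered positions counting as fold 0; and a
methylation call from hypo-/hyper-methylated region calls — the
overlap-length-weighted mean ratio, with the gene hypo-methylated below
0.25 and hyper-methylated above 0.75.

**Expression divergence** between family members g1, g2 over four cell
types, after FPKM → TPM conversion (TPMᵢ = FPKMᵢ / ΣFPKM × 10⁶):

d_m = ½ Σₖ | g1ₖ/Σg1 − g2ₖ/Σg2 |

the total-variation distance between normalized profiles, in [0, 1].

**The pair-context test.** With category frequencies p₁…p₅, independent
category assignment of the two members gives unordered-pair cell
probabilities qᵢᵢ = pᵢ² and qᵢⱼ = 2pᵢpⱼ. The observed 15-cell family table
is tested with Pearson's X² = Σ (O − nq)²/(nq) and a Monte-Carlo p-value:
B = 2000 multinomial(n, q) replicates, p = (1 + #{X²ₛᵢₘ ≥ X²ₒᵦₛ})/(B + 1).

**Family statistics**: age classes from dS (young < 1 ≤ middle-age < 2 ≤
old), within-family Spearman correlations of every epigenetic summary
(stratified by same/different TE environment and by age, BH-adjusted),
Kruskal–Wallis tests of d_m across age classes, and Kolmogorov–Smirnov
comparisons of ω = dN/dS distributions.

Because the original data sources are access-controlled or bulky, the
package ships a statistically controlled generator (`teneigh.simulate`)
that emulates all the inputs — gene/TE intervals, families with dS/dN,
enrichment tracks, methylation calls, FPKM tables — with tunable category
sharing, within-family rank correlation (Gaussian copula), and
age-dependent expression divergence.

## Worked example

The headline test applied to the published counts for the 1420 human
two-copy families (`examples/pair_context_published_counts.py`):

```
families analysed:           n = 1420
Pearson goodness-of-fit:     X^2 = 226.52
Monte-Carlo p (B = 2000):    p = 0.0004998
same TE environment:         31.9% of families
```

The observed pair table is wildly incompatible with independent category
assignment (no replicate under the null approaches X² = 226.52, so p is
the smallest value the convention allows, 1/2001), and 31.9% of families
have both members in the same TE category versus ≈ 25% expected under
independence.

`examples/simulate_and_analyze.py` runs the whole pipeline on a synthetic
bundle (600 genes, 250 families) and recovers the generator's settings:
category sharing above baseline, within-family Spearman rho ≈ 0.4 for
histone enrichment (stronger in same-TE-environment families), and d_m
increasing with family age. `examples/te_metrics_basics.py` walks each
metric on hand-sized inputs.

A shell entry point mirrors the library: `teneigh simulate`,
`teneigh run`, `teneigh from-printed-tables`.

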