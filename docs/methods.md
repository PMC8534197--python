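# Methods

This note documents the models and numerical choices behind `thyroclass`:
what each stage computes, the parameters that matter, what the synthetic
cohorts do and do not emulate, and the known limitations.

## Filter chains

**Variants.** Records are never dropped during flagging; each of the three
filters only adds a removal reason, so the filters commute and the chain
(quality → population → normal subtraction → rescue) is order-invariant up
to the final status resolution. Boundary semantics are strict on both
sides: QC exactly 20 passes (`< 20` removes), allele frequency exactly
0.001 passes (`> 0.001` removes). A frequency missing from gnomAD or ABraOM
is treated as evidence of rarity, not missing data. COSMIC rescue reimports
*all* flagged variants in catalogued oncogenes/TSGs — including
low-mapping-quality calls, which are marked `rescued_low_quality` in the
audit so they can be reviewed rather than silently trusted. Normal
subtraction keys on (chrom, pos, ref, alt) with 1-based, left-aligned
coordinates; allele re-normalization is the caller's job. Filters are
sample-agnostic: the same key in two samples is evaluated twice.

**Fusions.** FFPM strictly above 0.1 and both junction reads and spanning
fragments strictly above 10 ("each" mode; a "sum" mode is provided because
the conjunction could also be read over the total). Blacklist matching is
by ordered (5′, 3′) gene pair — the reciprocal fusion is a different
transcript. Fusion burden divides by *all* samples of a group, so samples
with zero passing fusions pull the mean down rather than vanishing.

## Expression matrix

Gene retention is set algebra: (prevalence-passing genes ∖ pseudogenes) ∪
COSMIC genes. Prevalence = count strictly above 10 in at least
⌈0.9 · n⌉ samples, computed on raw counts. Pseudogenes are any biotype
containing the substring "pseudogene" (case-insensitive), because the
annotation uses many pseudogene classes. COSMIC rescue overrides both the
prevalence filter and the pseudogene exclusion, so every catalogued cancer
gene expressed in the cohort is represented; provenance records which rule
retained each gene.

Normalization is median-of-ratios: size factor *s_j* = median over genes of
count_gj / (geometric mean of gene g), using only genes with positive
counts in every sample (an error, not a silent fallback, when no such gene
exists). FPM_gj = count_gj / (s_j · L̄) · 10⁶ with the robust library size
L̄ = mean_j(library_j / s_j); with unit factors and equal libraries this is
exactly counts-per-million (columns sum to 10⁶). Size factors are defined
up to a common scale; FPM is invariant to that scale. Factors are estimated
on the full matrix before gene filtering, since library composition is a
sample-level property. Finally log2(FPM + 1).

## Cluster inference

All dissimilarities are Euclidean on log2(FPM + 1) profiles.

**Hopkins statistic.** H = Σu / (Σu + Σw): u are nearest-real-neighbor
distances of m uniform pseudo-points in the bounding box of the data, w are
nearest-neighbor distances of m real probe points (self excluded),
m = ⌈0.1 · n⌉. H ≈ 0.5 on spatially random data and → 1 on clustered data;
the cohort is declared clusterable when the mean of 1−H over 512
bootstrapped replicates is below 0.5. To avoid the distance degeneracy of
~10³-dimensional profiles, the statistic is computed after PCA reduction to
min(10, n−1) components — but only when the ambient dimension actually
exceeds that target: rotating already-low-dimensional data would place the
bounding box's empty corners into the pseudo-point support and bias the
null upward (measured: mean 1−H ≈ 0.39 instead of 0.50 on uniform 5-d
data). Replicate r draws its randomness from the derived seed [seed, r].

**Consensus number of clusters.** Each bootstrap replicate samples 10% of
genes without replacement, builds WPGMA partitions for every k in 2..8, and
lets each index of a configurable panel vote for one k; the modal k over
all (replicate × index) votes wins, ties toward smaller k (parsimony).
The default panel has ten indices: Calinski–Harabasz, average silhouette,
Davies–Bouldin, Dunn, C-index, McClain–Rao, point-biserial, Hartigan
(threshold-10 rule of thumb, falling back to the index minimum),
Krzanowski–Lai, and the gap statistic (5 uniform reference sets per
replicate, first-SE rule). Indices that cannot produce a valid vote on a
replicate (e.g. a degenerate partition) are counted as invalid evaluations,
so votes + invalids = replicates × panel size. The majority-vote consensus,
not the exact panel composition, is the essential mechanism; the panel is a
plain mapping and can be replaced.

**WPGMA / McQuitty.** Agglomerative clustering with the update
d(a∪b, x) = (d(a,x) + d(b,x)) / 2, computed via `scipy`'s `weighted`
linkage; partitions come from cutting the tree into k groups. A naive O(n³)
re-implementation serves as the test oracle (exact agreement on 1000 random
10-point instances). Merge heights are non-decreasing for this update on
metric input.

**PCA and outliers.** Sample profiles are gene-centered and projected onto
the top right singular vectors; each component's sign is fixed so its
largest-magnitude gene loading is positive, making coordinates
reproducible. A sample is an outlier when its mean distance to all others
exceeds the cohort mean + 3 SD of that quantity. At n = 30 this max-z rule
has a familywise false-alarm rate of a few percent (that is intrinsic to
any z = 3 threshold over 30 correlated statistics); outliers are excluded
from clustering and group summaries but still scored.

**BL/RL assignment.** Each cluster is typed by the majority driver lesion
among its mutation-positive members (BRAF-type vs RAS/PAX8-PPARg-type);
driver-negative members inherit the type as negative-BL or negative-RL.
A cluster with no positives or a tied majority raises an error naming the
affected negatives — no silent choice. Negatives with a user-flagged
histology (e.g. Hürthle-cell carcinoma) are reported as negative-other.

## Score panel

**BRS.** Centroids are the within-group k-means solutions with a single
cluster — i.e. group mean vectors; group membership is already fixed by
mutation status, so within-group clustering is degenerate. Scores are
computed on the FPM scale (not log) as the difference of Euclidean
distances to the two centroids, rescaled by the cohort's maximum absolute
raw score, giving a [−1, 1] range with the extreme attained (all-zero raw
scores map to all-zero BRS). The max-absolute rescaling is one of several
maps onto [−1, 1]; it is the simplest that preserves the sign and the zero
point. Negative = BRAF-like. Note the scale is cohort-relative: BRS values
are comparable within a scored cohort, not across cohorts.

**TDS / ERK.** log2(FPM + 1) first, then per-gene median centering, then
the mean over signature genes. Centering before the log would produce
negative arguments, so the log-then-center order is used; the +1
pseudocount keeps zero expression finite. Both scores are invariant to
adding a constant (post-log) to any single gene across the cohort.

**TMB.** Retained (pass or rescued) non-synonymous variants — silent calls
excluded — divided by the capture size, default 50 Mb. Linear in the count,
inverse in the capture size.

**Gene lists.** The 71/16/52 signature identities are configuration
(plain-text files, one symbol per line), not code; the synthetic cohorts
use generated signatures with the same sizes.

## Synthetic cohorts

The generator emulates a 30-sample follicular-patterned tumor cohort:
archetype fractions 1/3 BRAF-like / 2/3 RAS-like, 14/30 driver-negative,
RAS-like positives split 80/20 between RAS point mutations and PAX8-PPARg
fusions. Counts are negative binomial with var = μ + 0.2 μ², gene base
means log-normal (well-expressed draws for signature genes so they survive
the prevalence filter), library sizes uniform in 0.8–1.2 M for a
2000-gene universe. Signature genes shift ± effect/2 (default effect = 2
log2 units between archetypes): BRS genes split half up / half down so both
score signs occur; ERK genes up in BRAF-like; TDS genes up in RAS-like.
Background variant calls (Poisson, mean 400/sample) are stratified into
clean / low-quality / population-common / normal-shared, with 5% of the
filtered strata placed in COSMIC genes to exercise the rescue path; the
load yields per-sample TMB near 4/Mb after filtering. Fusions per sample
are Poisson with archetype rates 1.0 and 2.8, with passing support
(threshold + geometric tails), plus sub-threshold calls and blacklist
artifacts so every filter branch occurs. The labelled reference cohort
(26 + 61 samples) shares the gene universe and archetype means, which is
what makes reference centroids applicable to the cohort.

All randomness flows from one seed through named sub-streams (gene
universe, sample truth, counts, variants, fusions, reference), so each
table is reproducible independently of generation order.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: gene–gene correlation beyond the archetype
factor, batch effects and GC/length biases, clonal heterogeneity and
subclonal allele fractions, realistic variant annotation noise, breakpoint
structure of fusions, and immune/stromal admixture. Results on synthetic
cohorts validate the *mechanics* of the pipeline (filters, normalization,
consensus, scores), not the biological discrimination power of the
signatures.

## Problem sizes and defaults

Defaults follow the published workflow where it states values: QC 20,
AF 0.001, FFPM 0.1, support 10, prevalence 10 / 90%, Hopkins 512
replicates, consensus 1080 replicates × 10% genes, k ≤ 8, capture 50 Mb.
Examples and tests run the bootstraps at reduced replicate counts
(16–128 Hopkins, 8–100 consensus) — the consensus is already stable at
tens of replicates on the 30-sample cohort, and the acceptance script uses
the full 512 Hopkins replicates. With the default synthetic conditions the
measured mean 1−H lands around 0.44–0.49: below the 0.5 threshold, but not
dramatically so, because the per-gene negative-binomial noise at dispersion
0.2 across ~1500 retained genes is large relative to a 2-log2-unit shift on
139 signature genes. That is the honest operating point of the statistic at
these conditions, not a tuned margin.

## Known limitations

* The Hopkins bounding box is axis-aligned in the reduced space; strongly
  anisotropic null data can still bias the statistic.
* The consensus panel is a 10-index stand-in for the larger panels used by
  R's NbClust-style tools; the vote pooling (all replicates × indices into
  one mode) is one of several defensible schemes.
* BRS is cohort-relative by construction (max-absolute scaling).
* The variant chain assumes upstream left-alignment and does not collapse
  multi-allelic records.
* `fusion_burden` counts calls, not unique fusion partners; recurrent
  identical calls in one sample count multiply.
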